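import io

import pytest
from PIL import Image

from pgpath.synthetic import clopidogrel_fixture


@pytest.fixture()
def fixture_bundle():
    """Fresh worked-example bundle: (records, pk_doc, pd_doc, manifest)."""
    return clopidogrel_fixture()


@pytest.fixture()
def pk_doc(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture()
def pd_doc(fixture_bundle):
    return fixture_bundle[2]


@pytest.fixture()
def manifest(fixture_bundle):
    return fixture_bundle[3]


@pytest.fixture()
def white_png():
    """A tiny valid PNG generated at test time."""
    buf = io.BytesIO()
    Image.new("RGB", (4, 4), "white").save(buf, format="PNG")
    return buf.getvalue()
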