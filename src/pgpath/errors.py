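"""Exception hierarchy for pgpath.

All library errors derive from :class:`PgPathError` so callers can catch a
single base class at the CLI boundary.
"""


class PgPathError(Exception):
    """Base class for all pgpath errors."""


class ValidationError(PgPathError):
    """A pathway document violates the standardized taxonomy."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.code}@{v.ref}" for v in self.violations)
        super().__init__(f"invalid pathway document: {lines}")


class EmptyInputError(PgPathError):
    """A builder received no interaction records."""


class MixedDrugError(PgPathError):
    """Interaction records name more than one drug (pathways are one-drug-centered)."""


class UnplacedGeneError(PgPathError):
    """An explicit placement map does not cover every gene in the records."""


class NoTargetError(PgPathError):
    """A pharmacodynamic pathway was requested without any target records."""


class ParseError(PgPathError):
    """GPML input could not be parsed."""


class FormatError(PgPathError):
    """A VCF or tabular input is malformed."""


class MissingSourceError(PgPathError):
    """The configured SIFT INFO key is absent from the VCF header."""


class ScoreRangeError(PgPathError):
    """A SIFT or GVB score falls outside its legal range."""


class ImageDecodeError(PgPathError):
    """Background bytes are not a decodable raster image."""


class TypeMismatchError(PgPathError):
    """An operation received a node type it does not support."""


class KindError(PgPathError):
    """An operation received a PK document where PD was required, or vice versa."""


class SameDrugError(PgPathError):
    """Drug-drug interaction inference requires two distinct principal drugs."""


class SpecError(PgPathError):
    """A synthetic-data specification is invalid."""


class UnknownArrowheadWarning(UserWarning):
    """A GPML interaction used an arrowhead class outside the documented mapping."""
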