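"""YAML/JSON configuration: vocabulary extensions, placements, theme, scoring.

The schema's compartment vocabulary is deliberately closed but extensible:
a config may register extra compartment names per level (a warning is
logged when they are used), override the role-default placements, the
excretion routing, the color theme and the scoring knobs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .errors import FormatError
from .gvb import DEFAULT_FLOOR
from .personalize import DEFAULT_IMPAIRED_THRESHOLD, ColorScale
from .render import Theme
from .vocab import CompartmentLevel, GeneRole

logger = logging.getLogger(__name__)


@dataclass
class PgPathConfig:
    extra_vocabulary: dict = field(default_factory=dict)  # CompartmentLevel -> set of names
    default_placement: dict = field(default_factory=dict)  # GeneRole -> compartment name
    excretion_overrides: dict = field(default_factory=dict)  # metabolite id -> compartment name
    theme: Theme = field(default_factory=Theme)
    gvb_floor: float = DEFAULT_FLOOR
    sift_threshold: float | None = None
    count_hom_alt_twice: bool = False
    impaired_threshold: float = DEFAULT_IMPAIRED_THRESHOLD


def load_config(text: str) -> PgPathConfig:
    """Parse a YAML (or JSON, a YAML subset) configuration document."""
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable config: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError("config root must be a mapping")
    cfg = PgPathConfig()

    for level_name, names in (raw.get("compartment_extensions") or {}).items():
        level = CompartmentLevel(level_name)
        cfg.extra_vocabulary[level] = set(names)
        logger.warning(
            "compartment vocabulary extended at level %s with %s", level.value, sorted(names)
        )
    for role_name, name in (raw.get("default_placement") or {}).items():
        cfg.default_placement[GeneRole(role_name)] = name
    cfg.excretion_overrides = dict(raw.get("excretion_overrides") or {})

    theme_raw = raw.get("theme") or {}
    scale_raw = theme_raw.pop("scale", {})
    for key, value in theme_raw.items():
        if not hasattr(cfg.theme, key):
            raise FormatError(f"unknown theme key {key!r}")
        setattr(cfg.theme, key, value)
    cfg.theme.scale = ColorScale(
        neutral=scale_raw.get("neutral", cfg.theme.scale.neutral),
        alert=scale_raw.get("alert", cfg.theme.scale.alert),
        floor=float(scale_raw.get("floor", cfg.theme.scale.floor)),
    )

    scoring = raw.get("scoring") or {}
    cfg.gvb_floor = float(scoring.get("floor", cfg.gvb_floor))
    if "sift_threshold" in scoring and scoring["sift_threshold"] is not None:
        cfg.sift_threshold = float(scoring["sift_threshold"])
    cfg.count_hom_alt_twice = bool(scoring.get("count_hom_alt_twice", False))
    cfg.impaired_threshold = float(scoring.get("impaired_threshold", cfg.impaired_threshold))
    return cfg
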