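"""Movement taxonomy: body parts, directions, and laterality.

Evoked movements are recorded as a body part (e.g. ``tongue``, ``shoulder``),
an optional movement direction drawn from a per-part vocabulary
(e.g. ``extension``, ``retraction``), and a laterality (contralateral by
default, bilateral for the minority of sites that move both sides).  Body
parts group into the four gross body regions used for somatotopic
summaries: face, forelimb, hindlimb, trunk.

The taxonomy is configurable; :func:`default_taxonomy` returns the
vocabulary used for galago-like sensorimotor maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

LATERALITIES = ("contralateral", "bilateral")

# file grammar: body_part[:direction][:bilateral]
_LABEL_SEP = ":"


@dataclass(frozen=True, order=True)
class MovementLabel:
    """One evoked movement: body part, optional direction, laterality."""

    body_part: str
    direction: str | None = None
    laterality: str = "contralateral"

    def __str__(self) -> str:
        parts = [self.body_part]
        if self.direction is not None:
            parts.append(self.direction)
        if self.laterality == "bilateral":
            parts.append("bilateral")
        return _LABEL_SEP.join(parts)


class TaxonomyError(ValueError):
    """A label does not validate against the active taxonomy."""


@dataclass(frozen=True)
class MovementTaxonomy:
    """Closed vocabulary of body parts, their regions and directions.

    Parameters
    ----------
    body_parts
        Ordered body-part names; order is used for stable reporting.
    body_regions
        Mapping body part -> body region (face/forelimb/hindlimb/trunk).
        Every body part must map to exactly one region.
    directions
        Per body part, the allowed direction vocabulary (may be empty).
    """

    body_parts: tuple[str, ...]
    body_regions: Mapping[str, str]
    directions: Mapping[str, tuple[str, ...]]
    lateralities: tuple[str, ...] = LATERALITIES

    def __post_init__(self) -> None:
        if len(set(self.body_parts)) != len(self.body_parts):
            raise TaxonomyError("body part names must be unique")
        missing = [p for p in self.body_parts if p not in self.body_regions]
        if missing:
            raise TaxonomyError(f"body parts without a region: {missing}")
        extra = [p for p in self.body_regions if p not in self.body_parts]
        if extra:
            raise TaxonomyError(f"regions declared for unknown body parts: {extra}")
        for part in self.directions:
            if part not in self.body_parts:
                raise TaxonomyError(f"directions declared for unknown body part {part!r}")

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.body_parts:
            seen.setdefault(self.body_regions[p], None)
        return tuple(seen)

    def parts_in_region(self, region: str) -> tuple[str, ...]:
        return tuple(p for p in self.body_parts if self.body_regions[p] == region)

    def validate(self, label: MovementLabel) -> MovementLabel:
        """Validate ``label`` against this taxonomy; return it unchanged."""
        if label.body_part not in self.body_parts:
            raise TaxonomyError(f"unknown body part {label.body_part!r}")
        if label.direction is not None:
            allowed = self.directions.get(label.body_part, ())
            if label.direction not in allowed:
                raise TaxonomyError(
                    f"unknown direction {label.direction!r} for body part "
                    f"{label.body_part!r} (allowed: {list(allowed)})"
                )
        if label.laterality not in self.lateralities:
            raise TaxonomyError(f"unknown laterality {label.laterality!r}")
        return label

    def parse(self, text: str) -> MovementLabel:
        """Parse ``body_part[:direction][:bilateral]`` and validate."""
        tokens = [t.strip() for t in text.strip().split(_LABEL_SEP) if t.strip()]
        if not tokens:
            raise TaxonomyError("empty movement label")
        laterality = "contralateral"
        if tokens[-1] in self.lateralities:
            laterality = tokens[-1]
            tokens = tokens[:-1]
        if not tokens or len(tokens) > 2:
            raise TaxonomyError(f"cannot parse movement label {text!r}")
        body_part = tokens[0]
        direction = tokens[1] if len(tokens) == 2 else None
        return self.validate(MovementLabel(body_part, direction, laterality))

    def parse_many(self, text: str, sep: str = ";") -> frozenset[MovementLabel]:
        """Parse a separator-joined list of labels (empty text -> empty set)."""
        text = text.strip()
        if not text:
            return frozenset()
        return frozenset(self.parse(tok) for tok in text.split(sep) if tok.strip())


_JOINT_DIRECTIONS = ("extension", "flexion")


def default_taxonomy() -> MovementTaxonomy:
    """Taxonomy for galago-like sensorimotor movement maps.

    Face parts carry mouth/orofacial directions (the tongue vocabulary
    includes lateral, up/down and repetitive movements); limb joints carry
    extension/flexion, with pronation/supination on the wrist.
    """
    body_regions = {
        "tongue": "face",
        "lips": "face",
        "ear": "face",
        "jaw": "face",
        "eye": "face",
        "eyelid": "face",
        "shoulder": "forelimb",
        "elbow": "forelimb",
        "wrist": "forelimb",
        "digit": "forelimb",
        "trunk": "trunk",
        "hip": "hindlimb",
        "knee": "hindlimb",
        "ankle": "hindlimb",
        "toe": "hindlimb",
    }
    directions = {
        "tongue": ("extension", "retraction", "lateral", "up", "down", "repetitive"),
        "lips": ("retraction", "open", "close"),
        "ear": ("retraction", "lateral"),
        "jaw": ("open", "close"),
        "eye": ("up", "down", "lateral"),
        "eyelid": ("open", "close"),
        "shoulder": _JOINT_DIRECTIONS,
        "elbow": _JOINT_DIRECTIONS,
        "wrist": _JOINT_DIRECTIONS + ("pronation", "supination"),
        "digit": _JOINT_DIRECTIONS,
        "trunk": _JOINT_DIRECTIONS + ("lateral",),
        "hip": _JOINT_DIRECTIONS,
        "knee": _JOINT_DIRECTIONS,
        "ankle": _JOINT_DIRECTIONS,
        "toe": _JOINT_DIRECTIONS,
    }
    return MovementTaxonomy(
        body_parts=tuple(body_regions),
        body_regions=body_regions,
        directions=directions,
    )


def taxonomy_from_dict(cfg: Mapping) -> MovementTaxonomy:
    """Build a taxonomy from a configuration mapping (e.g. parsed YAML)."""
    body_regions = dict(cfg["body_regions"])
    body_parts = tuple(cfg.get("body_parts", body_regions))
    directions = {k: tuple(v) for k, v in cfg.get("directions", {}).items()}
    lateralities = tuple(cfg.get("lateralities", LATERALITIES))
    return MovementTaxonomy(body_parts, body_regions, directions, lateralities)
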