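"""Morphology rules: suspicious features, benign features, and the typical
intrapulmonary-lymph-node (IPLN) pattern, reduced to one verdict per scan.

The verdict drives the classifier: *suspicious* morphology upgrades the risk
category by one step; *benign* morphology sends the nodule back to annual
screening at any size.  Benign takes precedence when both feature classes
co-occur, with the conflict recorded as a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .growth import InvalidInputError, SizeMeasurement

__all__ = [
    "SUSPICIOUS_FLAGS",
    "EXTENDED_SUSPICIOUS_FLAGS",
    "CALCIFICATION_PATTERNS",
    "BENIGN_CALCIFICATION_PATTERNS",
    "SHAPES",
    "MARGINS",
    "GGO_SUSPICIOUS_DIAMETER_MM",
    "MorphologyProfile",
    "MorphologyVerdict",
    "IplnCriteria",
    "IPLN_CRITERIA",
    "IPLN_CRITERIA_LITERATURE",
    "is_suspicious",
    "is_typical_ipln",
    "is_benign",
    "morphology_verdict",
]

#: Feature flags that upgrade the risk category when present.
SUSPICIOUS_FLAGS = (
    "spiculation",
    "pleural_tag",
    "fissural_displacement",
    "cystic_component",
    "bubble_like_lucencies",
    "concave_sign",
    "narrowed_vessels",
    "bronchus_cut_off",
)

#: Reported-in-the-literature flags accepted as input but only treated as
#: suspicious through an opt-in extension set.
EXTENDED_SUSPICIOUS_FLAGS = ("air_bronchogram",)

CALCIFICATION_PATTERNS = frozenset({"none", "central", "diffuse", "popcorn", "other"})
BENIGN_CALCIFICATION_PATTERNS = frozenset({"central", "diffuse", "popcorn"})
SHAPES = frozenset({"round", "oval", "lentiform", "triangular", "polygonal", "irregular"})
MARGINS = frozenset({"smooth", "lobulated", "spiculated"})

#: A ground-glass component of at least 3 cm is itself a suspicious feature
#: for subsolid nodules.
GGO_SUSPICIOUS_DIAMETER_MM = 30.0

#: Intranodular fat reads between -120 and -40 HU.
FAT_HU_RANGE = (-120.0, -40.0)


@dataclass(frozen=True)
class MorphologyProfile:
    """Per-scan morphology record.  Absent booleans mean "not reported" and
    are treated as False for suspicious flags, but disqualify the IPLN call
    (a benign label is never made on missing geometry)."""

    # suspicious feature flags
    spiculation: Optional[bool] = None
    pleural_tag: Optional[bool] = None
    fissural_displacement: Optional[bool] = None
    cystic_component: Optional[bool] = None
    bubble_like_lucencies: Optional[bool] = None
    concave_sign: Optional[bool] = None
    narrowed_vessels: Optional[bool] = None
    bronchus_cut_off: Optional[bool] = None
    air_bronchogram: Optional[bool] = None
    # benign features
    calcification_pattern: str = "none"
    fat_attenuation: Optional[bool] = None
    fat_hu: Optional[float] = None
    infection_suspected: Optional[bool] = None
    # geometry (for the IPLN pattern)
    shape: Optional[str] = None
    margin: Optional[str] = None
    distance_to_pleura_mm: Optional[float] = None
    below_carina: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.calcification_pattern not in CALCIFICATION_PATTERNS:
            raise InvalidInputError(
                f"unknown calcification pattern: {self.calcification_pattern!r}"
            )
        if self.shape is not None and self.shape not in SHAPES:
            raise InvalidInputError(f"unknown shape: {self.shape!r}")
        if self.margin is not None and self.margin not in MARGINS:
            raise InvalidInputError(f"unknown margin: {self.margin!r}")
        if self.fat_attenuation and self.fat_hu is not None:
            lo, hi = FAT_HU_RANGE
            if not (lo <= self.fat_hu <= hi):
                raise InvalidInputError(
                    f"fat attenuation requires HU in [{lo}, {hi}], got {self.fat_hu}"
                )
        if (
            self.distance_to_pleura_mm is not None
            and self.distance_to_pleura_mm < 0
        ):
            raise InvalidInputError("distance to pleura must be nonnegative")

    def flag(self, name: str) -> bool:
        """Boolean value of a feature flag with absent treated as False."""
        return bool(getattr(self, name))

    def suspicious_flags_set(self, extended: bool = False) -> tuple[str, ...]:
        names = SUSPICIOUS_FLAGS + (EXTENDED_SUSPICIOUS_FLAGS if extended else ())
        return tuple(n for n in names if self.flag(n))


@dataclass(frozen=True)
class MorphologyVerdict:
    verdict: str  # benign | neutral | suspicious
    reasons: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def benign(self) -> bool:
        return self.verdict == "benign"

    @property
    def suspicious(self) -> bool:
        return self.verdict == "suspicious"


@dataclass(frozen=True)
class IplnCriteria:
    """Geometric criteria for a typical intrapulmonary lymph node.

    The screening rule uses smooth margins; oval, lentiform or triangular
    shape; diameter and pleural distance strictly below 10 mm; location below
    the carina.  An alternative literature-derived set (<= 12 mm diameter,
    <= 15 mm from the pleura, round/oval/polygonal shape) is provided for
    sensitivity analyses.
    """

    shapes: frozenset[str] = frozenset({"oval", "lentiform", "triangular"})
    max_diameter_mm: float = 10.0
    max_pleural_distance_mm: float = 10.0
    inclusive: bool = False  # strict "<" bounds by default

    def _within(self, value: float, bound: float) -> bool:
        return value <= bound if self.inclusive else value < bound


IPLN_CRITERIA = IplnCriteria()
IPLN_CRITERIA_LITERATURE = IplnCriteria(
    shapes=frozenset({"round", "oval", "polygonal"}),
    max_diameter_mm=12.0,
    max_pleural_distance_mm=15.0,
    inclusive=True,
)


def is_suspicious(
    profile: MorphologyProfile,
    density: str,
    ggo_diameter_mm: Optional[float] = None,
    *,
    extended: bool = False,
) -> tuple[bool, tuple[str, ...]]:
    """True when any suspicious feature flag is set, or when a subsolid
    nodule's ground-glass component reaches 30 mm.  Returns every trigger."""
    if density not in {"solid", "part_solid", "non_solid"}:
        raise InvalidInputError(f"unknown density class: {density!r}")
    reasons = list(profile.suspicious_flags_set(extended=extended))
    if (
        density in {"part_solid", "non_solid"}
        and ggo_diameter_mm is not None
        and ggo_diameter_mm >= GGO_SUSPICIOUS_DIAMETER_MM
    ):
        reasons.append("ggo_component_ge_30mm")
    return bool(reasons), tuple(reasons)


def is_typical_ipln(
    profile: MorphologyProfile,
    size: SizeMeasurement,
    criteria: IplnCriteria = IPLN_CRITERIA,
) -> tuple[bool, tuple[str, ...]]:
    """Typical IPLN pattern: smooth margin, oval/lentiform/triangular shape,
    sub-centimetre, within a centimetre of the pleura, below the carina.

    Any absent geometry field fails the test — a nodule is never labelled a
    lymph node on missing information.
    """
    if profile.margin != "smooth":
        return False, ()
    if profile.shape is None or profile.shape not in criteria.shapes:
        return False, ()
    if not criteria._within(size.diameter_mm, criteria.max_diameter_mm):
        return False, ()
    if profile.distance_to_pleura_mm is None or not criteria._within(
        profile.distance_to_pleura_mm, criteria.max_pleural_distance_mm
    ):
        return False, ()
    if profile.below_carina is not True:
        return False, ()
    return True, ("typical_ipln",)


def is_benign(
    profile: MorphologyProfile,
    size: SizeMeasurement,
    ipln_criteria: IplnCriteria = IPLN_CRITERIA,
) -> tuple[bool, tuple[str, ...]]:
    """Benign-feature test: characteristic calcification, intranodular fat,
    typical IPLN pattern, or suspected infection."""
    reasons: list[str] = []
    if profile.calcification_pattern in BENIGN_CALCIFICATION_PATTERNS:
        reasons.append(f"benign_calcification_{profile.calcification_pattern}")
    if profile.flag("fat_attenuation"):
        reasons.append("fat_attenuation")
    ipln, ipln_reasons = is_typical_ipln(profile, size, ipln_criteria)
    if ipln:
        reasons.extend(ipln_reasons)
    if profile.flag("infection_suspected"):
        reasons.append("infection_suspected")
    return bool(reasons), tuple(reasons)


def morphology_verdict(
    profile: MorphologyProfile,
    density: str,
    size: SizeMeasurement,
    ggo_diameter_mm: Optional[float] = None,
    *,
    extended_suspicious: bool = False,
    ipln_criteria: IplnCriteria = IPLN_CRITERIA,
) -> MorphologyVerdict:
    """Single morphology verdict with full reason trace.

    Precedence: benign > suspicious > neutral.  A profile triggering both
    classes resolves to benign (annual screening at any size) but carries a
    warning so the conflict is auditable.
    """
    benign, benign_reasons = is_benign(profile, size, ipln_criteria)
    susp, susp_reasons = is_suspicious(
        profile, density, ggo_diameter_mm, extended=extended_suspicious
    )
    if benign:
        warnings = ()
        if susp:
            warnings = (
                "benign_and_suspicious_features_coexist_benign_precedence",
            )
        return MorphologyVerdict("benign", benign_reasons + susp_reasons, warnings)
    if susp:
        return MorphologyVerdict("suspicious", susp_reasons)
    return MorphologyVerdict("neutral", ())
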