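"""Size conversions and growth-rate computation for pulmonary nodules.

Everything downstream — the baseline/follow-up classifier, the programme
engine, the simulator — consumes the primitives in this module:

* sphere-equivalent ("effective") diameter <-> volume conversions,
* volume doubling time (VDT) under the exponential-growth model,
* the per-interval substantial-growth / regression assessment,
* the informational mass metric (volume x physical density).

Units are mm, mm^3 and days throughout.  VDT is reported in days; a nodule
whose volume is unchanged or shrinking has VDT = +inf so that "VDT >= cutoff"
comparisons hold without special-casing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "InvalidInputError",
    "IncomparableMeasurementsError",
    "SizeMeasurement",
    "GrowthAssessment",
    "effective_diameter",
    "volume_from_diameter",
    "diameter_growth_factor_for_volume_doubling",
    "volume_doubling_time",
    "vdt_cutoff_days",
    "diameter_growth_threshold_mm",
    "assess_growth",
    "nodule_mass",
]


class InvalidInputError(ValueError):
    """A measurement or parameter violates its physical domain."""


class IncomparableMeasurementsError(InvalidInputError):
    """Two scans share no size modality (no volume pair, no diameter pair)."""


# VDT workup cutoffs by elapsed interval: < 250 d at the 3-month recheck,
# < 400 d at 6 months, < 500 d at >= 12 months.  The nominal visits are
# 90 / 180 / 365 days; bin edges sit at the midpoints between them.
_VDT_BIN_EDGES_DAYS = (135, 270)
_VDT_CUTOFFS_DAYS = (250.0, 400.0, 500.0)

#: Manual/average diameter increase that counts as substantial growth when
#: volumetry fails, per comparison within at most one year.
DIAMETER_GROWTH_THRESHOLD_MM = 1.5

#: Default quantification of "marked decrease" for the regression rule.
DEFAULT_REGRESSION_VOLUME_FRACTION = 0.25
DEFAULT_REGRESSION_DIAMETER_MM = 2.0


@dataclass(frozen=True)
class SizeMeasurement:
    """One size measurement of a nodule (or of its solid component).

    At least one of ``volume_mm3`` / ``mean_diameter_mm`` must be present.
    A volume with no ``segmentation_complete`` flag is treated as completely
    segmented (the common case for reported volumetry).
    """

    volume_mm3: Optional[float] = None
    mean_diameter_mm: Optional[float] = None
    segmentation_complete: Optional[bool] = None
    measured_manually: bool = False

    def __post_init__(self) -> None:
        if self.volume_mm3 is None and self.mean_diameter_mm is None:
            raise InvalidInputError(
                "SizeMeasurement needs a volume or a mean diameter"
            )
        if self.volume_mm3 is not None and self.volume_mm3 < 0:
            raise InvalidInputError(f"negative volume: {self.volume_mm3}")
        if self.mean_diameter_mm is not None and self.mean_diameter_mm < 0:
            raise InvalidInputError(f"negative diameter: {self.mean_diameter_mm}")

    @property
    def has_volume(self) -> bool:
        return self.volume_mm3 is not None

    @property
    def diameter_mm(self) -> float:
        """Best available diameter: effective (from volume) when volumetry
        succeeded, otherwise the manual/average diameter."""
        if self.volume_mm3 is not None:
            return effective_diameter(self.volume_mm3)
        assert self.mean_diameter_mm is not None
        return self.mean_diameter_mm


@dataclass(frozen=True)
class GrowthAssessment:
    """Outcome of comparing two scans of the same nodule compartment.

    ``vdt_days`` is None when volumetry was unusable on either scan, +inf
    when the volume did not increase, and finite positive otherwise.
    ``substantial_growth`` and ``regression`` are mutually exclusive.
    """

    interval_days: int
    vdt_days: Optional[float]
    delta_diameter_mm: float
    delta_diameter_from_baseline_mm: float
    substantial_growth: bool
    regression: bool
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.substantial_growth and self.regression:
            raise InvalidInputError("growth and regression cannot both hold")

    @property
    def volume_growth_fraction(self) -> Optional[float]:
        """Fractional volume change implied by the VDT over the interval
        (0.15 means +15%); None when volumetry failed."""
        if self.vdt_days is None:
            return None
        if math.isinf(self.vdt_days):
            return 0.0
        return 2.0 ** (self.interval_days / self.vdt_days) - 1.0


def effective_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere with the given volume: d = (6 V / pi)^(1/3)."""
    if volume_mm3 < 0:
        raise InvalidInputError(f"negative volume: {volume_mm3}")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


def volume_from_diameter(diameter_mm: float) -> float:
    """Volume of a sphere with the given diameter: V = pi d^3 / 6."""
    if diameter_mm < 0:
        raise InvalidInputError(f"negative diameter: {diameter_mm}")
    return math.pi * diameter_mm**3 / 6.0


def diameter_growth_factor_for_volume_doubling() -> float:
    """Percent diameter increase corresponding to one volume doubling.

    A doubling in volume stretches each linear dimension by 2^(1/3), i.e.
    the diameter grows by only ~26% — the geometric reason volumetry detects
    growth earlier than calliper measurements.
    """
    return 100.0 * (2.0 ** (1.0 / 3.0) - 1.0)


def volume_doubling_time(v1_mm3: float, v2_mm3: float, interval_days: float) -> float:
    """VDT in days under exponential growth: VDT = dt * ln 2 / ln(v2/v1).

    Returns +inf when ``v2 <= v1`` (no growth: the nodule never doubles),
    so threshold comparisons of the form ``vdt >= cutoff`` are natural.
    """
    if v1_mm3 <= 0 or v2_mm3 <= 0:
        raise InvalidInputError("volumes must be strictly positive for VDT")
    if interval_days <= 0:
        raise InvalidInputError("interval must be strictly positive")
    if v2_mm3 <= v1_mm3:
        return math.inf
    return interval_days * math.log(2.0) / math.log(v2_mm3 / v1_mm3)


def vdt_cutoff_days(interval_days: float) -> float:
    """Substantial-growth VDT cutoff appropriate for the elapsed interval.

    <= 135 d -> 250 d, 136-270 d -> 400 d, > 270 d -> 500 d (bin edges at the
    midpoints between the nominal 3 / 6 / 12-month visits).
    """
    if interval_days <= 0:
        raise InvalidInputError("interval must be strictly positive")
    for edge, cutoff in zip(_VDT_BIN_EDGES_DAYS, _VDT_CUTOFFS_DAYS):
        if interval_days <= edge:
            return cutoff
    return _VDT_CUTOFFS_DAYS[-1]


def diameter_growth_threshold_mm(interval_days: float) -> float:
    """Diameter-increase threshold for the volumetry-failed fallback.

    Fixed at 1.5 mm for comparisons up to a year apart; pro-rated for longer
    gaps so the per-year reading of the rule is preserved.
    """
    if interval_days <= 366:
        return DIAMETER_GROWTH_THRESHOLD_MM
    return DIAMETER_GROWTH_THRESHOLD_MM * interval_days / 365.0


def _pair_diameters(prev: SizeMeasurement, curr: SizeMeasurement) -> tuple[float, float]:
    """Diameters for a scan pair, preferring a like-for-like modality.

    Effective diameters are used when both scans carry volumes; manual mean
    diameters when both carry them; otherwise whichever diameter each scan
    can provide (mixed modality, accepted because the effective diameter is
    defined to be comparable with the average diameter)."""
    if prev.has_volume and curr.has_volume:
        return effective_diameter(prev.volume_mm3), effective_diameter(curr.volume_mm3)
    if prev.mean_diameter_mm is not None and curr.mean_diameter_mm is not None:
        return prev.mean_diameter_mm, curr.mean_diameter_mm
    try:
        return prev.diameter_mm, curr.diameter_mm
    except (AssertionError, InvalidInputError) as exc:  # pragma: no cover
        raise IncomparableMeasurementsError(str(exc)) from exc


def assess_growth(
    prev: SizeMeasurement,
    curr: SizeMeasurement,
    interval_days: int,
    baseline: Optional[SizeMeasurement] = None,
    *,
    new_suspicious_morphology: bool = False,
    regression_volume_fraction: float = DEFAULT_REGRESSION_VOLUME_FRACTION,
    regression_diameter_mm: float = DEFAULT_REGRESSION_DIAMETER_MM,
) -> GrowthAssessment:
    """Compare two scans of one nodule compartment and classify the change.

    Substantial growth is declared when volumetry is usable on both scans
    and the VDT lies below the interval-appropriate cutoff, or — when
    volumetry is unusable — when the diameter increased by more than the
    fallback threshold, or when a suspicious morphology feature newly
    appeared (``new_suspicious_morphology``).

    Regression (disappearance, volume decrease >= ``regression_volume_fraction``,
    or diameter decrease >= ``regression_diameter_mm``) is mutually exclusive
    with substantial growth; morphology-driven growth takes precedence if
    both criteria fire, with a note recording the conflict.

    ``baseline`` (defaulting to ``prev``) anchors
    ``delta_diameter_from_baseline_mm``, used by the slow-growth referral rule.
    """
    if interval_days <= 0:
        raise InvalidInputError("interval must be strictly positive")
    if baseline is None:
        baseline = prev

    notes: list[str] = []

    volumetry_usable = prev.has_volume and curr.has_volume
    vdt: Optional[float] = None
    if volumetry_usable:
        if curr.volume_mm3 == 0:
            vdt = math.inf
            notes.append("nodule_disappeared")
        elif prev.volume_mm3 == 0:
            vdt = None  # appeared from nothing: VDT undefined
            notes.append("nodule_appeared")
        else:
            vdt = volume_doubling_time(prev.volume_mm3, curr.volume_mm3, interval_days)

    d_prev, d_curr = _pair_diameters(prev, curr)
    delta_d = d_curr - d_prev
    d_base, _ = _pair_diameters(baseline, curr)
    delta_d_base = d_curr - d_base

    if vdt is not None:
        growing = vdt < vdt_cutoff_days(interval_days)
        if growing:
            notes.append(f"vdt_{vdt:.0f}d_below_{vdt_cutoff_days(interval_days):.0f}d_cutoff")
    else:
        growing = delta_d > diameter_growth_threshold_mm(interval_days)
        if growing:
            notes.append("diameter_increase_gt_threshold")
    if new_suspicious_morphology:
        growing = True
        notes.append("substantial_morphology_change")

    disappeared = curr.has_volume and curr.volume_mm3 == 0
    vol_drop = (
        volumetry_usable
        and prev.volume_mm3 > 0
        and (prev.volume_mm3 - (curr.volume_mm3 or 0.0)) / prev.volume_mm3
        >= regression_volume_fraction
    )
    diam_drop = delta_d <= -regression_diameter_mm
    regressing = disappeared or vol_drop or diam_drop
    if regressing:
        notes.append("regression")

    if growing and regressing:
        # only reachable via a new suspicious flag on a shrinking nodule
        regressing = False
        notes.append("morphology_change_overrides_regression")

    return GrowthAssessment(
        interval_days=int(interval_days),
        vdt_days=vdt,
        delta_diameter_mm=delta_d,
        delta_diameter_from_baseline_mm=delta_d_base,
        substantial_growth=growing,
        regression=regressing,
        notes=tuple(notes),
    )


def nodule_mass(volume_mm3: float, mean_density_hu: float) -> float:
    """Nodule mass in mg: volume x physical density.

    CT numbers map linearly to physical density with water at 0 HU = 1 mg/mm^3
    and air at -1000 HU = 0, hence density = (HU + 1000) / 1000 mg/mm^3.
    Informational only — no current management rule consumes mass.
    """
    if volume_mm3 < 0:
        raise InvalidInputError(f"negative volume: {volume_mm3}")
    return volume_mm3 * (mean_density_hu + 1000.0) / 1000.0
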