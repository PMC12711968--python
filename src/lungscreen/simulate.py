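"""Synthetic screening cohorts: lesions with known natural history plus
calibrated measurement noise.

The simulator exists so the rule engine can be exercised end-to-end with a
ground-truth ledger and no real CT data.  Lesion volumes follow the
exponential-growth model V(t) = V0 * 2^((t - t0)/VDT); a negative VDT gives
exponential shrinkage (resolving inflammatory lesions).  Measurement noise is
calibrated to the reported variability of screening measurements: 95%
intervals of +/-12% for completely segmented volumetry, +/-30% for incomplete
segmentation, and manual-diameter 95% limits of agreement of +/-1.4 mm
(intra-observer) / +/-1.7 mm (inter-observer).

Class mixtures, prevalence and VDT distributions are configuration defaults
chosen to be plausible for a high-risk screening population; they are NOT
literature-calibrated estimates and are meant to be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .growth import InvalidInputError, SizeMeasurement, effective_diameter
from .io import MORPH_COLUMNS, OBSERVATION_COLUMNS
from .morphology import MorphologyProfile

__all__ = [
    "LESION_CLASSES",
    "LesionSpec",
    "MeasurementErrorModel",
    "NOISE_FREE",
    "CohortSpec",
    "DEFAULT_MIXTURE",
    "true_volume",
    "measure",
    "measure_diameter_manual",
    "draw_lesion",
    "generate_cohort",
]

LESION_CLASSES = (
    "malignant_solid",
    "malignant_subsolid",
    "benign_stable",
    "benign_slow_growing",
    "ipln",
    "inflammatory_resolving",
)

#: Minimum volume at which a lesion is detectable on LDCT (roughly a 3 mm
#: sphere); smaller lesions produce no observation row.
DETECTION_FLOOR_MM3 = 15.0


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth natural history of one lesion.

    ``true_vdt_days`` is signed: positive = doubling time of a grower,
    ``inf`` = stable, negative = halving time of a resolving lesion.
    Subsolid lesions may grow a solid core from ``core_onset_day`` on, with
    its own V0 and VDT.
    """

    lesion_class: str
    true_volume_mm3_at_t0: float
    true_vdt_days: float
    onset_day: int = 0
    core_onset_day: Optional[int] = None
    core_volume_mm3_at_onset: float = 30.0
    core_vdt_days: float = 200.0
    morphology: MorphologyProfile = field(default_factory=MorphologyProfile)

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise InvalidInputError(f"unknown lesion class: {self.lesion_class!r}")
        if self.true_volume_mm3_at_t0 <= 0:
            raise InvalidInputError("lesion V0 must be positive")
        if self.true_vdt_days == 0:
            raise InvalidInputError("VDT cannot be zero (use inf for stable)")
        if self.lesion_class.startswith("malignant") and not (
            0 < self.true_vdt_days < math.inf
        ):
            raise InvalidInputError("malignant growers need finite positive VDT")
        if self.lesion_class == "inflammatory_resolving" and self.true_vdt_days >= 0:
            raise InvalidInputError("resolving lesions need a negative (halving) VDT")

    @property
    def density(self) -> str:
        return "non_solid" if self.lesion_class == "malignant_subsolid" else "solid"


def true_volume(lesion: LesionSpec, day: float) -> Optional[float]:
    """Noise-free lesion volume on a given day; None before onset.

    V(t) = V0 * 2^((t - t0) / VDT); stable lesions keep V0; a negative VDT
    halves the volume every |VDT| days, bottoming out at zero detectability.
    """
    if day < lesion.onset_day:
        return None
    dt = day - lesion.onset_day
    if math.isinf(lesion.true_vdt_days):
        return lesion.true_volume_mm3_at_t0
    return lesion.true_volume_mm3_at_t0 * 2.0 ** (dt / lesion.true_vdt_days)


def true_core_volume(lesion: LesionSpec, day: float) -> Optional[float]:
    """Volume of the solid core of a subsolid lesion; None before it exists."""
    if lesion.core_onset_day is None or day < lesion.core_onset_day:
        return None
    dt = day - lesion.core_onset_day
    return lesion.core_volume_mm3_at_onset * 2.0 ** (dt / lesion.core_vdt_days)


@dataclass(frozen=True)
class MeasurementErrorModel:
    """Parameters of volumetric and manual-diameter measurement noise.

    The 95% interval of the multiplicative (lognormal) volumetric error is
    ``+/-volumetric_ci95_complete`` for completely segmented nodules and
    ``+/-volumetric_ci95_incomplete`` otherwise; manual diameters get
    additive Gaussian noise with single-measurement SD = LoA95 / (1.96 * sqrt 2)
    so the difference of two reads reproduces the stated limits of agreement.
    """

    volumetric_ci95_complete: float = 0.12
    volumetric_ci95_incomplete: float = 0.30
    p_incomplete_segmentation: float = 0.10
    diameter_loa95_intra_mm: float = 1.4
    diameter_loa95_inter_mm: float = 1.7
    p_volumetry_failure: float = 0.05

    def __post_init__(self) -> None:
        if self.volumetric_ci95_complete < 0 or self.volumetric_ci95_incomplete < 0:
            raise InvalidInputError("CIs must be nonnegative")
        for p in (self.p_incomplete_segmentation, self.p_volumetry_failure):
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError("probabilities must lie in [0, 1]")

    def sigma_log(self, complete: bool) -> float:
        ci = self.volumetric_ci95_complete if complete else self.volumetric_ci95_incomplete
        return math.log1p(ci) / 1.96

    def diameter_sd_mm(self, inter_observer: bool = False) -> float:
        loa = self.diameter_loa95_inter_mm if inter_observer else self.diameter_loa95_intra_mm
        return loa / (1.96 * math.sqrt(2.0))


#: Convenience model with all noise sources switched off.
NOISE_FREE = MeasurementErrorModel(
    volumetric_ci95_complete=0.0,
    volumetric_ci95_incomplete=0.0,
    p_incomplete_segmentation=0.0,
    diameter_loa95_intra_mm=0.0,
    diameter_loa95_inter_mm=0.0,
    p_volumetry_failure=0.0,
)


def measure(
    true_volume_mm3: float,
    model: MeasurementErrorModel,
    rng: np.random.Generator,
    *,
    force_failure: Optional[bool] = None,
) -> SizeMeasurement:
    """Simulate one software/manual measurement of a lesion volume.

    With probability ``p_volumetry_failure`` segmentation fails entirely and
    only a manual mean diameter (additive Gaussian noise, intra-observer LoA)
    is returned; otherwise the measured volume is lognormal-multiplicative
    around truth with the complete- or incomplete-segmentation 95% interval.
    """
    if true_volume_mm3 < 0:
        raise InvalidInputError("negative true volume")
    failed = (
        force_failure
        if force_failure is not None
        else bool(rng.random() < model.p_volumetry_failure)
    )
    if failed:
        d_true = effective_diameter(true_volume_mm3)
        sd = model.diameter_sd_mm()
        d_meas = d_true if sd == 0 else d_true + rng.normal(0.0, sd)
        return SizeMeasurement(
            mean_diameter_mm=max(0.0, d_meas), measured_manually=True
        )
    complete = bool(rng.random() >= model.p_incomplete_segmentation)
    sigma = model.sigma_log(complete)
    factor = 1.0 if sigma == 0 else math.exp(rng.normal(0.0, sigma))
    return SizeMeasurement(
        volume_mm3=true_volume_mm3 * factor,
        segmentation_complete=complete,
        measured_manually=False,
    )


def measure_diameter_manual(
    true_diameter_mm: float,
    model: MeasurementErrorModel,
    rng: np.random.Generator,
    *,
    inter_observer: bool = False,
) -> float:
    """One manual calliper read of a diameter (used for solid components)."""
    sd = model.diameter_sd_mm(inter_observer=inter_observer)
    if sd == 0:
        return true_diameter_mm
    return max(0.0, true_diameter_mm + rng.normal(0.0, sd))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Default lesion-class mixture among participants who have a lesion.
#: Plausible for a high-risk screening population; not literature-calibrated.
DEFAULT_MIXTURE = {
    "benign_stable": 0.50,
    "ipln": 0.20,
    "benign_slow_growing": 0.10,
    "inflammatory_resolving": 0.10,
    "malignant_solid": 0.07,
    "malignant_subsolid": 0.03,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    ``p_lesion`` is the probability that a participant carries any lesion;
    carriers receive one lesion drawn from ``mixture``.  Scans happen at
    baseline plus ``n_rounds`` annual rounds (the programme engine adds
    classifier-driven interim scans when run in closed loop).
    """

    n_participants: int = 100
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    p_lesion: float = 0.4
    p_incident_lesion: float = 0.02
    n_rounds: int = 3
    round_interval_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidInputError("need at least one participant")
        if not 0.0 <= self.p_lesion <= 1.0 or not 0.0 <= self.p_incident_lesion <= 1.0:
            raise InvalidInputError("probabilities must lie in [0, 1]")
        total = sum(self.mixture.values())
        if self.mixture and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise InvalidInputError(f"mixture must sum to 1, got {total}")
        unknown = set(self.mixture) - set(LESION_CLASSES)
        if unknown:
            raise InvalidInputError(f"unknown lesion classes in mixture: {unknown}")


# per-class morphology flag probabilities (field-plausible defaults)
_MORPH_PROBS = {
    "malignant_solid": {"spiculation": 0.40, "pleural_tag": 0.15, "concave_sign": 0.10},
    "malignant_subsolid": {"bubble_like_lucencies": 0.25, "concave_sign": 0.15},
    "benign_stable": {},
    "benign_slow_growing": {},
    "inflammatory_resolving": {},
    "ipln": {},
}
_CALCIFICATION_P = {"benign_stable": 0.25, "benign_slow_growing": 0.15}


def _draw_morphology(cls: str, rng: np.random.Generator) -> MorphologyProfile:
    kwargs: dict = {}
    for flagname, p in _MORPH_PROBS[cls].items():
        if rng.random() < p:
            kwargs[flagname] = True
    if rng.random() < _CALCIFICATION_P.get(cls, 0.0):
        kwargs["calcification_pattern"] = str(
            rng.choice(["central", "diffuse", "popcorn"])
        )
    if cls == "ipln":
        kwargs.update(
            margin="smooth",
            shape=str(rng.choice(["oval", "lentiform", "triangular"])),
            distance_to_pleura_mm=float(rng.uniform(0.0, 9.0)),
            below_carina=bool(rng.random() < 0.9),
        )
    else:
        kwargs.setdefault("margin", str(rng.choice(["smooth", "lobulated"])))
        kwargs.setdefault("shape", str(rng.choice(["round", "oval", "irregular"])))
    return MorphologyProfile(**kwargs)


def draw_lesion(cls: str, rng: np.random.Generator, onset_day: int = 0) -> LesionSpec:
    """Draw one lesion's natural-history parameters for a class.

    Malignant VDTs are lognormal with median 180 d (solid) and slower for the
    cores of subsolid cancers; benign slow growers and IPLNs draw VDTs in the
    slow-malignant range — IPLNs deliberately so, since lymph nodes can grow
    at malignant-like rates and must be caught by morphology, not volumetry.
    """
    if cls == "malignant_solid":
        v0 = float(np.exp(rng.normal(np.log(150.0), 0.8)))
        vdt = float(np.exp(rng.normal(np.log(180.0), 0.4)))
        return LesionSpec(cls, v0, vdt, onset_day, morphology=_draw_morphology(cls, rng))
    if cls == "malignant_subsolid":
        v0 = float(np.exp(rng.normal(np.log(2000.0), 0.5)))
        vdt = float(np.exp(rng.normal(np.log(700.0), 0.3)))
        core_onset = onset_day + int(rng.integers(200, 700))
        core_vdt = float(np.exp(rng.normal(np.log(250.0), 0.3)))
        return LesionSpec(
            cls, v0, vdt, onset_day,
            core_onset_day=core_onset,
            core_volume_mm3_at_onset=float(rng.uniform(20.0, 60.0)),
            core_vdt_days=core_vdt,
            morphology=_draw_morphology(cls, rng),
        )
    if cls == "benign_stable":
        v0 = float(np.exp(rng.normal(np.log(80.0), 0.9)))
        return LesionSpec(cls, v0, math.inf, onset_day, morphology=_draw_morphology(cls, rng))
    if cls == "benign_slow_growing":
        v0 = float(np.exp(rng.normal(np.log(100.0), 0.7)))
        vdt = float(np.exp(rng.normal(np.log(700.0), 0.3)))
        return LesionSpec(cls, v0, vdt, onset_day, morphology=_draw_morphology(cls, rng))
    if cls == "ipln":
        v0 = float(np.exp(rng.normal(np.log(60.0), 0.6)))
        vdt = float(np.exp(rng.normal(np.log(400.0), 0.4)))
        return LesionSpec(cls, v0, vdt, onset_day, morphology=_draw_morphology(cls, rng))
    if cls == "inflammatory_resolving":
        v0 = float(np.exp(rng.normal(np.log(200.0), 0.6)))
        halving = -float(np.exp(rng.normal(np.log(60.0), 0.3)))
        return LesionSpec(cls, v0, halving, onset_day, morphology=_draw_morphology(cls, rng))
    raise InvalidInputError(f"unknown lesion class: {cls!r}")


def lesion_observation_row(
    lesion: LesionSpec,
    day: float,
    model: MeasurementErrorModel,
    rng: np.random.Generator,
) -> Optional[dict]:
    """Measured sizes + density of one lesion on one scan day, or None when
    the lesion is absent / below the detection floor."""
    v = true_volume(lesion, day)
    if v is None or v < DETECTION_FLOOR_MM3:
        return None
    core_v = true_core_volume(lesion, day)
    density = lesion.density
    row: dict = {}
    if density == "non_solid" and core_v is not None and core_v >= DETECTION_FLOOR_MM3:
        density = "part_solid"
    whole = measure(v, model, rng)
    row["density"] = density
    row["volume_mm3"] = whole.volume_mm3
    row["mean_diameter_mm"] = whole.mean_diameter_mm
    row["segmentation_complete"] = whole.segmentation_complete
    row["measured_manually"] = whole.measured_manually
    if density == "part_solid":
        # solid components are measured manually on lung windows
        d_core = effective_diameter(core_v)
        row["solid_diameter_mm"] = measure_diameter_manual(d_core, model, rng)
        row["solid_volume_mm3"] = None
    else:
        row["solid_diameter_mm"] = None
        row["solid_volume_mm3"] = None
    return row


def _morph_row(m: MorphologyProfile) -> dict:
    return {c: getattr(m, c) for c in MORPH_COLUMNS if c != "fat_hu"}


def generate_cohort(
    spec: CohortSpec,
    error_model: Optional[MeasurementErrorModel] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (observations, ground-truth ledger) for a fixed-schedule
    cohort: baseline plus annual rounds.

    Observations has one row per nodule per scan it was visible on, in the
    table schema consumed by the programme engine; the ledger has one row
    per lesion with its true class, V0 and VDT.  Deterministic under seed.
    """
    if error_model is None:
        error_model = MeasurementErrorModel()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = sorted(spec.mixture)
    probs = np.array([spec.mixture[c] for c in classes]) if classes else None

    obs_rows: list[dict] = []
    ledger_rows: list[dict] = []
    scan_days = [r * spec.round_interval_days for r in range(spec.n_rounds + 1)]
    t0 = pd.Timestamp("2030-01-06")

    for p in range(spec.n_participants):
        pid = f"P{p:05d}"
        lesions: list[tuple[str, LesionSpec]] = []
        if classes is not None and rng.random() < spec.p_lesion:
            cls = str(rng.choice(classes, p=probs))
            lesions.append((f"{pid}-N1", draw_lesion(cls, rng)))
        # possible single incident lesion appearing between rounds
        if classes is not None and spec.n_rounds > 0 and rng.random() < spec.p_incident_lesion:
            cls = str(rng.choice(classes, p=probs))
            onset = int(rng.integers(1, spec.n_rounds * spec.round_interval_days))
            lesions.append((f"{pid}-N{len(lesions) + 1}", draw_lesion(cls, rng, onset_day=onset)))

        seen: set[str] = set()
        for nid, lesion in lesions:
            ledger_rows.append(
                {
                    "participant_id": pid,
                    "nodule_id": nid,
                    "lesion_class": lesion.lesion_class,
                    "true_volume_mm3_at_t0": lesion.true_volume_mm3_at_t0,
                    "true_vdt_days": lesion.true_vdt_days,
                    "onset_day": lesion.onset_day,
                    "core_onset_day": lesion.core_onset_day,
                }
            )
        for day in scan_days:
            for nid, lesion in lesions:
                row = lesion_observation_row(lesion, day, error_model, rng)
                if row is None:
                    continue
                if nid not in seen:
                    # incident if first visible after the baseline scan
                    registration = "prevalent" if day == 0 else "new"
                    seen.add(nid)
                else:
                    registration = "prevalent"
                obs_rows.append(
                    {
                        "participant_id": pid,
                        "scan_date": (t0 + pd.Timedelta(days=day)).date().isoformat(),
                        "nodule_id": nid,
                        "registration": registration,
                        **row,
                        **_morph_row(lesion.morphology),
                    }
                )

    obs = pd.DataFrame(obs_rows, columns=list(OBSERVATION_COLUMNS))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "participant_id", "nodule_id", "lesion_class",
            "true_volume_mm3_at_t0", "true_vdt_days", "onset_day", "core_onset_day",
        ],
    )
    return obs, ledger
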