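"""The decision core: map a nodule observation (baseline) or history
(follow-up / new nodule) to a management decision.

Three risk categories drive the screening schedule:

* **negative** — return to the annual round (``repeat_12m``);
* **indeterminate** — early recheck (``repeat_6m`` / ``repeat_3m``);
* **positive** — ``repeat_1m`` (part-solid with a large solid component),
  ``workup``, or referral to the multidisciplinary team (``mdt``).

Sizing is by the solid compartment: the whole nodule for solid nodules, the
solid component for part-solid nodules, the whole-nodule diameter for
non-solid (pure ground-glass) nodules.  Volume bins (100 / 250 / 500 mm^3)
govern whenever volumetry succeeded; the printed diameter bins
(6 / 8 / 10 mm) are the fallback when it failed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .growth import (
    GrowthAssessment,
    InvalidInputError,
    SizeMeasurement,
    assess_growth,
    diameter_growth_threshold_mm,
)
from .morphology import (
    IPLN_CRITERIA,
    IplnCriteria,
    MorphologyProfile,
    MorphologyVerdict,
    morphology_verdict,
)

__all__ = [
    "DENSITY_CLASSES",
    "REGISTRATION_STATES",
    "ACTIONS",
    "ACTION_INTENSITY",
    "ACTION_CATEGORY",
    "ACTION_INTERVAL_MONTHS",
    "NoduleObservation",
    "NoduleHistory",
    "ManagementDecision",
    "ClassifierConfig",
    "effective_density",
    "classify_baseline",
    "classify_new",
    "classify_followup",
    "classify",
    "participant_decision",
]

DENSITY_CLASSES = ("solid", "part_solid", "non_solid")
REGISTRATION_STATES = ("prevalent", "new", "missed_on_prior")

ACTIONS = ("repeat_12m", "repeat_6m", "repeat_3m", "repeat_1m", "workup", "mdt")

#: Total order of escalation used for monotonicity and participant-level max.
ACTION_INTENSITY = {a: i for i, a in enumerate(ACTIONS)}

ACTION_CATEGORY = {
    "repeat_12m": "negative",
    "repeat_6m": "indeterminate",
    "repeat_3m": "indeterminate",
    "repeat_1m": "positive",
    "workup": "positive",
    "mdt": "positive",
}

ACTION_INTERVAL_MONTHS = {
    "repeat_12m": 12,
    "repeat_6m": 6,
    "repeat_3m": 3,
    "repeat_1m": 1,
    "workup": None,
    "mdt": None,
}

# Solid(-component) size bins: volume thresholds in mm^3 with their printed
# diameter equivalents in mm (used only when volumetry failed).
_VOLUME_BINS_MM3 = (100.0, 250.0, 500.0)
_DIAMETER_BINS_MM = (6.0, 8.0, 10.0)

#: Solid fraction of total diameter above which a part-solid nodule is
#: managed as a solid nodule.
SOLID_FRACTION_RECLASS = 0.80

#: Non-solid nodules at or above this diameter leave the negative category.
NON_SOLID_SIZE_MM = 30.0

#: New solid(-component) nodules below this volume (diameter) are negative.
NEW_NODULE_VOLUME_MM3 = 30.0
NEW_NODULE_DIAMETER_MM = 4.0

#: Volume growth of a new nodule at its 3-month recheck that triggers workup.
NEW_NODULE_GROWTH_FRACTION = 0.15

#: Slow-growing nodules whose total diameter increased beyond this from
#: baseline are referred to the multidisciplinary team.
MDT_DELTA_DIAMETER_MM = 5.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable policy knobs; defaults reproduce the published rule set."""

    regression_volume_fraction: float = 0.25
    regression_diameter_mm: float = 2.0
    extended_suspicious_flags: bool = False
    ipln_criteria: IplnCriteria = IPLN_CRITERIA


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class NoduleObservation:
    """One nodule as measured on one scan."""

    nodule_id: str
    scan_date: _dt.date
    density: str
    whole: SizeMeasurement
    solid_component: Optional[SizeMeasurement] = None
    morphology: MorphologyProfile = field(default_factory=MorphologyProfile)
    registration: str = "prevalent"

    def __post_init__(self) -> None:
        if self.density not in DENSITY_CLASSES:
            raise InvalidInputError(f"unknown density class: {self.density!r}")
        if self.registration not in REGISTRATION_STATES:
            raise InvalidInputError(f"unknown registration: {self.registration!r}")
        if self.density == "part_solid" and self.solid_component is None:
            raise InvalidInputError("part-solid nodule requires a solid component")
        if self.density == "non_solid" and self.solid_component is not None:
            raise InvalidInputError(
                "non-solid nodule carries no solid component; the appearance "
                "of a solid core is a follow-up event (record as part_solid)"
            )


@dataclass(frozen=True)
class ManagementDecision:
    """Category + action + auditable rationale for one nodule on one scan."""

    nodule_id: str
    category: str
    action: str
    rationale: tuple[str, ...]
    effective_density: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.action not in ACTION_INTENSITY:
            raise InvalidInputError(f"unknown action: {self.action!r}")
        if ACTION_CATEGORY[self.action] != self.category:
            raise InvalidInputError(
                f"category {self.category!r} inconsistent with action {self.action!r}"
            )

    @property
    def interval_months(self) -> Optional[int]:
        return ACTION_INTERVAL_MONTHS[self.action]

    @property
    def intensity(self) -> int:
        return ACTION_INTENSITY[self.action]

    def to_dict(self) -> dict:
        return {
            "nodule_id": self.nodule_id,
            "category": self.category,
            "action": self.action,
            "interval_months": self.interval_months,
            "rationale": list(self.rationale),
            "effective_density": self.effective_density,
            "warnings": list(self.warnings),
        }


def _decision(
    nodule_id: str,
    action: str,
    rationale: Sequence[str],
    eff_density: str,
    warnings: Sequence[str] = (),
) -> ManagementDecision:
    return ManagementDecision(
        nodule_id=nodule_id,
        category=ACTION_CATEGORY[action],
        action=action,
        rationale=tuple(rationale),
        effective_density=eff_density,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class NoduleHistory:
    """Ordered observations of one registered nodule across scans."""

    observations: tuple[NoduleObservation, ...]

    def __post_init__(self) -> None:
        if not self.observations:
            raise InvalidInputError("empty nodule history")
        ids = {o.nodule_id for o in self.observations}
        if len(ids) != 1:
            raise InvalidInputError(f"inconsistent nodule ids in history: {ids}")
        dates = [o.scan_date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InvalidInputError("scan dates must be strictly increasing")

    @property
    def baseline(self) -> NoduleObservation:
        return self.observations[0]

    @property
    def current(self) -> NoduleObservation:
        return self.observations[-1]

    @property
    def previous(self) -> NoduleObservation:
        if len(self.observations) < 2:
            raise InvalidInputError("history has no prior scan")
        return self.observations[-2]

    def interval_days(self) -> int:
        return (self.current.scan_date - self.previous.scan_date).days

    def __len__(self) -> int:
        return len(self.observations)


# ---------------------------------------------------------------------------
# density and sizing helpers
# ---------------------------------------------------------------------------

def effective_density(obs: NoduleObservation) -> str:
    """Density class after the 80% rule: a part-solid nodule whose solid
    component exceeds 80% of the total diameter is managed as solid."""
    if obs.density != "part_solid":
        return obs.density
    assert obs.solid_component is not None
    try:
        solid_d = obs.solid_component.diameter_mm
        whole_d = obs.whole.diameter_mm
    except InvalidInputError as exc:
        raise InvalidInputError(
            "part-solid nodule needs whole and solid-component diameters "
            "(direct or effective)"
        ) from exc
    if whole_d <= 0:
        raise InvalidInputError("part-solid nodule with zero total diameter")
    if solid_d / whole_d > SOLID_FRACTION_RECLASS:
        return "solid"
    return "part_solid"


def _sizing_measurement(obs: NoduleObservation, eff_density: str) -> SizeMeasurement:
    """Compartment whose size drives the decision."""
    if eff_density == "part_solid":
        assert obs.solid_component is not None
        return obs.solid_component
    return obs.whole


def _volume_bin(size: SizeMeasurement) -> int:
    """Index into the solid(-component) size ladder: 0 = < 100 mm^3 (< 6 mm),
    1 = 100-<250 (6-<8 mm), 2 = 250-<500 (8-<10 mm), 3 = >= 500 (>= 10 mm).
    Volume governs when present; the printed diameter bins are the fallback."""
    if size.has_volume:
        value, edges = size.volume_mm3, _VOLUME_BINS_MM3
    else:
        value, edges = size.mean_diameter_mm, _DIAMETER_BINS_MM
    for i, edge in enumerate(edges):
        if value < edge:
            return i
    return len(edges)


def _ggo_component_diameter(obs: NoduleObservation, eff_density: str) -> Optional[float]:
    """Extent of the ground-glass component: whole-nodule diameter for
    subsolid nodules, undefined for solid ones."""
    if eff_density == "solid":
        return None
    try:
        return obs.whole.diameter_mm
    except InvalidInputError:
        return None


def _verdict(obs: NoduleObservation, eff_density: str, config: ClassifierConfig) -> MorphologyVerdict:
    return morphology_verdict(
        obs.morphology,
        eff_density,
        _sizing_measurement(obs, eff_density),
        ggo_diameter_mm=_ggo_component_diameter(obs, eff_density),
        extended_suspicious=config.extended_suspicious_flags,
        ipln_criteria=config.ipln_criteria,
    )


def _non_ggo_suspicious(verdict: MorphologyVerdict) -> bool:
    """Suspicious by a feature flag, ignoring the >= 30 mm ground-glass
    trigger (which is already encoded in the non-solid size rule)."""
    return verdict.suspicious and any(
        r != "ggo_component_ge_30mm" for r in verdict.reasons
    )


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def classify_baseline(
    obs: NoduleObservation, config: ClassifierConfig = DEFAULT_CONFIG
) -> ManagementDecision:
    """Baseline decision for a prevalent (or missed-on-prior) nodule.

    Benign morphology is negative at any size.  Otherwise solid(-component)
    size bins set the interval, with suspicious morphology upgrading one
    step on the ladder 12m -> 6m -> 3m -> workup; the 1-month recheck is the
    dedicated pathway for part-solid nodules with a solid component of at
    least 500 mm^3.
    """
    eff = effective_density(obs)
    verdict = _verdict(obs, eff, config)

    if verdict.benign:
        return _decision(
            obs.nodule_id, "repeat_12m",
            ("baseline_benign_features",) + verdict.reasons,
            eff, verdict.warnings,
        )

    if eff == "non_solid":
        try:
            d = obs.whole.diameter_mm
        except InvalidInputError as exc:
            raise InvalidInputError("non-solid nodule with no usable size") from exc
        suspicious = _non_ggo_suspicious(verdict)
        if d < NON_SOLID_SIZE_MM:
            action = "repeat_6m" if suspicious else "repeat_12m"
            rule = "baseline_non_solid_lt_30mm"
        else:
            action = "repeat_3m" if suspicious else "repeat_6m"
            rule = "baseline_non_solid_ge_30mm"
        rationale = [rule]
        if suspicious:
            rationale.append("suspicious_upgrade")
            rationale.extend(verdict.reasons)
        return _decision(obs.nodule_id, action, rationale, eff, verdict.warnings)

    size = _sizing_measurement(obs, eff)
    b = _volume_bin(size)
    rationale: list[str] = [f"baseline_solid_component_bin_{b}"]
    if verdict.suspicious:
        # printed upgrade: <100 -> 6m, 100-<250 -> 3m, >=250 -> workup
        action = ("repeat_6m", "repeat_3m", "workup", "workup")[b]
        rationale.append("suspicious_upgrade")
        rationale.extend(verdict.reasons)
    else:
        if b == 0:
            action = "repeat_12m"
        elif b == 1:
            action = "repeat_6m"
        elif b == 2:
            action = "repeat_3m"
        else:
            action = "repeat_1m" if eff == "part_solid" else "workup"
    return _decision(obs.nodule_id, action, rationale, eff, verdict.warnings)


# ---------------------------------------------------------------------------
# new nodules
# ---------------------------------------------------------------------------

def classify_new(
    obs: NoduleObservation,
    followup_of_new: Optional[GrowthAssessment] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ManagementDecision:
    """Decision for an incident (new) nodule, or for its 3-month recheck.

    Nodules that were merely missed on earlier scans follow the baseline
    rules.  Truly new solid(-component) nodules of at least 30 mm^3 (4 mm)
    are rechecked at 3 months; at that recheck, volume growth above 15% or
    diameter growth above 1.5 mm sends the nodule to workup, anything less
    de-escalates it into the prevalent-nodule pathway.
    """
    if obs.registration == "missed_on_prior":
        dec = classify_baseline(obs, config)
        return _decision(
            obs.nodule_id, dec.action,
            ("missed_nodule_managed_as_baseline",) + dec.rationale,
            dec.effective_density, dec.warnings,
        )
    if obs.registration != "new" and followup_of_new is None:
        raise InvalidInputError(
            f"classify_new requires a new/missed nodule, got {obs.registration!r}"
        )

    eff = effective_density(obs)
    verdict = _verdict(obs, eff, config)

    if followup_of_new is not None:
        gf = followup_of_new.volume_growth_fraction
        grew_volume = gf is not None and gf > NEW_NODULE_GROWTH_FRACTION
        # diameter criterion is the volumetry-failed fallback
        grew_diameter = gf is None and (
            followup_of_new.delta_diameter_mm > diameter_growth_threshold_mm(
                followup_of_new.interval_days
            )
        )
        if grew_volume or grew_diameter:
            rationale = ["new_nodule_recheck_growth"]
            if grew_volume:
                rationale.append("volume_growth_gt_15pct")
            if grew_diameter:
                rationale.append("diameter_growth_gt_1p5mm")
            return _decision(obs.nodule_id, "workup", rationale, eff, verdict.warnings)
        dec = classify_baseline(obs, config)
        return _decision(
            obs.nodule_id, dec.action,
            ("new_nodule_recheck_stable_deescalated",) + dec.rationale,
            dec.effective_density, dec.warnings,
        )

    if verdict.benign:
        return _decision(
            obs.nodule_id, "repeat_12m",
            ("new_nodule_benign_features",) + verdict.reasons,
            eff, verdict.warnings,
        )
    if eff == "non_solid":
        return _decision(
            obs.nodule_id, "repeat_12m", ("new_non_solid_any_size",), eff,
            verdict.warnings,
        )

    size = _sizing_measurement(obs, eff)
    if size.has_volume:
        small = size.volume_mm3 < NEW_NODULE_VOLUME_MM3
    else:
        small = size.mean_diameter_mm < NEW_NODULE_DIAMETER_MM
    if small:
        return _decision(
            obs.nodule_id, "repeat_12m",
            ("new_solid_component_lt_30mm3",), eff, verdict.warnings,
        )
    return _decision(
        obs.nodule_id, "repeat_3m",
        ("new_solid_component_ge_30mm3",), eff, verdict.warnings,
    )


# ---------------------------------------------------------------------------
# follow-up
# ---------------------------------------------------------------------------

def _solid_component_ge_500(obs: NoduleObservation) -> bool:
    if obs.density != "part_solid" or obs.solid_component is None:
        return False
    sc = obs.solid_component
    if sc.has_volume:
        return sc.volume_mm3 >= _VOLUME_BINS_MM3[-1]
    return sc.mean_diameter_mm >= _DIAMETER_BINS_MM[-1]


def classify_followup(
    hist: NoduleHistory, config: ClassifierConfig = DEFAULT_CONFIG
) -> ManagementDecision:
    """Follow-up decision for a prevalent nodule with at least two scans.

    Priority: MDT triggers (persistent large solid component of a part-solid
    nodule, total diameter growth > 5 mm of a slow-growing solid nodule,
    development of a solid core in a non-solid nodule) > workup (substantial
    growth by VDT, diameter fallback, or new suspicious morphology) >
    indeterminate continuation > negative (regression or growth above the
    VDT cutoff with a stable diameter).
    """
    if len(hist) < 2:
        raise InvalidInputError("follow-up classification needs >= 2 observations")

    curr, prev, base = hist.current, hist.previous, hist.baseline
    interval = hist.interval_days()
    eff = effective_density(curr)
    verdict = _verdict(curr, eff, config)

    prev_flags = set(prev.morphology.suspicious_flags_set(
        extended=config.extended_suspicious_flags))
    curr_flags = set(curr.morphology.suspicious_flags_set(
        extended=config.extended_suspicious_flags))
    new_flags = tuple(sorted(curr_flags - prev_flags))

    prev_eff = effective_density(prev)
    base_eff = effective_density(base)

    def growth_sizes(o: NoduleObservation, e: str) -> SizeMeasurement:
        return _sizing_measurement(o, e)

    growth = assess_growth(
        growth_sizes(prev, prev_eff),
        growth_sizes(curr, eff),
        interval,
        baseline=growth_sizes(base, base_eff),
        new_suspicious_morphology=bool(new_flags),
        regression_volume_fraction=config.regression_volume_fraction,
        regression_diameter_mm=config.regression_diameter_mm,
    )

    if verdict.benign:
        return _decision(
            curr.nodule_id, "repeat_12m",
            ("followup_benign_features",) + verdict.reasons,
            eff, verdict.warnings,
        )

    # --- MDT triggers ------------------------------------------------------
    if base_eff == "non_solid" and eff in {"part_solid", "solid"}:
        return _decision(
            curr.nodule_id, "mdt",
            ("non_solid_developed_solid_core",), eff, verdict.warnings,
        )
    if _solid_component_ge_500(prev) and _solid_component_ge_500(curr):
        return _decision(
            curr.nodule_id, "mdt",
            ("part_solid_persistent_solid_component_ge_500mm3",),
            eff, verdict.warnings,
        )
    slow_growing = not growth.substantial_growth
    try:
        total_delta_d = curr.whole.diameter_mm - base.whole.diameter_mm
    except InvalidInputError:
        total_delta_d = growth.delta_diameter_from_baseline_mm
    if (
        eff == "solid"
        and slow_growing
        and total_delta_d > MDT_DELTA_DIAMETER_MM
    ):
        return _decision(
            curr.nodule_id, "mdt",
            ("slow_growing_total_diameter_gt_5mm_from_baseline",),
            eff, verdict.warnings,
        )

    # --- non-solid size rules (the VDT workup row applies to solid
    # components only; a pure ground-glass nodule escalates through its size
    # category, a suspicious upgrade, or the solid-core MDT trigger) --------
    if eff == "non_solid":
        try:
            d = curr.whole.diameter_mm
        except InvalidInputError as exc:
            raise InvalidInputError("non-solid nodule with no usable size") from exc
        suspicious = _non_ggo_suspicious(verdict)
        if d >= NON_SOLID_SIZE_MM:
            action = "repeat_3m" if suspicious else "repeat_6m"
            rule = "followup_non_solid_ge_30mm"
        else:
            action = "repeat_6m" if suspicious else "repeat_12m"
            rule = "followup_non_solid_lt_30mm"
        rationale = [rule]
        if suspicious:
            rationale.append("suspicious_upgrade")
            rationale.extend(verdict.reasons)
        if growth.regression:
            rationale.append("regression")
        return _decision(curr.nodule_id, action, rationale, eff, verdict.warnings)

    # --- workup ------------------------------------------------------------
    if growth.substantial_growth:
        rationale = ["followup_substantial_growth"] + list(growth.notes)
        if new_flags:
            rationale.extend(f"new_suspicious_flag_{f}" for f in new_flags)
        return _decision(curr.nodule_id, "workup", rationale, eff, verdict.warnings)

    # --- part-solid 1-month pathway: component resolved or shrank ----------
    if _solid_component_ge_500(prev) and not _solid_component_ge_500(curr):
        dec = classify_baseline(curr, config)
        return _decision(
            curr.nodule_id, dec.action,
            ("part_solid_component_below_500mm3_rebaselined",) + dec.rationale,
            dec.effective_density, dec.warnings,
        )

    # --- indeterminate continuation / negative -----------------------------
    if growth.regression:
        return _decision(
            curr.nodule_id, "repeat_12m",
            ("followup_regression",) + growth.notes, eff, verdict.warnings,
        )
    if interval <= 135:
        # 3-month recheck: VDT >= 250 d and diameter increase <= 1.5 mm
        return _decision(
            curr.nodule_id, "repeat_6m",
            (f"recheck_3m_vdt_ge_250d_interval_{interval}d",),
            eff, verdict.warnings,
        )
    return _decision(
        curr.nodule_id, "repeat_12m",
        (f"followup_no_substantial_growth_interval_{interval}d",),
        eff, verdict.warnings,
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def classify(
    hist: NoduleHistory | NoduleObservation,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ManagementDecision:
    """Route a nodule to the applicable sub-classifier.

    Single observation: baseline rules (prevalent / missed) or new-nodule
    rules.  Two observations of a new nodule: the dedicated 3-month recheck.
    Anything longer: the prevalent follow-up rules.
    """
    if isinstance(hist, NoduleObservation):
        hist = NoduleHistory((hist,))
    first = hist.observations[0]
    if len(hist) == 1:
        if first.registration in {"new", "missed_on_prior"}:
            return classify_new(first, config=config)
        return classify_baseline(first, config)
    if first.registration == "new" and len(hist) == 2:
        curr, prev = hist.current, hist.previous
        eff_prev = effective_density(prev)
        eff_curr = effective_density(curr)
        growth = assess_growth(
            _sizing_measurement(prev, eff_prev),
            _sizing_measurement(curr, eff_curr),
            hist.interval_days(),
            regression_volume_fraction=config.regression_volume_fraction,
            regression_diameter_mm=config.regression_diameter_mm,
        )
        return classify_new(curr, followup_of_new=growth, config=config)
    return classify_followup(hist, config)


def participant_decision(
    decisions: Sequence[ManagementDecision],
) -> Optional[ManagementDecision]:
    """Participant-level recommendation: the maximum action intensity across
    the participant's nodules (reported with the driving nodule id); None
    for a nodule-free scan (negative, annual)."""
    if not decisions:
        return None
    return max(decisions, key=lambda d: d.intensity)
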