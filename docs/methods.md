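# Methods

This note records the modelling choices behind `lungscreen`: what the rule
engine implements, where the published recommendation leaves gaps and how
those gaps were closed, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## The decision model

The engine maps each nodule observation (baseline) or observation history
(follow-up, new nodule) to one of three categories — negative,
indeterminate, positive — and a concrete action (`repeat_12m`, `repeat_6m`,
`repeat_3m`, `repeat_1m`, `workup`, `mdt`).  Category and action are kept
mutually consistent by construction, and actions carry a total escalation
order used for participant-level aggregation (the maximum across a
participant's nodules, reported with the driving nodule id).

**Sizing.**  The managed compartment is the whole nodule for solid nodules,
the solid component for part-solid nodules, and the whole-nodule diameter
for non-solid nodules.  Volume bins (100 / 250 / 500 mm³ at baseline,
30 mm³ for new nodules) govern whenever volumetry succeeded; the printed
diameter equivalents (6 / 8 / 10 mm, 4 mm) are used only as the
volumetry-failure fallback.  The printed mm labels are rounded
approximations of the mm³ thresholds (a 100 mm³ sphere is 5.76 mm, not
6 mm), so decisions computed from a volume and from its effective diameter
can differ inside a ±0.3 mm band around bin edges; volume governs there.

**The 80% rule.**  A part-solid nodule whose solid-component diameter
exceeds 80% of the total diameter is reclassified and managed as solid.
Diameters for this ratio are manual where available, otherwise effective
diameters from volumes.

**Morphology.**  Suspicious features upgrade the neutral decision exactly
one rung on the ladder 12m → 6m → 3m → workup.  The 1-month action is not a
rung on that ladder: it is the dedicated pathway for part-solid nodules
with a neutral-morphology solid component ≥ 500 mm³, and the printed table
sends suspicious solid(-component) nodules ≥ 250 mm³ directly to workup.
Benign features dominate: any size goes back to annual screening, and when
benign and suspicious features coexist the verdict is benign with a warning
recorded in the decision trace (the published table's "benign features /
any size" row is unconditional; the conflict is surfaced rather than
silently resolved).

The ground-glass ≥ 30 mm suspicious trigger is not stacked on top of the
non-solid ≥ 30 mm size rule — the size rule already encodes that feature —
so a plain 35 mm ground-glass nodule is indeterminate (6 months), not
pushed further.  An `air_bronchogram` flag is accepted as input but treated
as suspicious only through an opt-in extension set, since the core rule
set does not list it.

**Intrapulmonary lymph nodes.**  The screening criteria (smooth margin;
oval, lentiform or triangular shape; diameter and pleural distance strictly
< 10 mm; below the carina) are the default; a literature-derived wider set
(≤ 12 mm, ≤ 15 mm, round/oval/polygonal) is available as a configurable
alternative.  Absent geometry fields fail the test — a nodule is never
called a lymph node on missing information.

**Growth.**  VDT = Δt·ln 2 / ln(V₂/V₁) under the standard
exponential-growth model (the recommendation uses VDT without printing the
formula).  A non-growing or shrinking nodule gets VDT = +∞ so that
"VDT ≥ cutoff" comparisons hold naturally.  The interval-dependent cutoffs
(250 / 400 / 500 days at the 3 / 6 / ≥ 12-month visits) are binned by
elapsed days at the midpoints between the nominal 90 / 180 / 365-day
visits: ≤ 135 d → 250, 136–270 d → 400, > 270 d → 500.  The
volumetry-failure fallback threshold of > 1.5 mm diameter increase is fixed
per comparison for intervals up to a year and pro-rated (1.5 mm ×
interval/365) beyond, preserving the per-year reading for gap years; the
interval is recorded in the rationale trace.

**Regression** ("complete disappearance or marked decrease") is quantified
as disappearance, a ≥ 25% volume decrease, or a ≥ 2 mm diameter decrease;
the 25% is a configurable parameter because "marked" is not quantified in
the source.  Substantial growth and regression are mutually exclusive; in
the only reachable conflict (a new suspicious feature on a shrinking
nodule) the morphology-driven growth trigger wins and the conflict is
noted.

**Follow-up priority** is MDT triggers, then workup, then indeterminate
continuation, then negative.  MDT triggers: a persistent ≥ 500 mm³
(≥ 10 mm) solid component of a part-solid nodule on consecutive scans; a
solid nodule not meeting the VDT workup cutoff whose *total* diameter has
drifted > 5 mm beyond the original baseline; the appearance of a solid core
in a previously non-solid nodule.  A part-solid component that drops back
below 500 mm³ at its 1-month recheck is re-baselined on current size.
Non-solid nodules escalate only through their size category (≥ 30 mm →
6-month recheck, persisting as long as the size persists), a suspicious
upgrade, or the solid-core MDT trigger — the VDT workup row applies to
solid components only.  A newly appearing suspicious feature at any
follow-up counts as substantial growth ("substantial change in
morphology").

**New nodules** of ≥ 30 mm³ go to a 3-month recheck; > 15% volume growth
(evaluated through the implied VDT) or, when volumetry failed, > 1.5 mm
diameter growth means workup, anything less de-escalates the nodule into
the prevalent pathway at its current size.  Nodules recorded as missed on
prior scans follow the baseline rules directly.  Nodules referred for
workup or MDT exit the screening schedule ("handed to the clinical
pathway") and are not rescheduled.

## The synthetic cohort simulator

The simulator exists to exercise the engine end-to-end against known
ground truth; it is not a calibrated epidemiological model.

**Natural history.**  Lesion volumes follow V(t) = V₀·2^((t−t₀)/VDT).  The
VDT is signed: positive for growers, +∞ for stable lesions, negative (a
halving time) for resolving inflammatory lesions.  Subsolid cancers start
as pure ground-glass lesions and may grow a solid core (its own V₀ and
VDT) from a per-lesion onset day.  Six lesion classes are provided:
malignant solid, malignant subsolid, stable benign, slow-growing benign,
intrapulmonary lymph node, and resolving inflammatory.  IPLNs are
deliberately given finite VDTs in the slow-malignant range — lymph nodes
can grow at malignant-like rates, which creates exactly the failure mode
(volumetry misleads) that the morphology gate must catch.

**Measurement noise.**  Volumetric error is multiplicative lognormal
(guaranteeing positivity, symmetric on the log scale; the source states
only 95% intervals, not a distribution), with σ_log = ln(1 + CI)/1.96 so
the upper 97.5% quantile of the measured/true ratio equals the configured
interval (+12% for complete segmentation, +30% for incomplete; the lower
tail is then −10.7% / −23%, keeping the whole empirical interval inside the
configured ± band).  With probability `p_volumetry_failure` segmentation
fails and only a manual diameter is returned, carrying additive Gaussian
noise with single-measurement SD = LoA95/(1.96·√2), so the difference of
two reads reproduces the stated 95% limits of agreement (±1.4 mm
intra-observer, ±1.7 mm inter-observer).  Solid components of part-solid
lesions are always measured manually, mirroring practice.

**Defaults that are choices, not estimates.**  The class mixture (50%
stable benign, 20% IPLN, 10% slow benign, 10% resolving, 7% malignant
solid, 3% malignant subsolid among lesion carriers), the 40% lesion
prevalence, and the VDT distributions (e.g. malignant solid VDT lognormal
with median 180 d) are field-plausible configuration defaults, explicitly
NOT literature-calibrated; real screening prevalences and the published
population fractions (≈ 80–85% negative) are population-dependent and are
not validated by this package.  A detection floor of 15 mm³ (≈ 3 mm)
hides lesions below LDCT visibility.

**What passing tests show.**  Simulated cohorts have exponential-growth
lesions, per-scan-independent noise and fully observed linkage, so green
tests demonstrate that the rules are implemented as printed and behave
sanely under the stated noise model — not that the recommendation performs
equivalently on real populations, real segmentation software, or real
reader variability.

## Programme execution

Date arithmetic is in days; the 1 / 3 / 6 / 12-month intervals map to
30 / 91 / 182 / 365-day nominal offsets when the closed-loop simulator
schedules scans.  Replay mode processes an existing table in scan-date
order and labels a scan interim when it follows the previous scan by
clearly less than a year, checking that some prior decision justified it
(violations are logged, not fatal).  Stopping is by configured annual
rounds (default horizon: the cohort's round count, capped by `max_rounds`
= 5).  Participants with no observation rows never appear in replay
output; the closed-loop simulator reports all participants, including the
nodule-free.

## Numerical conventions and edge cases

* Effective diameter (6V/π)^⅓ and its inverse πd³/6 round-trip to
  ~1e−15 relative error; 0 maps to 0.
* Nodule mass = V·(HU + 1000)/1000 mg (linear CT-number-to-density with
  water 1 mg/mm³ at 0 HU, air 0 at −1000 HU); informational only, never
  consumed by the classifier.
* All inequalities are exactly as printed: strict VDT < cutoff, strict
  > 1.5 mm, half-open size bins [low, high).
* A volume of exactly 0 at follow-up is disappearance (regression); a
  nodule appearing from measured 0 has undefined VDT and falls back to the
  diameter criterion.
* Absent boolean morphology flags are false; absent `segmentation_complete`
  with a volume present means complete.
* Table validation reports 1-based spreadsheet row numbers (header = row 1).

## Problem sizes

The test suite runs exhaustive rule-grid checks (~600 boundary cases),
truth-table morphology checks (2⁸ × 4 combinations), 10⁴-draw noise
calibrations and a 1000-grower VDT-recovery study; the acceptance script
repeats these and simulates a 400-participant, 3-round programme.  These
sizes give Monte-Carlo error comfortably below the asserted tolerances
while keeping the whole suite in a few seconds.

## Known limitations

* The engine consumes measurements; segmentation, volumetry and feature
  extraction are upstream and out of scope, as are model-based risk
  calculators and rule sets from other guidelines.
* The ±12% / ±30% volumetric-variability figures come from a small study
  with older segmentation software; they are configuration defaults, not
  constants.
* Whether "infection" as a benign feature should instead trigger a short
  1–3-month recheck (as some guidelines do) is an open question in the
  source; the engine follows the printed table (annual).
* Multi-nodule interactions beyond maximum-intensity aggregation (e.g.
  nodule-count-based risk) are not modelled.
* The simulator does not model reader disagreement on morphology flags,
  scanner/kernel effects on volumetry, or survival outcomes.
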