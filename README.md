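# lungscreen

A decision engine for pulmonary nodule management in low-dose CT (LDCT) lung
cancer screening, implementing the European (ESTI) nodule-management
recommendation as tested, reusable code: per-nodule growth metrics,
morphology assessment, baseline / follow-up / new-nodule classification,
longitudinal screening-programme execution, and a synthetic-cohort simulator
with calibrated measurement noise.

It is written for screening-programme engineers, guideline modellers and
imaging researchers who need the management rules as an executable,
auditable artifact — every decision carries a rationale trace — rather than
as a flowchart on paper.

## The rules in brief

Each screen-detected nodule is assigned one of three risk categories,
**negative** (annual screening), **indeterminate** (repeat LDCT at 3 or 6
months) or **positive** (1-month recheck, diagnostic workup, or referral to
the multidisciplinary team, MDT), from:

* **density class** — solid, part-solid, non-solid (pure ground-glass).  A
  part-solid nodule whose solid component exceeds 80% of the total diameter
  is managed as solid.
* **solid(-component) size** — volume bins 100 / 250 / 500 mm³, with the
  printed diameter bins 6 / 8 / 10 mm as fallback when volumetry fails.
  Volumes convert to the *effective diameter* d = (6V/π)^⅓ of the
  equal-volume sphere; note that a volume doubling moves the diameter by
  only 100·(2^⅓ − 1) ≈ 26%, which is why volumetry is preferred.
* **morphology** — suspicious features (spiculation, pleural tag, fissural
  displacement, cystic component, bubble-like lucencies, concave sign,
  narrowed vessels, bronchus cut-off, ground-glass component ≥ 3 cm)
  upgrade the category one step; benign features (central/diffuse/popcorn
  calcification, fat attenuation, typical intrapulmonary lymph node,
  infection) send the nodule back to annual screening at any size.
* **growth** at follow-up — the volume doubling time under exponential
  growth, VDT = Δt·ln 2 / ln(V₂/V₁), against interval-dependent cutoffs
  (< 250 d at 3 months, < 400 d at 6 months, < 500 d at ≥ 12 months), with
  a > 1.5 mm diameter increase as the volumetry-failure fallback; a
  slow-growing solid nodule whose total diameter drifts > 5 mm beyond
  baseline, a persistent ≥ 500 mm³ solid component, or a solid core
  appearing in a ground-glass nodule goes to the MDT.

New nodules of ≥ 30 mm³ (≥ 4 mm) are rechecked at 3 months, where > 15%
volume growth (or > 1.5 mm diameter growth) means workup.

## Worked example

```python
import datetime as dt, json
from lungscreen import (SizeMeasurement, MorphologyProfile, NoduleObservation,
                        NoduleHistory, classify)

baseline = NoduleObservation(
    nodule_id="N1", scan_date=dt.date(2030, 1, 6), density="solid",
    whole=SizeMeasurement(volume_mm3=180.0),
    morphology=MorphologyProfile(spiculation=True),
)
print(json.dumps(classify(baseline).to_dict(), indent=2))
```

```json
{
  "nodule_id": "N1",
  "category": "indeterminate",
  "action": "repeat_3m",
  "interval_months": 3,
  "rationale": [
    "baseline_solid_component_bin_1",
    "suspicious_upgrade",
    "spiculation"
  ],
  "effective_density": "solid",
  "warnings": []
}
```

A 180 mm³ solid nodule sits in the 100–250 mm³ bin (6-month recheck), and
the spiculation upgrades it one step to 3 months.  At that recheck the
nodule has grown to 290 mm³ in 91 days — VDT 132 days, far below the
250-day cutoff — so the decision escalates:

```python
followup = NoduleObservation(
    nodule_id="N1", scan_date=dt.date(2030, 4, 7), density="solid",
    whole=SizeMeasurement(volume_mm3=290.0),
)
print(json.dumps(classify(NoduleHistory((baseline, followup))).to_dict(), indent=2))
```

```json
{
  "nodule_id": "N1",
  "category": "positive",
  "action": "workup",
  "interval_months": null,
  "rationale": [
    "followup_substantial_growth",
    "vdt_132d_below_250d_cutoff"
  ],
  "effective_density": "solid",
  "warnings": []
}
```

## Command line

```bash
lungscreen simulate --participants 200 --rounds 3 --seed 1 --out cohort
lungscreen validate cohort.observations.csv
lungscreen classify cohort.observations.csv --out decisions.csv
lungscreen run-program cohort.observations.csv --ledger cohort.ledger.csv --out run
lungscreen report cohort.observations.csv --participant P00000 \
    --scan-date 2030-01-06 --format text
```

`simulate` writes a measurement table plus a ground-truth lesion ledger;
`run-program` replays a table longitudinally and writes per-scan decisions
and programme metrics (interim-scan burden, category distributions,
time-to-referral for malignant growers).

## Layout

* `lungscreen.growth` — size conversions, VDT, substantial-growth /
  regression assessment, nodule mass.
* `lungscreen.morphology` — suspicious / benign / IPLN feature rules.
* `lungscreen.classifier` — the baseline / follow-up / new-nodule decision
  core.
* `lungscreen.simulate` — lesion natural histories, measurement-error
  model, cohort generation.
* `lungscreen.engine` — longitudinal replay and closed-loop programme
  simulation, programme metrics.
* `lungscreen.io`, `lungscreen.report`, `lungscreen.cli` — table schema and
  validation, structured reports, command line.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
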