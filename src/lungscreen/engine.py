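"""Longitudinal execution of a screening programme.

Two modes:

* :func:`run_programme` replays an existing measurement table (real or
  simulated) in scan-date order, maintaining a per-nodule history and
  applying the classifier at every scan;
* :func:`simulate_programme` closes the loop with the cohort simulator —
  interim scans requested by the classifier are actually acquired (with
  measurement noise) at their nominal offsets, so programme-level burden
  (interim scans, time-to-referral) can be measured against ground truth.

Nodules referred for workup or to the multidisciplinary team exit the
screening schedule ("handed to the clinical pathway") and are no longer
scheduled, though replayed observations of them are still classified.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierConfig,
    ManagementDecision,
    NoduleHistory,
    NoduleObservation,
    classify,
    participant_decision,
)
from .growth import InvalidInputError
from .io import OBSERVATION_COLUMNS, decisions_to_frame, parse_table, validate_table
from .simulate import (
    CohortSpec,
    MeasurementErrorModel,
    _morph_row,
    draw_lesion,
    lesion_observation_row,
)

__all__ = [
    "ProgrammeConfig",
    "ProgrammeRun",
    "run_programme",
    "simulate_programme",
    "programme_metrics",
]

#: Nominal day offsets for the recheck intervals.
INTERVAL_DAYS = {1: 30, 3: 91, 6: 182, 12: 365}


@dataclass(frozen=True)
class ProgrammeConfig:
    """Programme-level policy: stopping rules and classifier knobs."""

    max_rounds: int = 5
    round_interval_days: int = 365
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)


@dataclass
class ProgrammeRun:
    """Result of one programme execution.

    ``decisions`` is a tidy table with one row per (participant, scan,
    nodule); ``participant_scans`` one row per (participant, scan) with the
    overall recommendation and scan type; counters and referral times are
    derived tallies.
    """

    decisions: pd.DataFrame
    participant_scans: pd.DataFrame
    scan_counts: Counter
    time_to_referral_days: dict[str, int]
    config: ProgrammeConfig
    log: list[str] = field(default_factory=list)
    observations: Optional[pd.DataFrame] = None  # filled by simulate_programme

    @property
    def n_participants(self) -> int:
        if self.participant_scans.empty:
            return 0
        return self.participant_scans["participant_id"].nunique()


def _scan_type_for_interval(months: Optional[int]) -> str:
    return {1: "1m", 3: "3m", 6: "6m", 12: "annual"}.get(months, "annual")


def run_programme(
    observations: pd.DataFrame, config: Optional[ProgrammeConfig] = None
) -> ProgrammeRun:
    """Replay a measurement table through the classifier.

    Scans are processed in date order per participant; each nodule's history
    grows as rows arrive and is re-classified at every scan it appears on.
    A scan is labelled interim when it follows the previous scan of the same
    participant by clearly less than the annual interval; soundness (every
    interim scan justified by a prior decision) is checked and violations
    are logged rather than fatal.
    """
    if config is None:
        config = ProgrammeConfig()
    errors = validate_table(observations)
    if errors:
        raise InvalidInputError(
            "measurement table failed validation:\n" + "\n".join(errors)
        )
    parsed = parse_table(observations)

    by_participant: dict[str, list[NoduleObservation]] = defaultdict(list)
    for pid, obs in parsed:
        by_participant[pid].append(obs)

    log: list[str] = []
    dec_records: list[tuple[str, _dt.date, ManagementDecision]] = []
    scan_records: list[dict] = []
    scan_counts: Counter = Counter()
    referral_day: dict[str, int] = {}

    for pid in sorted(by_participant):
        rows = by_participant[pid]
        histories: dict[str, list[NoduleObservation]] = defaultdict(list)
        first_seen: dict[str, _dt.date] = {}
        exited: set[str] = set()
        scan_dates = sorted({o.scan_date for o in rows})
        prev_scan: Optional[_dt.date] = None
        prev_requested_months: Optional[int] = None
        for scan_date in scan_dates:
            todays = [o for o in rows if o.scan_date == scan_date]
            decisions: list[ManagementDecision] = []
            for obs in todays:
                key = obs.nodule_id
                hist_list = histories[key]
                if hist_list and hist_list[-1].scan_date >= obs.scan_date:
                    raise InvalidInputError(
                        f"nodule {key}: duplicate or unordered scan {obs.scan_date}"
                    )
                hist_list.append(obs)
                first_seen.setdefault(key, obs.scan_date)
                dec = classify(NoduleHistory(tuple(hist_list)), config.classifier)
                decisions.append(dec)
                dec_records.append((pid, scan_date, dec))
                if dec.action in {"workup", "mdt"} and key not in referral_day:
                    referral_day[key] = (scan_date - first_seen[key]).days
                if dec.action in {"workup", "mdt"} and key not in exited:
                    exited.add(key)
                    log.append(
                        f"{pid}/{key}: exited to clinical pathway on {scan_date}"
                    )
            overall = participant_decision(decisions)
            if prev_scan is None:
                scan_type = "baseline"
            else:
                gap = (scan_date - prev_scan).days
                scan_type = "annual" if gap >= 300 else _scan_type_for_interval(
                    min(
                        (m for m, d in INTERVAL_DAYS.items() if gap <= d + 45),
                        default=12,
                    )
                )
                if scan_type != "annual" and (
                    prev_requested_months is None or prev_requested_months >= 12
                ):
                    log.append(
                        f"{pid}: interim scan on {scan_date} not justified by a "
                        "prior decision"
                    )
            scan_counts[scan_type] += 1
            scan_records.append(
                {
                    "participant_id": pid,
                    "scan_date": scan_date.isoformat(),
                    "scan_type": scan_type,
                    "n_nodules": len(decisions),
                    "category": overall.category if overall else "negative",
                    "action": overall.action if overall else "repeat_12m",
                    "driving_nodule_id": overall.nodule_id if overall else None,
                }
            )
            prev_scan = scan_date
            live = [d for d in decisions if d.nodule_id not in exited]
            months = [
                d.interval_months for d in live if d.interval_months is not None
            ]
            prev_requested_months = min(months) if months else 12

    return ProgrammeRun(
        decisions=decisions_to_frame(dec_records),
        participant_scans=pd.DataFrame(
            scan_records,
            columns=[
                "participant_id", "scan_date", "scan_type", "n_nodules",
                "category", "action", "driving_nodule_id",
            ],
        ),
        scan_counts=scan_counts,
        time_to_referral_days=referral_day,
        config=config,
        log=log,
    )


def simulate_programme(
    spec: CohortSpec,
    error_model: Optional[MeasurementErrorModel] = None,
    config: Optional[ProgrammeConfig] = None,
    seed: Optional[int] = None,
) -> tuple[ProgrammeRun, pd.DataFrame]:
    """Closed-loop simulation: the classifier's requested interval drives the
    next scan date, interim scans included, until the annual horizon
    (``spec.n_rounds`` rounds) or ``config.max_rounds`` annual rounds.

    Returns the run plus the ground-truth lesion ledger.
    """
    if error_model is None:
        error_model = MeasurementErrorModel()
    if config is None:
        config = ProgrammeConfig()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = sorted(spec.mixture)
    probs = np.array([spec.mixture[c] for c in classes]) if classes else None
    t0 = pd.Timestamp("2030-01-06")
    horizon = min(spec.n_rounds, config.max_rounds) * spec.round_interval_days

    log: list[str] = []
    dec_records: list[tuple[str, _dt.date, ManagementDecision]] = []
    scan_records: list[dict] = []
    obs_rows: list[dict] = []
    scan_counts: Counter = Counter()
    referral_day: dict[str, int] = {}
    ledger_rows: list[dict] = []

    for p in range(spec.n_participants):
        pid = f"P{p:05d}"
        lesions = []
        if classes is not None and rng.random() < spec.p_lesion:
            cls = str(rng.choice(classes, p=probs))
            lesions.append((f"{pid}-N1", draw_lesion(cls, rng)))
        if classes is not None and spec.n_rounds > 0 and rng.random() < spec.p_incident_lesion:
            cls = str(rng.choice(classes, p=probs))
            onset = int(rng.integers(1, max(2, horizon)))
            lesions.append(
                (f"{pid}-N{len(lesions) + 1}", draw_lesion(cls, rng, onset_day=onset))
            )
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

        histories: dict[str, list[NoduleObservation]] = defaultdict(list)
        first_seen_day: dict[str, int] = {}
        exited: set[str] = set()
        day = 0
        scan_type = "baseline"
        while day <= horizon:
            scan_date = (t0 + pd.Timedelta(days=day)).date()
            decisions: list[ManagementDecision] = []
            for nid, lesion in lesions:
                if nid in exited:
                    continue
                row = lesion_observation_row(lesion, day, error_model, rng)
                if row is None:
                    if histories[nid]:
                        # previously seen lesion vanished: record resolution
                        log.append(f"{pid}/{nid}: resolved by day {day}")
                        exited.add(nid)
                    continue
                registration = "prevalent"
                if nid not in first_seen_day:
                    registration = "prevalent" if day == 0 else "new"
                    first_seen_day[nid] = day
                obs = NoduleObservation(
                    nodule_id=nid,
                    scan_date=scan_date,
                    density=row["density"],
                    whole=_size_from_row(row),
                    solid_component=_solid_from_row(row),
                    morphology=lesion.morphology,
                    registration=(
                        histories[nid][0].registration if histories[nid] else registration
                    ),
                )
                histories[nid].append(obs)
                obs_rows.append(
                    {
                        "participant_id": pid,
                        "scan_date": scan_date.isoformat(),
                        "nodule_id": nid,
                        "registration": registration,
                        **row,
                        **_morph_row(lesion.morphology),
                    }
                )
                dec = classify(NoduleHistory(tuple(histories[nid])), config.classifier)
                decisions.append(dec)
                dec_records.append((pid, scan_date, dec))
                if dec.action in {"workup", "mdt"}:
                    referral_day.setdefault(nid, day - first_seen_day[nid])
                    exited.add(nid)
                    log.append(f"{pid}/{nid}: exited to clinical pathway on day {day}")
            overall = participant_decision(decisions)
            scan_counts[scan_type] += 1
            scan_records.append(
                {
                    "participant_id": pid,
                    "scan_date": scan_date.isoformat(),
                    "scan_type": scan_type,
                    "n_nodules": len(decisions),
                    "category": overall.category if overall else "negative",
                    "action": overall.action if overall else "repeat_12m",
                    "driving_nodule_id": overall.nodule_id if overall else None,
                }
            )
            live = [d for d in decisions if d.nodule_id not in exited]
            months = [d.interval_months for d in live if d.interval_months is not None]
            next_months = min(months) if months else 12
            if next_months >= 12:
                # return to the annual schedule at the next round boundary
                next_day = (day // spec.round_interval_days + 1) * spec.round_interval_days
                scan_type = "annual"
            else:
                next_day = day + INTERVAL_DAYS[next_months]
                scan_type = _scan_type_for_interval(next_months)
            day = next_day

    run = ProgrammeRun(
        decisions=decisions_to_frame(dec_records),
        participant_scans=pd.DataFrame(
            scan_records,
            columns=[
                "participant_id", "scan_date", "scan_type", "n_nodules",
                "category", "action", "driving_nodule_id",
            ],
        ),
        scan_counts=scan_counts,
        time_to_referral_days=referral_day,
        config=config,
        log=log,
    )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "participant_id", "nodule_id", "lesion_class",
            "true_volume_mm3_at_t0", "true_vdt_days", "onset_day",
            "core_onset_day",
        ],
    )
    run.observations = pd.DataFrame(obs_rows, columns=list(OBSERVATION_COLUMNS))
    return run, ledger


def _size_from_row(row: dict):
    from .growth import SizeMeasurement

    return SizeMeasurement(
        volume_mm3=row.get("volume_mm3"),
        mean_diameter_mm=row.get("mean_diameter_mm"),
        segmentation_complete=row.get("segmentation_complete"),
        measured_manually=bool(row.get("measured_manually")),
    )


def _solid_from_row(row: dict):
    from .growth import SizeMeasurement

    if row.get("solid_volume_mm3") is None and row.get("solid_diameter_mm") is None:
        return None
    return SizeMeasurement(
        volume_mm3=row.get("solid_volume_mm3"),
        mean_diameter_mm=row.get("solid_diameter_mm"),
        measured_manually=row.get("solid_volume_mm3") is None,
    )


def programme_metrics(
    run: ProgrammeRun, ledger: Optional[pd.DataFrame] = None
) -> dict:
    """Programme-level summary.

    Always: scan counts by type, interim scans per 1000 participants, and the
    per-round category distribution.  With a ground-truth ledger: referral
    coverage and median time-to-referral for malignant growers, plus the
    interim-scan burden attributable to benign lesions.
    """
    n = run.n_participants
    interim = sum(
        v for k, v in run.scan_counts.items() if k not in {"baseline", "annual"}
    )
    metrics: dict = {
        "n_participants": n,
        "n_scans_total": int(sum(run.scan_counts.values())),
        "scan_counts": dict(run.scan_counts),
        "interim_scans": int(interim),
        "interim_scans_per_1000": (1000.0 * interim / n) if n else 0.0,
    }
    ps = run.participant_scans
    if not ps.empty:
        dist = (
            ps.groupby(["scan_type", "category"]).size().unstack(fill_value=0)
        )
        metrics["category_distribution_by_scan_type"] = {
            st: {c: int(v) for c, v in row.items()}
            for st, row in dist.iterrows()
        }
        base = ps[ps["scan_type"] == "baseline"]
        if len(base):
            metrics["baseline_negative_fraction"] = float(
                (base["category"] == "negative").mean()
            )
    if ledger is not None and not ledger.empty:
        mal = ledger[ledger["lesion_class"].str.startswith("malignant")]
        referred = [
            nid for nid in mal["nodule_id"] if nid in run.time_to_referral_days
        ]
        metrics["n_malignant_lesions"] = int(len(mal))
        metrics["malignant_referred_fraction"] = (
            len(referred) / len(mal) if len(mal) else float("nan")
        )
        if referred:
            metrics["median_time_to_referral_days"] = float(
                np.median([run.time_to_referral_days[nid] for nid in referred])
            )
        benign = set(
            ledger.loc[
                ~ledger["lesion_class"].str.startswith("malignant"), "nodule_id"
            ]
        )
        if not ps.empty:
            interim_rows = ps[~ps["scan_type"].isin(["baseline", "annual"])]
            metrics["interim_scans_from_benign_lesions"] = int(
                interim_rows["driving_nodule_id"].isin(benign).sum()
            )
    return metrics
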