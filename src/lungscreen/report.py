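"""Structured per-scan reports: one block per nodule with sizes, morphology,
growth metrics and the management decision, plus the overall recommendation
(the maximum action intensity across blocks).

Reports serialize deterministically to JSON (round-trip safe) or to a plain
text rendering for human readers.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .classifier import (
    ManagementDecision,
    NoduleHistory,
    effective_density,
    participant_decision,
)
from .growth import InvalidInputError, assess_growth

__all__ = ["StructuredReport", "build_report", "emit_report", "parse_report"]

_FORMATS = ("json", "text")


@dataclass(frozen=True)
class StructuredReport:
    participant_id: str
    scan_date: str  # ISO-8601
    nodules: tuple[dict, ...]
    overall_category: str
    overall_action: str
    overall_interval_months: Optional[int]

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "scan_date": self.scan_date,
            "nodules": [dict(b) for b in self.nodules],
            "overall": {
                "category": self.overall_category,
                "action": self.overall_action,
                "interval_months": self.overall_interval_months,
            },
        }


def _size_block(size) -> dict:
    if size is None:
        return {}
    return {
        "volume_mm3": size.volume_mm3,
        "mean_diameter_mm": size.mean_diameter_mm,
        "effective_or_mean_diameter_mm": round(size.diameter_mm, 2),
        "measured_manually": size.measured_manually,
    }


def _nodule_block(hist: NoduleHistory, decision: ManagementDecision) -> dict:
    curr = hist.current
    block: dict = {
        "nodule_id": curr.nodule_id,
        "density": curr.density,
        "effective_density": effective_density(curr),
        "registration": curr.registration,
        "whole": _size_block(curr.whole),
        "solid_component": _size_block(curr.solid_component),
        "morphology_flags": list(curr.morphology.suspicious_flags_set(extended=True)),
        "calcification_pattern": curr.morphology.calcification_pattern,
    }
    if len(hist) >= 2:
        interval = hist.interval_days()
        try:
            g = assess_growth(
                hist.previous.whole, curr.whole, interval, baseline=hist.baseline.whole
            )
            block["growth"] = {
                "interval_days": g.interval_days,
                "vdt_days": (
                    None if g.vdt_days is None
                    else ("inf" if g.vdt_days == float("inf") else round(g.vdt_days, 1))
                ),
                "delta_diameter_mm": round(g.delta_diameter_mm, 2),
                "delta_diameter_from_baseline_mm": round(
                    g.delta_diameter_from_baseline_mm, 2
                ),
                "substantial_growth": g.substantial_growth,
                "regression": g.regression,
            }
        except InvalidInputError:
            block["growth"] = None
    else:
        block["growth"] = None
    block["decision"] = decision.to_dict()
    return block


def build_report(
    participant_id: str,
    scan_date: _dt.date | str,
    items: Sequence[tuple[NoduleHistory, ManagementDecision]] = (),
) -> StructuredReport:
    """Assemble a structured report for one participant's scan.

    ``items`` pairs each nodule's history-to-date with its decision on this
    scan; an empty sequence yields the nodule-free report (negative, annual).
    """
    if isinstance(scan_date, _dt.date):
        scan_date = scan_date.isoformat()
    blocks = tuple(_nodule_block(h, d) for h, d in items)
    overall = participant_decision([d for _, d in items])
    if overall is None:
        category, action, interval = "negative", "repeat_12m", 12
    else:
        category, action, interval = (
            overall.category, overall.action, overall.interval_months
        )
    return StructuredReport(
        participant_id=str(participant_id),
        scan_date=scan_date,
        nodules=blocks,
        overall_category=category,
        overall_action=action,
        overall_interval_months=interval,
    )


def emit_report(report: StructuredReport, fmt: str = "json") -> str:
    """Serialize a report; deterministic for fixed input."""
    if fmt not in _FORMATS:
        raise InvalidInputError(f"unknown report format: {fmt!r}")
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    lines = [
        f"Screening report — participant {report.participant_id}, "
        f"scan {report.scan_date}",
        "-" * 64,
    ]
    if not report.nodules:
        lines.append("No pulmonary nodules.")
    for b in report.nodules:
        dec = b["decision"]
        lines.append(f"Nodule {b['nodule_id']} ({b['density']}"
                     + (f", managed as {b['effective_density']}"
                        if b["effective_density"] != b["density"] else "")
                     + ")")
        whole = b.get("whole") or {}
        if whole.get("volume_mm3") is not None:
            lines.append(f"  volume: {whole['volume_mm3']:.1f} mm3 "
                         f"(effective diameter {whole['effective_or_mean_diameter_mm']} mm)")
        elif whole.get("mean_diameter_mm") is not None:
            lines.append(f"  mean diameter: {whole['mean_diameter_mm']:.1f} mm (manual)")
        sc = b.get("solid_component") or {}
        if sc:
            lines.append(
                "  solid component: "
                f"{sc.get('volume_mm3') or sc.get('mean_diameter_mm'):.1f} "
                + ("mm3" if sc.get("volume_mm3") is not None else "mm")
            )
        if b.get("morphology_flags"):
            lines.append("  suspicious features: " + ", ".join(b["morphology_flags"]))
        g = b.get("growth")
        if g:
            lines.append(
                f"  growth over {g['interval_days']} d: VDT {g['vdt_days']} d, "
                f"dD {g['delta_diameter_mm']} mm "
                f"(from baseline {g['delta_diameter_from_baseline_mm']} mm)"
            )
        interval = dec["interval_months"]
        lines.append(
            f"  decision: {dec['category']} / {dec['action']}"
            + (f" (repeat in {interval} months)" if interval else "")
        )
        lines.append(f"  rationale: {'; '.join(dec['rationale'])}")
    lines.append("-" * 64)
    lines.append(
        f"Overall: {report.overall_category} / {report.overall_action}"
        + (
            f" — next scan in {report.overall_interval_months} months"
            if report.overall_interval_months
            else " — referred, leaves screening schedule"
        )
    )
    return "\n".join(lines)


def parse_report(serialized: str) -> StructuredReport:
    """Inverse of :func:`emit_report` for the JSON format."""
    d = json.loads(serialized)
    return StructuredReport(
        participant_id=d["participant_id"],
        scan_date=d["scan_date"],
        nodules=tuple(d["nodules"]),
        overall_category=d["overall"]["category"],
        overall_action=d["overall"]["action"],
        overall_interval_months=d["overall"]["interval_months"],
    )
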