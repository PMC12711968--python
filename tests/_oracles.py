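"""Independent oracles used by the tests.

These are deliberately literal transcriptions of the published management
table and growth inequalities, written as flat lookups with no shared code
with the package, so that the rule engine can be checked against them
exhaustively.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Management-table lookup (baseline + new nodules)
#
# density: solid | part_solid | non_solid.  For solid/part_solid, size is the
# solid(-component) volume in mm^3; for non_solid it is the whole-nodule
# diameter in mm.  verdict: benign | neutral | suspicious.
# registration: prevalent | new | missed_on_prior.
# ---------------------------------------------------------------------------


def table_action(
    density: str,
    size: float,
    verdict: str,
    registration: str,
    *,
    diameter_units: bool = False,
) -> str:
    """Printed management for one nodule.

    ``size`` is the solid(-component) volume in mm^3 (or, with
    ``diameter_units``, the printed mm bins when volumetry failed); for
    non_solid it is always the whole-nodule diameter in mm.
    """
    new_cut, low, mid, high = (
        (4.0, 6.0, 8.0, 10.0) if diameter_units else (30.0, 100.0, 250.0, 500.0)
    )

    if verdict == "benign":
        return "repeat_12m"  # benign features, any size -> 12 months

    if registration == "new":
        # new-nodule block: non-solid any size negative; solid(-component)
        # < 30 mm^3 (< 4 mm) negative, above -> 3 months
        if density == "non_solid":
            return "repeat_12m"
        return "repeat_12m" if size < new_cut else "repeat_3m"

    # prevalent & missed-on-prior follow the baseline block
    if density == "non_solid":
        if size < 30:  # mm
            return "repeat_6m" if verdict == "suspicious" else "repeat_12m"
        return "repeat_3m" if verdict == "suspicious" else "repeat_6m"

    if verdict == "suspicious":
        if size < low:
            return "repeat_6m"
        if size < mid:
            return "repeat_3m"
        return "workup"  # >= 250 mm^3 (>= 8 mm): work up

    if size < low:
        return "repeat_12m"
    if size < mid:
        return "repeat_6m"
    if size < high:
        return "repeat_3m"
    return "repeat_1m" if density == "part_solid" else "workup"


# ---------------------------------------------------------------------------
# Growth inequalities (printed cutoffs re-evaluated from scratch)
# ---------------------------------------------------------------------------


def growth_oracle(v1: float, v2: float, interval_days: float) -> dict:
    if v2 > v1:
        vdt = interval_days * math.log(2) / math.log(v2 / v1)
    else:
        vdt = math.inf
    if interval_days <= 135:
        cutoff = 250.0
    elif interval_days <= 270:
        cutoff = 400.0
    else:
        cutoff = 500.0
    d1 = (6 * v1 / math.pi) ** (1 / 3)
    d2 = (6 * v2 / math.pi) ** (1 / 3)
    substantial = vdt < cutoff
    regression = (v1 - v2) / v1 >= 0.25 or (d2 - d1) <= -2.0
    return {
        "vdt": vdt,
        "cutoff": cutoff,
        "substantial": substantial and not regression,
        "regression": regression and not substantial,
        "delta_d": d2 - d1,
    }


# ---------------------------------------------------------------------------
# Morphology truth-table oracle
# ---------------------------------------------------------------------------

SUSPICIOUS = (
    "spiculation", "pleural_tag", "fissural_displacement", "cystic_component",
    "bubble_like_lucencies", "concave_sign", "narrowed_vessels",
    "bronchus_cut_off",
)


def morphology_oracle(
    flags: dict,
    calcification: str,
    fat: bool,
    infection: bool,
    ipln: bool,
    density: str = "solid",
    ggo_diameter_mm: float | None = None,
) -> str:
    benign = (
        calcification in {"central", "diffuse", "popcorn"} or fat or infection or ipln
    )
    suspicious = any(flags.get(f) for f in SUSPICIOUS) or (
        density in {"part_solid", "non_solid"}
        and ggo_diameter_mm is not None
        and ggo_diameter_mm >= 30.0
    )
    if benign:
        return "benign"
    if suspicious:
        return "suspicious"
    return "neutral"
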