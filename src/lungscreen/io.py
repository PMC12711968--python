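"""Tabular I/O: the per-scan nodule measurement schema, validation with
row-numbered errors, CSV / JSON-lines readers and writers, and YAML config.

Table schema (CSV: UTF-8, comma separated, header required, ISO-8601 dates,
missing values as empty fields):

========================  =======================================================
column                    meaning
========================  =======================================================
participant_id            opaque participant key
scan_date                 ISO-8601 date of the scan
nodule_id                 opaque per-nodule key, stable across scans
registration              prevalent | new | missed_on_prior
density                   solid | part_solid | non_solid
volume_mm3                software volumetry of the whole nodule (blank if failed)
mean_diameter_mm          manual mean/average diameter (blank if not measured)
segmentation_complete     true/false; blank means complete when a volume is given
measured_manually         true/false
solid_volume_mm3          solid-component volumetry (part-solid only)
solid_diameter_mm         solid-component manual diameter (part-solid only)
<morphology flags>        lowercase snake-case booleans (spiculation, ...)
calcification_pattern     none | central | diffuse | popcorn | other
fat_attenuation           true/false   (fat_hu optional, -120..-40)
infection_suspected       true/false
shape / margin            geometry enums (see morphology module)
distance_to_pleura_mm     nonnegative real
below_carina              true/false
========================  =======================================================
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .classifier import (
    DENSITY_CLASSES,
    REGISTRATION_STATES,
    ClassifierConfig,
    ManagementDecision,
    NoduleObservation,
)
from .growth import InvalidInputError, SizeMeasurement
from .morphology import (
    CALCIFICATION_PATTERNS,
    MARGINS,
    SHAPES,
    MorphologyProfile,
)

__all__ = [
    "MORPH_COLUMNS",
    "OBSERVATION_COLUMNS",
    "SchemaError",
    "validate_table",
    "read_observations",
    "write_observations",
    "parse_table",
    "observation_from_row",
    "decisions_to_frame",
    "load_config",
    "classifier_config_from_dict",
]

MORPH_COLUMNS = (
    "spiculation", "pleural_tag", "fissural_displacement", "cystic_component",
    "bubble_like_lucencies", "concave_sign", "narrowed_vessels",
    "bronchus_cut_off", "air_bronchogram", "calcification_pattern",
    "fat_attenuation", "infection_suspected", "shape", "margin",
    "distance_to_pleura_mm", "below_carina",
)

OBSERVATION_COLUMNS = (
    "participant_id", "scan_date", "nodule_id", "registration", "density",
    "volume_mm3", "mean_diameter_mm", "segmentation_complete",
    "measured_manually", "solid_volume_mm3", "solid_diameter_mm",
) + MORPH_COLUMNS

_REQUIRED_COLUMNS = (
    "participant_id", "scan_date", "nodule_id", "registration", "density",
)

_BOOL_COLUMNS = frozenset(
    {
        "segmentation_complete", "measured_manually", "fat_attenuation",
        "infection_suspected", "below_carina",
        "spiculation", "pleural_tag", "fissural_displacement",
        "cystic_component", "bubble_like_lucencies", "concave_sign",
        "narrowed_vessels", "bronchus_cut_off", "air_bronchogram",
    }
)
_FLOAT_COLUMNS = frozenset(
    {"volume_mm3", "mean_diameter_mm", "solid_volume_mm3", "solid_diameter_mm",
     "distance_to_pleura_mm", "fat_hu"}
)


class SchemaError(InvalidInputError):
    """Measurement table violates the published schema."""


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _parse_bool(value) -> Optional[bool]:
    if _missing(value):
        return None
    if isinstance(value, (bool,)):
        return bool(value)
    if isinstance(value, (int, float)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise SchemaError(f"not a boolean: {value!r}")


def _parse_float(value) -> Optional[float]:
    if _missing(value):
        return None
    return float(value)


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    if isinstance(value, (pd.Timestamp, _dt.datetime)):
        return value.date()
    return _dt.date.fromisoformat(str(value).strip())


def observation_from_row(row: dict) -> tuple[str, NoduleObservation]:
    """Build (participant_id, NoduleObservation) from one table row."""
    density = str(row["density"]).strip()
    whole = SizeMeasurement(
        volume_mm3=_parse_float(row.get("volume_mm3")),
        mean_diameter_mm=_parse_float(row.get("mean_diameter_mm")),
        segmentation_complete=_parse_bool(row.get("segmentation_complete")),
        measured_manually=_parse_bool(row.get("measured_manually")) or False,
    )
    solid = None
    sv = _parse_float(row.get("solid_volume_mm3"))
    sd = _parse_float(row.get("solid_diameter_mm"))
    if sv is not None or sd is not None:
        solid = SizeMeasurement(
            volume_mm3=sv, mean_diameter_mm=sd, measured_manually=sv is None
        )
    morph_kwargs: dict = {}
    for col in MORPH_COLUMNS:
        if col not in row:
            continue
        value = row[col]
        if col == "calcification_pattern":
            morph_kwargs[col] = "none" if _missing(value) else str(value).strip()
        elif col in {"shape", "margin"}:
            if not _missing(value):
                morph_kwargs[col] = str(value).strip()
        elif col in {"distance_to_pleura_mm", "fat_hu"}:
            morph_kwargs[col] = _parse_float(value)
        else:
            morph_kwargs[col] = _parse_bool(value)
    obs = NoduleObservation(
        nodule_id=str(row["nodule_id"]),
        scan_date=_parse_date(row["scan_date"]),
        density=density,
        whole=whole,
        solid_component=solid,
        morphology=MorphologyProfile(**morph_kwargs),
        registration=str(row["registration"]).strip(),
    )
    return str(row["participant_id"]), obs


def validate_table(df: pd.DataFrame) -> list[str]:
    """Schema check; returns human-readable errors with 1-based row numbers
    (header = row 1, first data row = row 2, matching spreadsheet dialects)."""
    errors: list[str] = []
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column: {col}")
    if errors:
        return errors
    for idx, row in enumerate(df.to_dict("records")):
        rowno = idx + 2
        if str(row["density"]).strip() not in DENSITY_CLASSES:
            errors.append(f"row {rowno}: unknown density {row['density']!r}")
            continue
        if str(row["registration"]).strip() not in REGISTRATION_STATES:
            errors.append(f"row {rowno}: unknown registration {row['registration']!r}")
            continue
        try:
            _parse_date(row["scan_date"])
        except (ValueError, TypeError):
            errors.append(f"row {rowno}: unparseable scan_date {row['scan_date']!r}")
            continue
        for col in _FLOAT_COLUMNS & set(df.columns):
            try:
                v = _parse_float(row.get(col))
            except (TypeError, ValueError):
                errors.append(f"row {rowno}: non-numeric {col}: {row.get(col)!r}")
                continue
            if v is not None and v < 0:
                errors.append(f"row {rowno}: negative {col}: {v}")
        for col in _BOOL_COLUMNS & set(df.columns):
            try:
                _parse_bool(row.get(col))
            except SchemaError:
                errors.append(f"row {rowno}: non-boolean {col}: {row.get(col)!r}")
        cp = row.get("calcification_pattern")
        if not _missing(cp) and str(cp).strip() not in CALCIFICATION_PATTERNS:
            errors.append(f"row {rowno}: unknown calcification_pattern {cp!r}")
        sh = row.get("shape")
        if not _missing(sh) and str(sh).strip() not in SHAPES:
            errors.append(f"row {rowno}: unknown shape {sh!r}")
        mg = row.get("margin")
        if not _missing(mg) and str(mg).strip() not in MARGINS:
            errors.append(f"row {rowno}: unknown margin {mg!r}")
        try:
            observation_from_row(row)
        except (InvalidInputError, ValueError) as exc:
            errors.append(f"row {rowno}: {exc}")
    return errors


def parse_table(df: pd.DataFrame) -> list[tuple[str, NoduleObservation]]:
    """Parse a validated table into observations sorted by participant, date,
    nodule id (replay order)."""
    parsed = [observation_from_row(r) for r in df.to_dict("records")]
    parsed.sort(key=lambda t: (t[0], t[1].scan_date, t[1].nodule_id))
    return parsed


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a measurement table from CSV or JSON-lines (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        return pd.read_json(path, orient="records", lines=True)
    return pd.read_csv(path)


def write_observations(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", lines=True)
    else:
        raise InvalidInputError(f"unknown format: {fmt!r}")


def decisions_to_frame(
    records: Iterable[tuple[str, _dt.date, ManagementDecision]],
) -> pd.DataFrame:
    """Flatten (participant, scan_date, decision) triples to a table."""
    rows = []
    for pid, date, dec in records:
        d = dec.to_dict()
        d["rationale"] = ";".join(d["rationale"])
        d["warnings"] = ";".join(d["warnings"])
        rows.append({"participant_id": pid, "scan_date": date.isoformat(), **d})
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "scan_date", "nodule_id", "category", "action",
            "interval_months", "effective_density", "rationale", "warnings",
        ],
    )


def classifier_config_from_dict(d: dict) -> ClassifierConfig:
    known = {
        "regression_volume_fraction", "regression_diameter_mm",
        "extended_suspicious_flags",
    }
    unknown = set(d) - known
    if unknown:
        raise InvalidInputError(f"unknown classifier config keys: {sorted(unknown)}")
    return ClassifierConfig(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file (sections: classifier, cohort, error_model,
    programme) to a plain dict; absent file sections default downstream."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidInputError("config must be a YAML mapping")
    return data


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
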