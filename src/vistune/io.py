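"""Readers and writers for the flat trial table, results table and battery metadata.

All formats are plain text (CSV with a header row, JSON sidecar for battery
metadata) with a period as decimal separator regardless of locale.  Infinite
metric values (e.g. bandwidths of low- or high-pass cells) are serialized as the
literal token ``inf``.
"""
from __future__ import annotations

import json
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    SchemaError,
    StimulusCondition,
    TrialObservation,
    UnitRecord,
    ValidationError,
)

TRIAL_COLUMNS = [
    "unit",
    "animal",
    "group",
    "hemisphere",
    "kind",
    "direction",
    "sf",
    "tf",
    "contrast",
    "duration",
    "drift_mode",
    "trial",
    "rate",
]

RESULT_KEY_COLUMNS = ["unit", "animal", "group"]


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_trial_table(path) -> List[UnitRecord]:
    """Read a trial-level CSV into :class:`UnitRecord` objects grouped by unit.

    Blank presentations are identified by ``kind == "blank"`` and leave the
    grating columns empty.  Malformed rows raise with the 1-based file line
    number (header is line 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table {path} missing mandatory columns: {missing}")

    records: dict = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            condition = StimulusCondition(
                kind=str(row.kind),
                duration=float(row.duration),
                drift_mode=str(row.drift_mode),
                direction=_opt(row.direction),
                spatial_frequency=_opt(row.sf),
                temporal_frequency=_opt(row.tf),
                contrast=_opt(row.contrast),
            )
            obs = TrialObservation(
                unit_id=str(row.unit),
                condition=condition,
                trial_index=int(row.trial),
                rate_mean=float(row.rate),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from exc
        key = str(row.unit)
        if key not in records:
            records[key] = UnitRecord(
                unit_id=key,
                animal_id=str(row.animal),
                hemisphere=str(row.hemisphere),
                group=str(row.group),
            )
        rec = records[key]
        if (rec.animal_id, rec.hemisphere, rec.group) != (
            str(row.animal),
            str(row.hemisphere),
            str(row.group),
        ):
            raise ValidationError(
                f"{path} line {line}: unit {key} has inconsistent animal/hemisphere/group labels"
            )
        rec.trials.append(obs)
    out = list(records.values())
    for rec in out:
        seen = set()
        for t in rec.trials:
            k = (t.condition, t.trial_index)
            if k in seen:
                raise ValidationError(
                    f"unit {rec.unit_id}: duplicate trial_index {t.trial_index} for a condition"
                )
            seen.add(k)
    return out


def write_trial_table(records: Iterable[UnitRecord], path) -> None:
    """Write unit records to the trial CSV (inverse of :func:`read_trial_table`)."""
    rows = []
    for rec in records:
        for t in rec.trials:
            c = t.condition
            rows.append(
                {
                    "unit": rec.unit_id,
                    "animal": rec.animal_id,
                    "group": rec.group,
                    "hemisphere": rec.hemisphere,
                    "kind": c.kind,
                    "direction": c.direction,
                    "sf": c.spatial_frequency,
                    "tf": c.temporal_frequency,
                    "contrast": c.contrast,
                    "duration": c.duration,
                    "drift_mode": c.drift_mode,
                    "trial": t.trial_index,
                    "rate": t.rate_mean,
                }
            )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def write_results_table(rows: Sequence[Mapping], path) -> None:
    """Write one row per unit of named metric columns.

    Column order is deterministic: ``unit, animal, group`` then metrics in
    order of first appearance.  Infinite values serialize as ``inf``.
    """
    rows = list(rows)
    columns = list(RESULT_KEY_COLUMNS)
    seen_units = set()
    for row in rows:
        for key in RESULT_KEY_COLUMNS:
            if key not in row:
                raise SchemaError(f"result row missing mandatory key {key!r}")
        if row["unit"] in seen_units:
            raise ValidationError(f"duplicate unit_id {row['unit']!r} in results")
        seen_units.add(row["unit"])
        for key in row:
            if key not in columns:
                columns.append(key)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read a results CSV; the ``inf`` token parses back to ``np.inf``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RESULT_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results table {path} missing columns: {missing}")
    return df


def _condition_to_dict(c: StimulusCondition) -> dict:
    return {
        "kind": c.kind,
        "duration": c.duration,
        "drift_mode": c.drift_mode,
        "direction": c.direction,
        "sf": c.spatial_frequency,
        "tf": c.temporal_frequency,
        "contrast": c.contrast,
    }


def _condition_from_dict(d: Mapping) -> StimulusCondition:
    return StimulusCondition(
        kind=d["kind"],
        duration=d["duration"],
        drift_mode=d["drift_mode"],
        direction=d.get("direction"),
        spatial_frequency=d.get("sf"),
        temporal_frequency=d.get("tf"),
        contrast=d.get("contrast"),
    )


def write_battery_json(batteries: Mapping[str, Sequence[StimulusCondition]],
                       repeats: Mapping[str, int], path) -> None:
    """Write battery metadata (condition lists and repeat counts) as JSON."""
    payload = {
        "repeats": dict(repeats),
        "batteries": {
            name: [_condition_to_dict(c) for c in conds]
            for name, conds in batteries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_battery_json(path):
    with open(path) as fh:
        payload = json.load(fh)
    batteries = {
        name: [_condition_from_dict(d) for d in conds]
        for name, conds in payload["batteries"].items()
    }
    return batteries, payload["repeats"]
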