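"""End-to-end orchestration: simulate/load -> extract -> metrics -> group stats.

A pipeline run is a pure function of its configuration and seed: it produces a
per-unit metrics CSV, a per-metric statistics JSON, a (metric, group) summary
table and a log with versions, seeds and per-stage unit counts.
"""
from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import UnitRecord, ValidationError
from . import io as vio
from . import synth
from .extraction import inclusion_anova, slice_tuning
from .selectivity import (
    direction_index,
    fit_double_gaussian,
    orientation_index,
    preferred_orientation_vector,
)
from .frequency import fit_frequency_curve, lowpass_highpass_index
from .contrast import blank_sd, contrast_sensitivity, excitability_metrics, fit_naka_rushton
from .inference import fit_lmem, preference_distribution_test, rank_transform_with_infinities

RANK_METRICS = {
    "tf_bandwidth_rectified",
    "tf_bandwidth_absolute",
    "sf_bandwidth_rectified",
    "sf_bandwidth_absolute",
}

DEFAULT_METRICS = [
    "osi",
    "dsi",
    "pref_tf",
    "pref_sf",
    "tf_lpi",
    "tf_hpi",
    "sf_lpi",
    "sf_hpi",
    "tf_bandwidth_rectified",
    "tf_bandwidth_absolute",
    "sf_bandwidth_rectified",
    "sf_bandwidth_absolute",
    "peak_rate",
    "suppression",
    "background",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, unit_id: Optional[str], message: str):
        self.stage = stage
        self.unit_id = unit_id
        where = f"stage {stage}" + (f", unit {unit_id}" if unit_id else "")
        super().__init__(f"[{where}] {message}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (from YAML or constructed directly)."""

    out_dir: str
    seed: Optional[int] = None
    trials_path: Optional[str] = None
    simulate: Optional[dict] = None  # {n_animals, units_per_animal, batteries}
    metrics: List[str] = field(default_factory=lambda: list(DEFAULT_METRICS))

    def __post_init__(self) -> None:
        if self.simulate is not None and self.seed is None:
            raise ValidationError("seed is mandatory when simulating")
        if self.simulate is None and self.trials_path is None:
            raise ValidationError("either trials_path or simulate must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def compute_unit_metrics(unit: UnitRecord) -> dict:
    """All per-unit metrics available from the unit's batteries.

    Metrics whose battery is absent or whose inclusion ANOVA fails are NaN;
    inclusion outcomes are reported alongside.
    """
    row: Dict = {"unit": unit.unit_id, "animal": unit.animal_id, "group": unit.group}
    batteries = unit.batteries()

    if "B2" in batteries:
        inc = inclusion_anova(unit, "B2")
        row["included_B2"] = inc.included
        row["inclusion_p_B2"] = inc.p_value
        if inc.included:
            tf_curve = slice_tuning(unit, "temporal_frequency", inc)
            row["tf_lpi"], row["tf_hpi"] = lowpass_highpass_index(tf_curve)
            for variant in ("rectified", "absolute"):
                fit = fit_frequency_curve(tf_curve, variant)
                row[f"tf_bandwidth_{variant}"] = fit.bandwidth_octaves
                row[f"tf_L50_{variant}"] = fit.L50
                row[f"tf_H50_{variant}"] = fit.H50
                if variant == "rectified":
                    row["pref_tf"] = fit.peak_frequency
            dir_curve = slice_tuning(unit, "direction", inc)
            row["dsi"] = direction_index(dir_curve)
            dg = fit_double_gaussian(dir_curve)
            row["pref_direction"] = dg.pref_direction if dg.fit_ok else math.nan
            row["dir_fit_ok"] = dg.fit_ok

    if "B1" in batteries:
        inc1 = inclusion_anova(unit, "B1")
        row["included_B1"] = inc1.included
        row["inclusion_p_B1"] = inc1.p_value
        if inc1.included:
            ori_curve = slice_tuning(unit, "orientation", inc1)
            row["osi"] = orientation_index(ori_curve)
            row["pref_orientation"] = preferred_orientation_vector(ori_curve)
            sf_curve = slice_tuning(unit, "spatial_frequency", inc1)
            row["sf_lpi"], row["sf_hpi"] = lowpass_highpass_index(sf_curve)
            for variant in ("rectified", "absolute"):
                fit = fit_frequency_curve(sf_curve, variant)
                row[f"sf_bandwidth_{variant}"] = fit.bandwidth_octaves
                if variant == "rectified":
                    row["pref_sf"] = fit.peak_frequency
            contrast_curve = slice_tuning(unit, "contrast", inc1)
            cfit = fit_naka_rushton(contrast_curve)
            row["c50"] = cfit.c50
            row["contrast_n"] = cfit.n_exp
            row["contrast_rmax"] = cfit.R_max
            row["contrast_sensitivity"] = contrast_sensitivity(cfit, blank_sd(unit, "B1"))

    try:
        exc = excitability_metrics(unit)
    except ValidationError as err:
        raise PipelineError("extraction", unit.unit_id, str(err))
    row["peak_rate"] = exc.peak_rate
    row["suppression"] = exc.suppression
    row["background"] = exc.background
    return row


def metrics_table(records: Sequence[UnitRecord]) -> pd.DataFrame:
    rows = []
    for unit in records:
        try:
            rows.append(compute_unit_metrics(unit))
        except PipelineError:
            raise
        except ValidationError as err:
            raise PipelineError("metrics", unit.unit_id, str(err))
    return pd.DataFrame(rows)


def group_statistics(metrics: pd.DataFrame, metric_names: Sequence[str]) -> dict:
    """Per-metric mixed-model statistics; rank transform for bandwidth metrics."""
    out = {}
    for name in metric_names:
        if name not in metrics.columns:
            continue
        sub = metrics[["unit", "animal", "group", name]].rename(columns={name: "value"})
        if name in RANK_METRICS:
            sub = sub[~sub["value"].isna()].copy()
            if len(sub) == 0:
                continue
            sub["value"] = rank_transform_with_infinities(sub["value"].to_numpy())
            transform = "rank"
        else:
            sub = sub[np.isfinite(sub["value"].astype(float))].copy()
            transform = "none"
        if sub["group"].nunique() < 2 or len(sub) < 4:
            continue
        res = fit_lmem(sub, metric=name)
        d = res.to_dict()
        d["transform"] = transform
        out[name] = d
    for pref, space in (("pref_direction", 360.0), ("pref_orientation", 180.0)):
        if pref in metrics.columns:
            sub = metrics[["group", pref]].dropna()
            if sub["group"].nunique() >= 2 and len(sub) >= 8:
                stat, p, table = preference_distribution_test(
                    sub[pref].to_numpy(), sub["group"].to_numpy(), space=space
                )
                out[f"{pref}_distribution"] = {
                    "chi2": stat,
                    "p": p,
                    "table": {g: [int(v) for v in table.loc[g]] for g in table.index},
                }
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle into ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines = [f"vistune {__version__}", f"seed {config.seed}"]

    if config.simulate is not None:
        sim = dict(config.simulate)
        batteries = tuple(sim.get("batteries", ("B1", "B2")))
        specs = synth.default_group_specs(
            n_animals=int(sim.get("n_animals", 6)),
            units_per_animal=int(sim.get("units_per_animal", 20)),
        )
        records, truth = synth.simulate_dataset(specs, batteries=batteries, seed=config.seed)
        vio.write_trial_table(records, os.path.join(config.out_dir, "trials.csv"))
        truth.to_csv(os.path.join(config.out_dir, "ground_truth.csv"), index=False)
        vio.write_battery_json(
            {b: synth.make_battery(b) for b in batteries},
            {b: synth.DEFAULT_REPEATS[b] for b in batteries},
            os.path.join(config.out_dir, "batteries.json"),
        )
    else:
        try:
            records = vio.read_trial_table(config.trials_path)
        except Exception as err:
            raise PipelineError("data", None, str(err))
    log_lines.append(f"units in: {len(records)}")

    metrics = metrics_table(records)
    metrics_path = os.path.join(config.out_dir, "metrics.csv")
    vio.write_results_table(metrics.to_dict("records"), metrics_path)
    for b in ("B1", "B2"):
        col = f"included_{b}"
        if col in metrics.columns:
            n_in = int(metrics[col].sum())
            log_lines.append(f"battery {b}: {n_in} included / {len(metrics)} units")

    statistics = group_statistics(metrics, config.metrics)
    stats_path = os.path.join(config.out_dir, "stats.json")
    with open(stats_path, "w") as fh:
        json.dump(statistics, fh, indent=1, sort_keys=True, default=_json_default)

    summary_rows = []
    for metric, d in statistics.items():
        if "group_means" not in d:
            continue
        for g, m in sorted(d["group_means"].items()):
            entry = {
                "metric": metric,
                "group": g,
                "mean": m,
                "se": d["group_se"][g],
                "median": d["group_medians"][g],
                "n_cells": d["n_cells"][g],
                "n_animals": d["n_animals"][g],
            }
            if g in d["contrasts_vs_reference"]:
                entry["p_vs_reference"] = d["contrasts_vs_reference"][g]["p"]
            summary_rows.append(entry)
    summary = pd.DataFrame(summary_rows)
    summary_path = os.path.join(config.out_dir, "summary.csv")
    summary.to_csv(summary_path, index=False)

    with open(os.path.join(config.out_dir, "log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    digest = hashlib.sha256(open(metrics_path, "rb").read()).hexdigest()
    return {
        "metrics": metrics,
        "statistics": statistics,
        "summary": summary,
        "metrics_path": metrics_path,
        "stats_path": stats_path,
        "summary_path": summary_path,
        "metrics_sha256": digest,
        "log": log_lines,
    }
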