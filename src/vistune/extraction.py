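"""From trial observations to blank-subtracted tuning curves.

Responses are quantified either as the mean firing rate over the stimulus
window or as the F1 component (response modulation at the stimulus temporal
frequency); the same quantity computed for the battery's blank is subtracted to
yield the stimulus-driven response, which may be negative (suppression).  Units
enter analysis only if a one-way ANOVA over all of a battery's conditions
(blank included) rejects the hypothesis of a common mean response at p < 0.05.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TrialObservation, TuningCurve, UnitRecord, ValidationError

SLICE_TARGETS = (
    "orientation",
    "spatial_frequency",
    "temporal_frequency",
    "direction",
    "contrast",
)

INCLUSION_ALPHA = 0.05


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the visual-responsiveness ANOVA for one unit and battery."""

    unit_id: str
    battery: str
    p_value: float
    included: bool


def mean_response(trials: Sequence[TrialObservation], blank_rate: float) -> float:
    """Blank-subtracted mean firing rate over a condition's trials (signed, Hz)."""
    if not trials:
        raise ValidationError("mean_response requires >= 1 trial")
    return float(np.mean([t.rate_mean for t in trials]) - blank_rate)


def f1_complex(spike_times: Sequence[float], duration: float, stim_tf: float) -> complex:
    """Complex F1 coefficient (2/T) * sum_j exp(-i 2 pi f t_j).

    The factor 2 makes a rate r(t) = m + a*sin(2 pi f t) yield |F1| = a.
    Averaging these complex coefficients across trials before taking the
    modulus exploits the trial-locked stimulus phase and cancels spike-count
    noise that would otherwise bias the amplitude upward.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    t = np.asarray(list(spike_times), dtype=float)
    if t.size and (t.min() < -1e-9 or t.max() > duration + 1e-9):
        raise ValidationError("spike times must lie within [0, duration]")
    return complex((2.0 / duration) * np.sum(np.exp(-2j * math.pi * stim_tf * t)))


def f1_response(spike_times: Sequence[float], duration: float, stim_tf: float) -> float:
    """F1 amplitude (Hz) of a single spike train; 0 for an empty train."""
    return abs(f1_complex(spike_times, duration, stim_tf))


def _condition_groups(unit: UnitRecord, battery: str):
    groups: Dict = {}
    for t in unit.trials_for_battery(battery):
        groups.setdefault(t.condition, []).append(t)
    if not groups:
        raise ValidationError(f"unit {unit.unit_id}: no trials for battery {battery}")
    return groups


def inclusion_anova(unit: UnitRecord, battery: str) -> InclusionResult:
    """One-way ANOVA over all conditions of a battery (blank included).

    The unit is included iff p < 0.05.  Identical responses everywhere give a
    non-rejecting p of 1.
    """
    groups = _condition_groups(unit, battery)
    samples = []
    for cond, trials in sorted(groups.items(), key=lambda kv: repr(kv[0])):
        if len(trials) < 2:
            raise ValidationError(
                f"unit {unit.unit_id}: condition {cond} has < 2 trials; ANOVA needs >= 2"
            )
        samples.append([t.rate_mean for t in trials])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.f_oneway(*samples)
    if np.isnan(p):  # all values identical across every condition
        p = 1.0
    return InclusionResult(
        unit_id=unit.unit_id, battery=battery,
        p_value=float(p), included=bool(p < INCLUSION_ALPHA),
    )


def choose_modality(mean_curve: TuningCurve, f1_curve: TuningCurve) -> TuningCurve:
    """Pick the response modality with the larger maximum response.

    Ties go to the mean response.  Temporal-frequency analysis bypasses this
    choice and always uses mean responses, because profound suppression makes
    F1 misleading there.
    """
    if not np.array_equal(mean_curve.x_values, f1_curve.x_values):
        raise ValidationError("mean and F1 curves must share x_values")
    if float(np.max(f1_curve.responses)) > float(np.max(mean_curve.responses)):
        return f1_curve
    return mean_curve


def _response_frame(unit: UnitRecord, battery: str) -> Tuple[pd.DataFrame, float]:
    """Per-condition blank-subtracted mean responses of one battery."""
    groups = _condition_groups(unit, battery)
    blank_rate = unit.blank_rate(battery)
    rows = []
    for cond, trials in groups.items():
        if cond.is_blank:
            continue
        rates = np.array([t.rate_mean for t in trials])
        se = float(rates.std(ddof=1) / math.sqrt(len(rates))) if len(rates) > 1 else 0.0
        rows.append(
            {
                "direction": cond.direction,
                "orientation": cond.orientation,
                "spatial_frequency": cond.spatial_frequency,
                "temporal_frequency": cond.temporal_frequency,
                "contrast": cond.contrast,
                "response": float(rates.mean() - blank_rate),
                "se": se,
                "n": len(rates),
            }
        )
    if not rows:
        raise ValidationError(f"unit {unit.unit_id}: battery {battery} has no grating trials")
    return pd.DataFrame(rows), blank_rate


def _argmax_low(values: pd.Series) -> float:
    """Index label of the maximum; ties broken toward the lower label."""
    values = values.sort_index()
    m = values.max()
    return float(values.index[np.nonzero((values.values >= m - 1e-12))[0][0]])


def _b1_preferences(frame: pd.DataFrame) -> Tuple[float, float]:
    """Preferred orientation and spatial frequency from the B1 response table.

    Preferred orientation is the argmax of the full-contrast responses averaged
    over spatial frequency; preferred SF is then the argmax at that orientation
    at full contrast.  Ties break toward the lower angle / lower frequency.
    """
    full = frame[frame["contrast"] == frame["contrast"].max()]
    ori_marginal = full.groupby("orientation")["response"].mean()
    pref_ori = _argmax_low(ori_marginal)
    at_ori = full[full["orientation"] == pref_ori]
    sf_curve = at_ori.groupby("spatial_frequency")["response"].mean()
    pref_sf = _argmax_low(sf_curve)
    return pref_ori, pref_sf


def _b2_preferences(frame: pd.DataFrame) -> Tuple[float, float]:
    """Preferred direction (marginal over TF) and TF (at preferred direction)."""
    dir_marginal = frame.groupby("direction")["response"].mean()
    pref_dir = _argmax_low(dir_marginal)
    at_dir = frame[frame["direction"] == pref_dir]
    tf_curve = at_dir.groupby("temporal_frequency")["response"].mean()
    pref_tf = _argmax_low(tf_curve)
    return pref_dir, pref_tf


def _curve(frame: pd.DataFrame, varied: str, blank_rate: float) -> TuningCurve:
    g = frame.groupby(varied).agg(response=("response", "mean"), se=("se", "mean"))
    g = g.sort_index()
    return TuningCurve(
        varied_parameter=varied,
        x_values=np.asarray(g.index, dtype=float),
        responses=g["response"].to_numpy(),
        response_se=g["se"].to_numpy(),
        response_modality="mean",
        blank_rate=blank_rate,
    )


def slice_tuning(
    unit: UnitRecord,
    target: str,
    inclusion: Optional[InclusionResult] = None,
) -> TuningCurve:
    """Extract a 1-D tuning curve at the unit's empirically preferred parameters.

    Targets: ``orientation`` (at preferred SF, full contrast), ``spatial_frequency``
    (at preferred orientation, full contrast), ``contrast`` (at preferred
    orientation and SF), ``temporal_frequency`` (at preferred direction),
    ``direction`` (at preferred TF).  Preferences are argmaxes of
    blank-subtracted responses with ties broken toward the lower value.  The
    unit must pass the inclusion ANOVA of the relevant battery.
    """
    if target not in SLICE_TARGETS:
        raise ValidationError(f"unknown slice target {target!r}")
    battery = "B1" if target in ("orientation", "spatial_frequency", "contrast") else "B2"
    if inclusion is None:
        inclusion = inclusion_anova(unit, battery)
    if inclusion.battery != battery:
        raise ValidationError("inclusion result is for the wrong battery")
    if not inclusion.included:
        raise ValidationError(
            f"unit {unit.unit_id} failed the inclusion test for battery {battery} "
            f"(p={inclusion.p_value:.3g})"
        )
    frame, blank_rate = _response_frame(unit, battery)
    if battery == "B1":
        pref_ori, pref_sf = _b1_preferences(frame)
        cmax = frame["contrast"].max()
        if target == "orientation":
            sel = frame[(frame["contrast"] == cmax) & (frame["spatial_frequency"] == pref_sf)]
            return _curve(sel, "orientation", blank_rate)
        if target == "spatial_frequency":
            sel = frame[(frame["contrast"] == cmax) & (frame["orientation"] == pref_ori)]
            return _curve(sel, "spatial_frequency", blank_rate)
        sel = frame[(frame["orientation"] == pref_ori) & (frame["spatial_frequency"] == pref_sf)]
        return _curve(sel, "contrast", blank_rate)
    pref_dir, pref_tf = _b2_preferences(frame)
    if target == "temporal_frequency":
        sel = frame[frame["direction"] == pref_dir]
        return _curve(sel, "temporal_frequency", blank_rate)
    sel = frame[frame["temporal_frequency"] == pref_tf]
    return _curve(sel, "direction", blank_rate)
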