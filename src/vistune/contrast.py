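"""Naka-Rushton contrast response fitting, sensitivity, and excitability metrics.

The contrast response is fit with

    R(c) = R_max * c^n / (c50^n + c^n) + B

where ``R_max`` is the saturating response above baseline, ``c50`` the
half-saturation contrast, ``n`` the exponent and ``B`` the baseline.  Contrast
sensitivity is the reciprocal of the lowest contrast at which the fitted
response rises more than five standard deviations of the blank-trial rates
above baseline.

Excitability of a unit is summarized by three numbers: the peak blank-subtracted
response over all stimuli, the deepest suppression below the background rate,
and the background rate itself (mean rate during gray-screen blanks).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.optimize import least_squares

from .datamodel import TuningCurve, UnitRecord, ValidationError

C_MIN = 1e-6  # numeric floor for the sensitivity crossing contrast


def naka_rushton(c, r_max: float, c50: float, n: float, b: float):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, r_max * c ** n / (c50 ** n + c ** n), 0.0) + b
    return out if out.ndim else float(out)


@dataclass
class ContrastFit:
    """Fitted Naka-Rushton parameters; R(c) is monotone nondecreasing in c."""

    R_max: float
    c50: float
    n_exp: float
    B: float
    fit_sse: float
    sensitivity: float = math.nan
    degenerate: bool = False


def fit_naka_rushton(curve: TuningCurve) -> ContrastFit:
    """Deterministic multi-start bounded least-squares Naka-Rushton fit."""
    c = np.asarray(curve.x_values, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if len(c) < 4:
        raise ValidationError("need >= 4 contrast levels to fit")
    if float(np.ptp(y)) < 1e-12:
        return ContrastFit(R_max=0.0, c50=math.nan, n_exp=math.nan,
                           B=float(np.mean(y)), fit_sse=0.0, degenerate=True)

    starts = []
    for c50_0 in np.geomspace(0.01, 1.5, 12):
        for n0 in (0.5, 1.0, 2.0, 4.0):
            shape = c ** n0 / (c50_0 ** n0 + c ** n0)
            X = np.column_stack([shape, np.ones_like(c)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rmax0 = max(coef[0], 0.0)
            sse = float(np.sum((X @ [rmax0, coef[1]] - y) ** 2))
            starts.append((sse, rmax0, c50_0, n0, coef[1]))
    starts.sort(key=lambda s: (s[0], s[2], s[3]))

    lb = [0.0, 1e-3, 0.5, -np.inf]
    ub = [np.inf, 1.5, 6.0, np.inf]

    def residual(x):
        return naka_rushton(c, *x) - y

    best = None
    for sse0, rmax0, c50_0, n0, b0 in starts[:5]:
        try:
            sol = least_squares(residual, [max(rmax0, 1e-9), c50_0, n0, b0],
                                bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol.x)
    sse, x = best
    return ContrastFit(R_max=float(x[0]), c50=float(x[1]), n_exp=float(x[2]),
                       B=float(x[3]), fit_sse=sse)


def contrast_sensitivity(fit: ContrastFit, blank_sd: float) -> float:
    """Reciprocal of the lowest contrast where R(c) - B exceeds 5 blank SDs.

    Solved in closed form from the fitted Naka-Rushton; NaN when the fitted
    response never exceeds the threshold at any contrast <= 1.  The crossing
    contrast is floored at a numeric tolerance so a zero threshold yields a
    finite (grid-resolution-bounded) sensitivity.
    """
    if blank_sd < 0:
        raise ValidationError("blank_sd must be >= 0")
    if fit.degenerate:
        return math.nan
    threshold = 5.0 * blank_sd
    r_at_1 = fit.R_max / (fit.c50 ** fit.n_exp + 1.0)
    if r_at_1 <= threshold:
        return math.nan
    if threshold <= 0:
        return 1.0 / C_MIN
    c_star = fit.c50 * (threshold / (fit.R_max - threshold)) ** (1.0 / fit.n_exp)
    c_star = max(c_star, C_MIN)
    if c_star > 1.0:
        return math.nan
    return 1.0 / c_star


@dataclass
class ExcitabilityMetrics:
    """Peak response, suppression below background and background rate (Hz)."""

    peak_rate: float
    suppression: float
    background: float


def excitability_metrics(unit: UnitRecord) -> ExcitabilityMetrics:
    """Compute the three excitability metrics across all available batteries.

    Responses are blank-subtracted condition means using each battery's own
    blank; the background metric pools blank trials across batteries.  Peak is
    floored at zero; suppression is the magnitude of the most negative
    blank-subtracted response (zero if none is negative).
    """
    blanks = unit.blank_trials()
    if not blanks:
        raise ValidationError(f"unit {unit.unit_id}: no blank trials")
    background = float(np.mean([t.rate_mean for t in blanks]))
    diffs = []
    for battery in unit.batteries():
        blank_rate = unit.blank_rate(battery)
        by_cond: Dict = {}
        for t in unit.trials_for_battery(battery):
            if not t.condition.is_blank:
                by_cond.setdefault(t.condition, []).append(t.rate_mean)
        for rates in by_cond.values():
            diffs.append(float(np.mean(rates)) - blank_rate)
    if not diffs:
        raise ValidationError(f"unit {unit.unit_id}: no grating trials")
    diffs = np.array(diffs)
    return ExcitabilityMetrics(
        peak_rate=float(max(0.0, diffs.max())),
        suppression=float(max(0.0, -diffs.min())),
        background=background,
    )


def blank_sd(unit: UnitRecord, battery: Optional[str] = None) -> float:
    """Between-trial standard deviation of blank rates (ddof=1)."""
    rates = [t.rate_mean for t in unit.blank_trials(battery)]
    if len(rates) < 2:
        return 0.0
    return float(np.std(rates, ddof=1))
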