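"""Parametric spatial/temporal frequency tuning analysis.

The frequency-response model is

    R(f) = k * exp(-(f/fc)^2) / (1 + (fh/f)^beta)

a Gaussian high-frequency falloff (scale ``fc``) multiplied by a sigmoidal
low-frequency attenuation (corner ``fh``, steepness ``beta``).  With ``fh = 0``
the curve is purely low-pass; with ``fh > 0`` it is band-pass with a single
interior peak.  Derived quantities:

* L50 / H50 — the frequencies flanking the peak of the fitted curve where the
  response first drops to half its maximum.  If the fitted response never drops
  below half-maximum within the tested range on the low (high) side, the cell is
  low-pass (high-pass): L50 = 0 (H50 = infinity).
* bandwidth = log2(H50/L50) octaves; infinite for low- and/or high-pass cells.
* low-pass index (LPI) = measured response at the lowest tested frequency
  divided by the maximum measured response; high-pass index (HPI) likewise at
  the highest tested frequency.  Both are computed from measured (not fitted)
  blank-subtracted responses, rectified to >= 0.

Fitting supports two response transforms: ``rectified`` (negative responses
clipped to zero) and ``absolute`` (suppression below background counted as
response), mirroring the two bandwidth variants reported for cells that are
suppressed below baseline at some frequencies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import least_squares

from .datamodel import TuningCurve, ValidationError

VARIANTS = ("rectified", "absolute")


def eval_model(k: float, fc: float, fh: float, beta: float, f) -> np.ndarray:
    """Evaluate the frequency-response model at frequency ``f`` (> 0, Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("frequency must be > 0")
    out = k * np.exp(-((f / fc) ** 2)) / (1.0 + (fh / f) ** beta)
    return out if out.ndim else float(out)


@dataclass
class FrequencyFit:
    """Fitted frequency-model parameters and derived tuning quantities."""

    k: float
    fc: float
    fh: float
    beta: float
    variant: str
    L50: float
    H50: float
    bandwidth_octaves: float
    lpi: float
    hpi: float
    fit_sse: float
    peak_frequency: float
    degenerate: bool = False


def _transform(responses: np.ndarray, variant: str) -> np.ndarray:
    if variant == "rectified":
        return np.clip(responses, 0.0, None)
    if variant == "absolute":
        return np.abs(responses)
    raise ValidationError(f"unknown variant {variant!r}")


def _fit_shape_gain(f: np.ndarray, y: np.ndarray, fc: float, fh: float, beta: float):
    """Optimal nonnegative gain k for a fixed curve shape, and its SSE."""
    shape = eval_model(1.0, fc, fh, beta, f)
    denom = float(shape @ shape)
    k = max(0.0, float(shape @ y) / denom) if denom > 0 else 0.0
    resid = y - k * shape
    return k, float(resid @ resid)


def fit_frequency_curve(curve: TuningCurve, variant: str = "rectified") -> FrequencyFit:
    """Least-squares fit of the frequency model to a measured tuning curve.

    Deterministic multi-start: a coarse grid over (fc, fh, beta) with the gain
    solved in closed form, followed by bounded local refinement of the best
    starts.  Derived cutoffs, bandwidth and LPI/HPI are populated on the tested
    frequency range.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    f = np.asarray(curve.x_values, dtype=float)
    if len(f) < 5:
        raise ValidationError("need >= 5 frequency points to fit")
    y = _transform(np.asarray(curve.responses, dtype=float), variant)
    lpi, hpi = lowpass_highpass_index(curve)
    fmin, fmax = float(f[0]), float(f[-1])

    if not np.any(y > 0):
        return FrequencyFit(
            k=0.0, fc=np.nan, fh=np.nan, beta=np.nan, variant=variant,
            L50=np.nan, H50=np.nan, bandwidth_octaves=np.nan,
            lpi=lpi, hpi=hpi, fit_sse=0.0, peak_frequency=np.nan, degenerate=True,
        )

    fc_grid = np.geomspace(fmin / 2.0, fmax * 2.0, 9)
    fh_grid = np.concatenate([[0.0], np.geomspace(fmin / 2.0, fmax, 7)])
    beta_grid = [1.0, 2.0, 4.0]
    starts = []
    for fc0 in fc_grid:
        for fh0 in fh_grid:
            for b0 in beta_grid:
                k0, sse = _fit_shape_gain(f, y, fc0, fh0, b0)
                starts.append((sse, k0, fc0, fh0, b0))
    starts.sort(key=lambda s: (s[0], s[2], s[3], s[4]))

    lb = [0.0, fmin / 8.0, 0.0, 0.5]
    ub = [np.inf, fmax * 8.0, fmax * 8.0, 8.0]

    def resid(x):
        return eval_model(x[0], x[1], max(x[2], 0.0), x[3], f) - y

    def jac(x):
        k, fc, fh, beta = x[0], x[1], max(x[2], 0.0), x[3]
        E = np.exp(-((f / fc) ** 2))
        u = (fh / f) ** beta
        D = 1.0 + u
        base = E / D
        dk = base
        dfc = k * base * 2.0 * f ** 2 / fc ** 3
        if fh > 0:
            dfh = -k * E / D ** 2 * beta * u / fh
            dbeta = -k * E / D ** 2 * u * np.log(fh / f)
        else:
            dfh = np.zeros_like(f)
            dbeta = np.zeros_like(f)
        return np.column_stack([dk, dfc, dfh, dbeta])

    best = None
    for sse0, k0, fc0, fh0, b0 in starts[:6]:
        x0 = [max(k0, 1e-9), fc0, max(fh0, 0.0), b0]
        try:
            sol = least_squares(resid, x0, jac=jac, bounds=(lb, ub),
                                x_scale="jac", xtol=1e-11, ftol=1e-11,
                                max_nfev=120)
        except Exception:
            continue
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol.x)
    if best is None:  # pragma: no cover - optimizer always returns something
        sse, x = starts[0][0], np.array(starts[0][1:])
    else:
        sse, x = best
    k, fc, fh, beta = (float(v) for v in x)
    L50, H50 = half_height_cutoffs((k, fc, fh, beta), (fmin, fmax))
    peak = _peak_on_range(k, fc, fh, beta, fmin, fmax)
    return FrequencyFit(
        k=k, fc=fc, fh=fh, beta=beta, variant=variant,
        L50=L50, H50=H50, bandwidth_octaves=bandwidth_octaves(L50, H50),
        lpi=lpi, hpi=hpi, fit_sse=sse, peak_frequency=peak, degenerate=False,
    )


def _peak_on_range(k, fc, fh, beta, fmin, fmax) -> float:
    """Location of the fitted curve's maximum within the tested range."""
    grid = np.geomspace(fmin, fmax, 513)
    vals = eval_model(k, fc, fh, beta, grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    if lo < hi:
        res = minimize_scalar(
            lambda lf: -eval_model(k, fc, fh, beta, math.exp(lf)),
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        cand = math.exp(res.x)
        if eval_model(k, fc, fh, beta, cand) >= vals[i]:
            return float(cand)
    return float(grid[i])


def half_height_cutoffs(fit, f_range: Tuple[float, float]) -> Tuple[float, float]:
    """Half-height cutoffs (L50, H50) of a fitted curve on the tested range.

    Starting from the peak of the continuous fitted curve, the curve is followed
    toward lower (higher) frequencies until the response first drops to half its
    maximum.  If that never happens at or above fmin the cell is low-pass and
    L50 = 0; if it never happens at or below fmax the cell is high-pass and
    H50 = infinity.
    """
    if isinstance(fit, FrequencyFit):
        if fit.degenerate:
            raise ValidationError("cannot compute cutoffs of a degenerate fit")
        k, fc, fh, beta = fit.k, fit.fc, fit.fh, fit.beta
    else:
        k, fc, fh, beta = fit
    fmin, fmax = float(f_range[0]), float(f_range[1])
    if not (0 < fmin < fmax):
        raise ValidationError("f_range must satisfy 0 < fmin < fmax")
    if k <= 0:
        raise ValidationError("cannot compute cutoffs for a zero-gain fit")
    fpeak = _peak_on_range(k, fc, fh, beta, fmin, fmax)
    rmax = eval_model(k, fc, fh, beta, fpeak)
    half = rmax / 2.0

    from scipy.optimize import brentq

    def g(f):
        return eval_model(k, fc, fh, beta, f) - half

    tol = 1e-12 * rmax
    if g(fmin) >= -tol:
        L50 = 0.0
    else:
        L50 = float(brentq(g, fmin, fpeak, xtol=1e-12, rtol=1e-14))
    if g(fmax) >= -tol:
        H50 = math.inf
    else:
        H50 = float(brentq(g, fpeak, fmax, xtol=1e-12, rtol=1e-14))
    return L50, H50


def bandwidth_octaves(L50: float, H50: float) -> float:
    """Tuning bandwidth log2(H50/L50); infinite for low- and/or high-pass cells."""
    if np.isnan(L50) or np.isnan(H50):
        return np.nan
    if L50 < 0 or H50 <= 0:
        raise ValidationError("require L50 >= 0 and H50 > 0")
    if L50 == 0.0 or math.isinf(H50):
        return math.inf
    if H50 < L50:
        raise ValidationError("H50 < L50: inconsistent cutoffs")
    return float(math.log2(H50 / L50))


def lowpass_highpass_index(curve: TuningCurve) -> Tuple[float, float]:
    """Low- and high-pass indices from measured rectified responses.

    LPI = R(f_lowest) / max_f R(f), HPI = R(f_highest) / max_f R(f), with the
    responses blank-subtracted and rectified to >= 0.  NaN when the cell gives
    no positive response at any tested frequency.
    """
    r = np.clip(np.asarray(curve.responses, dtype=float), 0.0, None)
    denom = float(np.max(r)) if len(r) else 0.0
    if denom <= 0:
        return (np.nan, np.nan)
    return float(r[0] / denom), float(r[-1] / denom)
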