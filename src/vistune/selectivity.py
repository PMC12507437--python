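"""Orientation/direction selectivity indices and angle-preference fitting.

Selectivity is quantified as the magnitude of the circular resultant of the
tuning curve: in orientation space the angles are doubled,

    1 - CV  = | sum_k r_k e^{i 2 theta_k} / sum_k r_k |,

and in direction space they are not,

    1 - DCV = | sum_k R(theta_k) e^{i theta_k} / sum_k R(theta_k) |.

Both lie in [0, 1] when responses are nonnegative and are invariant to scaling
all responses.  Blank-subtracted responses below zero are clipped to zero
before the resultant (weights must be nonnegative for the resultant to be
interpretable; pass ``rectify=False`` to use raw signed values instead).
Angle preference is obtained by fitting a double Gaussian with lobes 180 deg
apart and a shared width.
"""
from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
import numpy as np
from scipy.optimize import least_squares

from .datamodel import TuningCurve, ValidationError


@dataclass
class SelectivityResult:
    """Per-unit selectivity indices and fitted angle preferences."""

    osi_1_minus_cv: float = math.nan
    dsi_1_minus_dcv: float = math.nan
    pref_orientation: float = math.nan
    pref_direction: float = math.nan
    fit_ok: bool = False


def _angles_responses(curve_or_angles, responses=None):
    if isinstance(curve_or_angles, TuningCurve):
        return (
            np.asarray(curve_or_angles.x_values, dtype=float),
            np.asarray(curve_or_angles.responses, dtype=float),
        )
    return np.asarray(curve_or_angles, dtype=float), np.asarray(responses, dtype=float)


def _resultant(angles_deg: np.ndarray, responses: np.ndarray, fold: int,
               rectify: bool) -> complex:
    r = np.clip(responses, 0.0, None) if rectify else responses
    total = float(np.sum(r))
    if total <= 0:
        return complex(math.nan, math.nan)
    z = np.sum(r * np.exp(1j * fold * np.deg2rad(angles_deg))) / total
    return complex(z)


def orientation_index(curve, responses=None, rectify: bool = True) -> float:
    """1 - CV: magnitude of the doubled-angle resultant; NaN if no response."""
    angles, resp = _angles_responses(curve, responses)
    distinct = np.unique(angles % 180.0)
    if len(distinct) < 3 or (distinct.max() - distinct.min()) < 135.0 - 1e-9:
        raise ValidationError("need >= 3 distinct angles spanning >= 135 deg in direction space")
    return abs(_resultant(angles, resp, fold=2, rectify=rectify))


def direction_index(curve, responses=None, rectify: bool = True) -> float:
    """1 - DCV: magnitude of the direction-space resultant; NaN if no response."""
    angles, resp = _angles_responses(curve, responses)
    if len(np.unique(angles % 360.0)) < 4:
        raise ValidationError("need >= 4 distinct directions")
    return abs(_resultant(angles, resp, fold=1, rectify=rectify))


def preferred_orientation_vector(curve, responses=None, rectify: bool = True) -> float:
    """Orientation preference (deg, [0, 180)) from the doubled-angle resultant."""
    angles, resp = _angles_responses(curve, responses)
    z = _resultant(angles, resp, fold=2, rectify=rectify)
    if z != z:  # NaN
        return math.nan
    return (math.degrees(cmath.phase(z)) / 2.0) % 180.0


@dataclass
class DoubleGaussianFit:
    """Double-Gaussian direction-tuning fit: lobes at theta_p and theta_p+180."""

    pref_direction: float
    amp_pref: float
    amp_null: float
    width: float
    baseline: float
    r_squared: float
    fit_ok: bool


def _wrapped(a):
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def _dg_model(theta, baseline, a1, a2, theta_p, sigma):
    g1 = np.exp(-(_wrapped(theta - theta_p) ** 2) / (2 * sigma ** 2))
    g2 = np.exp(-(_wrapped(theta - theta_p - 180.0) ** 2) / (2 * sigma ** 2))
    return baseline + a1 * g1 + a2 * g2


def fit_double_gaussian(curve, responses=None) -> DoubleGaussianFit:
    """Fit R(theta) = B + A1 G(theta - theta_p) + A2 G(theta - theta_p - 180).

    Shared lobe width, 180-deg lobe separation; deterministic multi-start
    (theta_p at each sampled angle x a small width grid, amplitudes/baseline
    solved linearly) followed by bounded refinement.  ``fit_ok`` is false for
    optimizer failure or explained variance below 0.5.
    """
    angles, resp = _angles_responses(curve, responses)
    if len(angles) < 5:
        raise ValidationError("need >= 5 points for a double-Gaussian fit")
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))

    starts = []
    for theta0 in angles:
        for sigma0 in (15.0, 30.0, 60.0):
            g1 = np.exp(-(_wrapped(angles - theta0) ** 2) / (2 * sigma0 ** 2))
            g2 = np.exp(-(_wrapped(angles - theta0 - 180.0) ** 2) / (2 * sigma0 ** 2))
            X = np.column_stack([np.ones_like(angles), g1, g2])
            coef, *_ = np.linalg.lstsq(X, resp, rcond=None)
            sse = float(np.sum((X @ coef - resp) ** 2))
            starts.append((sse, coef[0], max(coef[1], 0.0), max(coef[2], 0.0), theta0, sigma0))
    starts.sort(key=lambda s: (s[0], s[4], s[5]))

    lb = [-np.inf, 0.0, 0.0, -360.0, 5.0]
    ub = [np.inf, np.inf, np.inf, 720.0, 180.0]

    def residual(x):
        return _dg_model(angles, *x) - resp

    best = None
    for sse0, b0, a10, a20, t0, s0 in starts[:5]:
        try:
            sol = least_squares(residual, [b0, a10, a20, t0, s0],
                                bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol.x)
    if best is None:
        return DoubleGaussianFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                                 math.nan, False)
    sse, (baseline, a1, a2, theta_p, sigma) = best
    if a2 > a1:
        a1, a2 = a2, a1
        theta_p += 180.0
    theta_p = float(theta_p % 360.0)
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else math.nan
    fit_ok = bool(ss_tot > 0 and r2 >= 0.5)
    return DoubleGaussianFit(
        pref_direction=theta_p, amp_pref=float(a1), amp_null=float(a2),
        width=float(sigma), baseline=float(baseline),
        r_squared=float(r2) if r2 == r2 else math.nan, fit_ok=fit_ok,
    )
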