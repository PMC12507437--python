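"""Synthetic trial-level datasets with the statistical structure the analysis assumes.

The generator emulates the study design end to end: two stimulus batteries
(B1: 4 orientations x 8 spatial frequencies x 6 contrasts at 4 Hz, drifting
back and forth, 5 repeats; B2: 8 directions x 7 temporal frequencies at spatial
frequency 0.1 cpd and full contrast, unidirectional, 7 repeats; each battery
with one gray-screen blank of matched 4 s duration), four experimental groups,
per-animal random intercepts, and Poisson trial noise on spike counts.

Each ground-truth neuron's mean rate is composed from the same parametric
families the analysis fits, each profile normalized to 1 at its peak:

    rate = background
         + k * dir(theta) * tf_profile(f) * sf_profile(s) * contrast_profile(c)
         - suppression_depth * min(1, (f / 32)^2)

clipped at zero.  Direction tuning is a wrapped double Gaussian with lobes at
the preferred direction and its opposite (anti-preferred amplitude =
``dir_selectivity`` x preferred); back-and-forth stimuli pool the two drift
phases.  TF and SF profiles use the frequency-response model of
:mod:`vistune.frequency`; the contrast profile is a baseline-free Naka-Rushton.
The suppression term is a negative lobe that deepens toward the highest tested
temporal frequency, reproducing below-background responses without a mechanism
claim.  Because the generator's families match the fitting families, parameter
recovery by the analysis pipeline is a meaningful end-to-end check.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import GROUPS, StimulusCondition, TrialObservation, UnitRecord, ValidationError
from .frequency import eval_model

B1_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
B1_SPATIAL_FREQUENCIES = (0.04, 0.08, 0.16, 0.24, 0.32, 0.64, 0.90, 1.25)
B1_CONTRASTS = (0.04, 0.08, 0.16, 0.32, 0.64, 1.0)
B1_TEMPORAL_FREQUENCY = 4.0
B2_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))
B2_TEMPORAL_FREQUENCIES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
B2_SPATIAL_FREQUENCY = 0.1
STIM_DURATION = 4.0
DEFAULT_REPEATS = {"B1": 5, "B2": 7}
SUPPRESSION_REF_TF = 32.0  # highest tested temporal frequency


def make_battery(battery_id: str) -> List[StimulusCondition]:
    """Build the condition list (gratings + one blank) of battery B1 or B2."""
    if battery_id == "B1":
        conds = [
            StimulusCondition(
                kind="grating",
                duration=STIM_DURATION,
                drift_mode="back_and_forth",
                direction=ori,
                spatial_frequency=sf,
                temporal_frequency=B1_TEMPORAL_FREQUENCY,
                contrast=c,
            )
            for ori in B1_ORIENTATIONS
            for sf in B1_SPATIAL_FREQUENCIES
            for c in B1_CONTRASTS
        ]
        conds.append(
            StimulusCondition(kind="blank", duration=STIM_DURATION, drift_mode="back_and_forth")
        )
        return conds
    if battery_id == "B2":
        conds = [
            StimulusCondition(
                kind="grating",
                duration=STIM_DURATION,
                drift_mode="unidirectional",
                direction=d,
                spatial_frequency=B2_SPATIAL_FREQUENCY,
                temporal_frequency=tf,
                contrast=1.0,
            )
            for d in B2_DIRECTIONS
            for tf in B2_TEMPORAL_FREQUENCIES
        ]
        conds.append(
            StimulusCondition(kind="blank", duration=STIM_DURATION, drift_mode="unidirectional")
        )
        return conds
    raise ValidationError(f"unknown battery id {battery_id!r}")


@dataclass
class GroundTruthNeuron:
    """Generative parameters of one simulated unit.

    ``dir_selectivity`` is the ratio of the anti-preferred to the preferred
    lobe amplitude (1 = direction-symmetric, 0 = fully direction selective).
    ``k`` is the peak stimulus-driven rate above background at the preferred
    direction, peak frequencies and full contrast.
    """

    pref_direction: float = 0.0
    dir_selectivity: float = 0.5
    tuning_width: float = 30.0
    k: float = 10.0
    fc: float = 6.0
    fh: float = 1.0
    beta: float = 2.0
    sf_peak: float = 0.05
    sf_broadness: float = 8.0
    background: float = 2.0
    suppression_depth: float = 0.0
    c50: float = 0.16
    n_exp: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k", "background", "suppression_depth", "fh"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sf_broadness <= 1.0:
            raise ValidationError("sf_broadness must be > 1")
        for name in ("tuning_width", "fc", "sf_peak", "c50", "n_exp", "beta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.dir_selectivity <= 1):
            raise ValidationError("dir_selectivity must lie in [0, 1]")
        self.pref_direction = float(self.pref_direction % 360.0)


@lru_cache(maxsize=4096)
def _tf_peak_and_norm(fc: float, fh: float, beta: float) -> Tuple[float, float]:
    """Argmax and peak value of the unnormalized frequency profile over f > 0."""
    grid = np.geomspace(1e-4, 200.0, 2048)
    vals = eval_model(1.0, fc, fh, beta, grid)
    i = int(np.argmax(vals))
    from scipy.optimize import minimize_scalar

    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda lf: -eval_model(1.0, fc, fh, beta, math.exp(lf)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    fstar = math.exp(res.x)
    peak = eval_model(1.0, fc, fh, beta, fstar)
    if peak < vals[i]:
        fstar, peak = float(grid[i]), float(vals[i])
    return float(fstar), float(peak)


def tf_peak_frequency(neuron: GroundTruthNeuron) -> float:
    """Temporal frequency at which the neuron's TF profile peaks."""
    return _tf_peak_and_norm(neuron.fc, neuron.fh, neuron.beta)[0]


def tf_profile(neuron: GroundTruthNeuron, f) -> np.ndarray:
    """TF profile normalized to 1 at its peak."""
    _, peak = _tf_peak_and_norm(neuron.fc, neuron.fh, neuron.beta)
    return eval_model(1.0, neuron.fc, neuron.fh, neuron.beta, f) / peak


def _sf_params(sf_peak: float, broadness: float = 8.0) -> Tuple[float, float, float]:
    # Same model family as TF, with beta = 2.  fc = broadness * sf_peak and
    # fh = sf_peak / sqrt(broadness^2 - 1) place the analytic peak exactly at
    # sf_peak; large broadness gives the shallow, near-low-pass spatial
    # profiles these cells show (they respond robustly well above their
    # preferred SF, which is what makes the fixed-0.1-cpd battery viable).
    fc = broadness * sf_peak
    fh = sf_peak / math.sqrt(broadness ** 2 - 1.0)
    return fc, fh, 2.0


def sf_profile(neuron: GroundTruthNeuron, s) -> np.ndarray:
    """SF profile normalized to 1 at ``sf_peak``."""
    fc, fh, beta = _sf_params(neuron.sf_peak, neuron.sf_broadness)
    peak = eval_model(1.0, fc, fh, beta, neuron.sf_peak)
    return eval_model(1.0, fc, fh, beta, s) / peak


def contrast_profile(neuron: GroundTruthNeuron, c) -> np.ndarray:
    """Baseline-free Naka-Rushton contrast profile normalized to 1 at c = 1."""
    c = np.asarray(c, dtype=float)
    n, c50 = neuron.n_exp, neuron.c50
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(c > 0, c ** n / (c50 ** n + c ** n), 0.0)
    out = raw * (c50 ** n + 1.0)
    return out if out.ndim else float(out)


def _wrapped_diff(a, b):
    return (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0


def dir_tuning(neuron: GroundTruthNeuron, theta) -> np.ndarray:
    """Wrapped double-Gaussian direction tuning, normalized to 1 at preferred."""
    w = neuron.tuning_width
    g1 = np.exp(-(_wrapped_diff(theta, neuron.pref_direction) ** 2) / (2 * w * w))
    g2 = np.exp(-(_wrapped_diff(theta, neuron.pref_direction + 180.0) ** 2) / (2 * w * w))
    raw = g1 + neuron.dir_selectivity * g2
    peak = 1.0 + neuron.dir_selectivity * math.exp(-(180.0 ** 2) / (2 * w * w))
    out = raw / peak
    return out if out.ndim else float(out)


def expected_rate(neuron: GroundTruthNeuron, condition: StimulusCondition) -> float:
    """Mean firing rate (Hz) of a ground-truth neuron for one condition.

    Blanks return the background rate exactly.  Gratings compose the normalized
    profiles multiplicatively on top of background, minus the TF-dependent
    suppression lobe; the result is clipped at zero.
    """
    if condition.is_blank:
        return float(neuron.background)
    theta = condition.direction
    if condition.drift_mode == "back_and_forth":
        drive_dir = 0.5 * (dir_tuning(neuron, theta) + dir_tuning(neuron, theta + 180.0))
    else:
        drive_dir = dir_tuning(neuron, theta)
    drive = (
        drive_dir
        * tf_profile(neuron, condition.temporal_frequency)
        * sf_profile(neuron, condition.spatial_frequency)
        * contrast_profile(neuron, condition.contrast)
    )
    supp = neuron.suppression_depth * min(
        1.0, (condition.temporal_frequency / SUPPRESSION_REF_TF) ** 2
    )
    return float(max(0.0, neuron.background + neuron.k * drive - supp))


def ground_truth_lpi(neuron: GroundTruthNeuron,
                     tested_tfs: Sequence[float] = B2_TEMPORAL_FREQUENCIES) -> float:
    """The neuron's noise-free low-pass index over the tested TF grid."""
    p = eval_model(1.0, neuron.fc, neuron.fh, neuron.beta, np.asarray(tested_tfs))
    return float(p[0] / np.max(p))


def solve_fh_for_lpi(target_lpi: float, fc: float, beta: float = 2.0,
                     tested_tfs: Sequence[float] = B2_TEMPORAL_FREQUENCIES) -> float:
    """Low-frequency corner ``fh`` giving a requested low-pass index.

    The LPI of the model over the tested grid decreases from 1 (fh -> 0, pure
    low-pass) toward 0 as fh grows; the unique crossing is found by bisection
    on log10(fh).
    """
    if not (0 < target_lpi < 1):
        raise ValidationError("target_lpi must lie in (0, 1)")
    tfs = np.asarray(tested_tfs, dtype=float)

    def lpi_of(log_fh: float) -> float:
        p = eval_model(1.0, fc, 10.0 ** log_fh, beta, tfs)
        return float(p[0] / np.max(p))

    lo, hi = -8.0, 3.0
    if lpi_of(lo) < target_lpi:
        return 10.0 ** lo
    if lpi_of(hi) > target_lpi:  # pragma: no cover - extremely low targets
        return 10.0 ** hi
    root = brentq(lambda x: lpi_of(x) - target_lpi, lo, hi, xtol=1e-12)
    return float(10.0 ** root)


# ---------------------------------------------------------------------------
# Population sampling


DEFAULT_PARAMETER_DISTRIBUTIONS: Dict[str, dict] = {
    "pref_direction": {"dist": "uniform", "low": 0.0, "high": 360.0},
    "dir_selectivity": {"dist": "uniform", "low": 0.1, "high": 0.9},
    "tuning_width": {"dist": "norm", "loc": 30.0, "scale": 8.0, "low": 15.0, "high": 60.0},
    "k": {"dist": "norm", "loc": 8.0, "scale": 3.0, "low": 2.0, "high": 30.0},
    "fc": {"dist": "lognorm", "loc": math.log(6.0), "scale": 0.4, "low": 1.0, "high": 24.0},
    "lpi": {"dist": "norm", "loc": 0.20, "scale": 0.08, "low": 0.02, "high": 0.95},
    "beta": {"dist": "const", "loc": 2.0},
    "sf_peak": {"dist": "lognorm", "loc": math.log(0.045), "scale": 0.35, "low": 0.01, "high": 0.5},
    "sf_broadness": {"dist": "const", "loc": 8.0},
    "background": {"dist": "norm", "loc": 2.6, "scale": 1.0, "low": 0.2, "high": 40.0},
    "suppression_depth": {"dist": "norm", "loc": 1.0, "scale": 0.5, "low": 0.0, "high": 20.0},
    "c50": {"dist": "norm", "loc": 0.16, "scale": 0.05, "low": 0.05, "high": 0.6},
    "n_exp": {"dist": "norm", "loc": 2.0, "scale": 0.5, "low": 1.0, "high": 4.0},
}

DEFAULT_ANIMAL_SD: Dict[str, float] = {"background": 0.5, "k": 0.15, "lpi": 0.03}


@dataclass
class GroupSpec:
    """Simulation specification of one experimental group.

    ``parameter_distributions`` overrides entries of
    :data:`DEFAULT_PARAMETER_DISTRIBUTIONS`; the special key ``lpi`` is the
    target low-pass index from which each unit's ``fh`` is solved.
    ``animal_sd`` gives per-animal random-intercept scales: additive (Hz) on
    ``background``, multiplicative (lognormal sigma) on ``k``, additive on the
    ``lpi`` target.  ``dispersion`` > 1 switches the trial noise from Poisson
    to a gamma-mixed Poisson with that variance inflation factor.
    """

    group: str
    n_animals: int
    units_per_animal: int
    parameter_distributions: Dict[str, dict] = field(default_factory=dict)
    animal_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANIMAL_SD))
    dispersion: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.units_per_animal < 1:
            raise ValidationError("units_per_animal must be >= 1")
        if self.dispersion < 1.0:
            raise ValidationError("dispersion must be >= 1")

    def distribution(self, name: str) -> dict:
        base = dict(DEFAULT_PARAMETER_DISTRIBUTIONS[name])
        base.update(self.parameter_distributions.get(name, {}))
        return base


def _draw(dist: Mapping, rng: np.random.Generator) -> float:
    kind = dist.get("dist", "norm")
    low = dist.get("low", -math.inf)
    high = dist.get("high", math.inf)
    if kind == "const":
        return float(dist["loc"])
    if kind == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    for _ in range(1000):
        if kind == "norm":
            x = rng.normal(dist["loc"], dist["scale"])
        elif kind == "lognorm":
            x = math.exp(rng.normal(dist["loc"], dist["scale"]))
        else:
            raise ValidationError(f"unknown distribution kind {kind!r}")
        if low <= x <= high:
            return float(x)
    raise ValidationError(f"truncated sampling failed for {dist}")


def sample_neuron(spec: GroupSpec, rng: np.random.Generator,
                  animal_effects: Mapping[str, float]) -> Tuple[GroundTruthNeuron, float]:
    """Draw one ground-truth neuron under a group spec and animal intercepts."""
    p = {name: _draw(spec.distribution(name), rng)
         for name in DEFAULT_PARAMETER_DISTRIBUTIONS}
    background = max(0.0, p["background"] + animal_effects.get("background", 0.0))
    k = p["k"] * math.exp(animal_effects.get("k_log", 0.0))
    lpi_target = float(np.clip(p["lpi"] + animal_effects.get("lpi", 0.0), 0.01, 0.99))
    fh = solve_fh_for_lpi(lpi_target, p["fc"], p["beta"])
    neuron = GroundTruthNeuron(
        pref_direction=p["pref_direction"],
        dir_selectivity=p["dir_selectivity"],
        tuning_width=p["tuning_width"],
        k=k,
        fc=p["fc"],
        fh=fh,
        beta=p["beta"],
        sf_peak=p["sf_peak"],
        sf_broadness=p["sf_broadness"],
        background=background,
        suppression_depth=p["suppression_depth"],
        c50=p["c50"],
        n_exp=p["n_exp"],
    )
    return neuron, lpi_target


def simulate_dataset(
    specs: Sequence[GroupSpec],
    batteries: Sequence[str] = ("B1", "B2"),
    repeats: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> Tuple[List[UnitRecord], pd.DataFrame]:
    """Simulate trial data for all groups; returns records + ground-truth table.

    Per-trial rates are Poisson spike counts over the stimulus window divided
    by the duration.  The same seed always yields the identical dataset.
    """
    if repeats is None:
        repeats = DEFAULT_REPEATS
    conditions = {b: make_battery(b) for b in batteries}
    root = np.random.SeedSequence(seed)
    group_seeds = root.spawn(len(specs))
    records: List[UnitRecord] = []
    truth_rows = []
    for spec, gseed in zip(specs, group_seeds):
        rng = np.random.default_rng(
            gseed if spec.seed is None else np.random.SeedSequence(spec.seed)
        )
        for a in range(spec.n_animals):
            animal_id = f"{spec.group}-A{a:02d}"
            hemisphere = "left" if a % 2 == 0 else "right"
            effects = {
                "background": rng.normal(0.0, spec.animal_sd.get("background", 0.0)),
                "k_log": rng.normal(0.0, spec.animal_sd.get("k", 0.0)),
                "lpi": rng.normal(0.0, spec.animal_sd.get("lpi", 0.0)),
            }
            for u in range(spec.units_per_animal):
                unit_id = f"{spec.group}-A{a:02d}-U{u:03d}"
                neuron, lpi_target = sample_neuron(spec, rng, effects)
                rec = UnitRecord(
                    unit_id=unit_id, animal_id=animal_id,
                    hemisphere=hemisphere, group=spec.group,
                )
                for b in batteries:
                    conds = conditions[b]
                    mu = np.array([expected_rate(neuron, c) for c in conds])
                    nrep = int(repeats[b])
                    lam = mu[None, :] * STIM_DURATION
                    if spec.dispersion > 1.0:
                        shape = 1.0 / (spec.dispersion - 1.0)
                        lam = lam * rng.gamma(shape, 1.0 / shape, size=(nrep, len(conds)))
                    counts = rng.poisson(np.broadcast_to(lam, (nrep, len(conds))))
                    rates = counts / STIM_DURATION
                    for j, cond in enumerate(conds):
                        for r in range(nrep):
                            rec.trials.append(
                                TrialObservation(
                                    unit_id=unit_id, condition=cond,
                                    trial_index=r, rate_mean=float(rates[r, j]),
                                )
                            )
                records.append(rec)
                row = {
                    "unit": unit_id, "animal": animal_id, "group": spec.group,
                    "hemisphere": hemisphere, "lpi_target": lpi_target,
                    "lpi_true": ground_truth_lpi(neuron),
                    "tf_peak_true": tf_peak_frequency(neuron),
                }
                row.update({f"{name}": getattr(neuron, name)
                            for name in ("pref_direction", "dir_selectivity", "tuning_width",
                                         "k", "fc", "fh", "beta", "sf_peak", "background",
                                         "suppression_depth", "c50", "n_exp")})
                truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def default_group_specs(n_animals: int = 6, units_per_animal: int = 20) -> List[GroupSpec]:
    """Group specifications at the study's reported population values.

    Low-pass index means (0.20 control, 0.35 EO1contra, 0.22 EO1ipsi, 0.33
    EO2), background rates (2.6 / 6.6 / 11.1 / 6.6 Hz) and suppression depths
    differ by group; all other tuning parameters share the same distributions.
    """
    settings = {
        "control": {"lpi": 0.20, "background": 2.6, "suppression": 1.0},
        "EO1contra": {"lpi": 0.35, "background": 6.6, "suppression": 3.4},
        "EO1ipsi": {"lpi": 0.22, "background": 11.1, "suppression": 7.0},
        "EO2": {"lpi": 0.33, "background": 6.6, "suppression": 2.8},
    }
    specs = []
    for group, s in settings.items():
        specs.append(
            GroupSpec(
                group=group,
                n_animals=n_animals,
                units_per_animal=units_per_animal,
                parameter_distributions={
                    "lpi": {"loc": s["lpi"]},
                    "background": {"loc": s["background"]},
                    "suppression_depth": {"loc": s["suppression"], "scale": s["suppression"] / 3},
                },
            )
        )
    return specs
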