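"""Population statistics across experimental groups.

Per-cell index values are compared across groups with a linear mixed-effects
model: treatment group as fixed effect (control as the reference level) and a
random intercept per animal, estimated by REML with Wald tests on the fixed
effects.  Metrics that can be infinite for many cells (octave bandwidths of
low-/high-pass cells) are first converted to ranks, with all infinite values
sharing the top average rank.  Distributions of angle preferences are compared
across groups with a chi-square test of homogeneity on 45-degree bins.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

REFERENCE_GROUP = "control"


@dataclass
class GroupModelResult:
    """Mixed-model group estimates for one metric."""

    metric: str
    reference: str
    group_means: Dict[str, float]
    group_se: Dict[str, float]
    group_medians: Dict[str, float]
    contrasts_vs_reference: Dict[str, Tuple[float, float, float]]  # (estimate, se, p)
    animal_effects: Dict[str, float]
    n_cells: Dict[str, int]
    n_animals: Dict[str, int]
    animal_var: float = math.nan
    residual_var: float = math.nan
    degenerate: bool = False
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "reference": self.reference,
            "group_means": self.group_means,
            "group_se": self.group_se,
            "group_medians": self.group_medians,
            "contrasts_vs_reference": {
                g: {"estimate": e, "se": s, "p": p}
                for g, (e, s, p) in self.contrasts_vs_reference.items()
            },
            "animal_effects": self.animal_effects,
            "n_cells": self.n_cells,
            "n_animals": self.n_animals,
            "animal_var": self.animal_var,
            "residual_var": self.residual_var,
            "degenerate": self.degenerate,
            "notes": self.notes,
        }


def _prepare(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    for col in ("value", "animal", "group"):
        if col not in df.columns:
            raise ValidationError(f"fit_lmem input needs a {col!r} column")
    vals = np.asarray(df["value"], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError(
            f"metric {metric!r} contains non-finite values; rank-transform first"
        )
    return df


def fit_lmem(df: pd.DataFrame, metric: str = "value") -> GroupModelResult:
    """Random-intercept-per-animal model with group fixed effects.

    ``df`` needs columns ``value``, ``animal``, ``group``.  Groups with a
    single animal are allowed with a recorded note.  Degenerate inputs (zero
    within-group variance) fall back to exact group means with a flag.
    """
    import statsmodels.formula.api as smf

    df = _prepare(df, metric).copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValidationError("fit_lmem needs >= 2 groups")
    reference = REFERENCE_GROUP if REFERENCE_GROUP in groups else groups[0]
    others = [g for g in groups if g != reference]

    n_cells = df.groupby("group")["value"].size().to_dict()
    n_animals = df.groupby("group")["animal"].nunique().to_dict()
    medians = df.groupby("group")["value"].median().to_dict()
    notes = []
    for g, na in n_animals.items():
        if na < 2:
            msg = f"group {g} has a single animal; animal variance poorly identified"
            notes.append(msg)
            warnings.warn(msg)

    within_var = df.groupby("group")["value"].var(ddof=0).fillna(0.0)
    if float(within_var.max()) < 1e-24 or float(df["value"].var(ddof=0)) < 1e-24:
        means = df.groupby("group")["value"].mean().to_dict()
        contrasts = {g: (means[g] - means[reference], 0.0, math.nan) for g in others}
        return GroupModelResult(
            metric=metric, reference=reference,
            group_means={g: float(means[g]) for g in groups},
            group_se={g: 0.0 for g in groups},
            group_medians={g: float(medians[g]) for g in groups},
            contrasts_vs_reference=contrasts,
            animal_effects={}, n_cells=n_cells, n_animals=n_animals,
            animal_var=0.0, residual_var=0.0, degenerate=True,
            notes=notes + ["zero within-group variance; exact group means reported"],
        )

    formula = f"value ~ C(group, Treatment('{reference}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["animal"])
        try:
            result = model.fit(reml=True)
        except Exception as exc:
            notes.append(f"mixed model failed ({exc}); ordinary least squares fallback")
            result = smf.ols(formula, df).fit()

    params = result.params
    cov = result.cov_params()

    def term(g: str) -> str:
        return f"C(group, Treatment('{reference}'))[T.{g}]"

    group_means, group_se = {}, {}
    intercept = float(params["Intercept"])
    group_means[reference] = intercept
    group_se[reference] = float(math.sqrt(cov.loc["Intercept", "Intercept"]))
    contrasts = {}
    for g in others:
        t = term(g)
        est = float(params[t])
        var = (
            cov.loc["Intercept", "Intercept"]
            + cov.loc[t, t]
            + 2.0 * cov.loc["Intercept", t]
        )
        group_means[g] = intercept + est
        group_se[g] = float(math.sqrt(max(var, 0.0)))
        se = float(math.sqrt(cov.loc[t, t]))
        p = float(result.pvalues[t])
        contrasts[g] = (est, se, p)

    animal_effects = {}
    animal_var = residual_var = math.nan
    if hasattr(result, "random_effects"):
        animal_effects = {
            str(a): float(np.asarray(re).ravel()[0])
            for a, re in result.random_effects.items()
        }
        animal_var = float(np.asarray(result.cov_re).ravel()[0])
        residual_var = float(result.scale)
    return GroupModelResult(
        metric=metric, reference=reference,
        group_means=group_means, group_se=group_se,
        group_medians={g: float(medians[g]) for g in groups},
        contrasts_vs_reference=contrasts,
        animal_effects=animal_effects,
        n_cells=n_cells, n_animals=n_animals,
        animal_var=animal_var, residual_var=residual_var,
        degenerate=False, notes=notes,
    )


def rank_transform_with_infinities(values, infinite_mask=None) -> np.ndarray:
    """Average ranks with all infinite values tied above every finite value.

    Suitable as the response variable of :func:`fit_lmem` when many cells have
    infinite bandwidth.
    """
    v = np.asarray(values, dtype=float)
    if infinite_mask is not None:
        v = np.where(np.asarray(infinite_mask, dtype=bool), math.inf, v)
    if np.any(np.isnan(v)):
        raise ValidationError("rank transform does not accept NaN")
    return stats.rankdata(v, method="average")


def preference_distribution_test(
    preferences: Sequence[float],
    groups: Sequence[str],
    bin_width: float = 45.0,
    space: float = 360.0,
) -> Tuple[float, float, pd.DataFrame]:
    """Chi-square homogeneity test of binned angle preferences across groups.

    ``space`` is 360 for direction preferences, 180 for orientation
    preferences.  Bins with zero counts in every group are dropped with a
    warning.  Returns (statistic, p, contingency table).
    """
    prefs = np.asarray(preferences, dtype=float) % space
    groups = np.asarray(groups)
    if len(prefs) != len(groups):
        raise ValidationError("preferences and groups must have equal length")
    uniq = sorted(set(groups.tolist()))
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    nbins = int(round(space / bin_width))
    idx = np.minimum((prefs / bin_width).astype(int), nbins - 1)
    table = np.zeros((len(uniq), nbins), dtype=int)
    for gi, g in enumerate(uniq):
        sel = idx[groups == g]
        for b in sel:
            table[gi, b] += 1
    keep = table.sum(axis=0) > 0
    if not np.all(keep):
        warnings.warn("dropping angle bins with zero counts in all groups")
        table = table[:, keep]
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    cols = [f"bin{b}" for b in range(table.shape[1])]
    return float(stat), float(p), pd.DataFrame(table, index=uniq, columns=cols)
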