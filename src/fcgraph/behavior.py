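"""Behavioural analysis: normalized scores, interaction model, power.

Performance on degraded trials is expressed relative to each
participant's own non-degraded baseline::

    normalized score = (raw - chance) / (baseline - chance) - 1

with chance = 0.5 for the same-different task. A score of 0 means no
change from baseline, -1 means chance performance, positive values a
benefit. One integrated score per participant x task x degradation x
cutoff cell enters a linear model with the full three-way interaction of
cutoff (categorical, 5 levels), task and degradation; the model is
compared by an F-test against the reduced main-effects-only model.
Sample-size adequacy is assessed with the noncentral-F power of the
multiple-regression omnibus test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .inference import vif as _vif

__all__ = [
    "collapse_response",
    "normalized_score",
    "integrate_scores",
    "fit_behavior_model",
    "power_f2",
    "PowerSpec",
    "BehaviorModelResult",
]

CHANCE = 0.5

_SAME = {"Same", "Maybe Same", "Same not sure"}
_DIFFERENT = {"Different not sure", "Maybe Different", "Different"}


def collapse_response(response6: str) -> str:
    """Collapse the 6-point confidence response to 'same' / 'different'."""
    if response6 in _SAME:
        return "same"
    if response6 in _DIFFERENT:
        return "different"
    raise ValueError(f"unknown response label {response6!r}")


def normalized_score(raw, baseline, chance: float = CHANCE):
    """Baseline-referenced performance score.

    ``(raw - chance) / (baseline - chance) - 1``: 0 at baseline, -1 at
    chance. Requires above-chance baseline performance, otherwise the
    normalization is undefined.
    """
    raw = np.asarray(raw, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= chance):
        raise ValueError("baseline must exceed chance for normalization")
    out = (raw - chance) / (baseline - chance) - 1.0
    return float(out) if out.ndim == 0 else out


def integrate_scores(trials: pd.DataFrame, chance: float = CHANCE) -> pd.DataFrame:
    """One normalized score per participant x task x degradation x cutoff.

    The raw score of a cell is its proportion of correct trials; the
    baseline is the proportion correct on that participant's non-degraded
    block for the same task. At study scale (15 participants) this yields
    300 integrated values.
    """
    required = {"participant", "task", "degradation", "cutoff", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    baseline_rows = trials[trials["degradation"] == "none"]
    if baseline_rows.empty:
        raise ValueError("no baseline (non-degraded) trials present")
    baselines = (
        baseline_rows.groupby(["participant", "task"], observed=True)["correct"]
        .mean()
        .rename("baseline")
    )
    degraded = trials[trials["degradation"] != "none"]
    cells = (
        degraded.groupby(
            ["participant", "task", "degradation", "cutoff"], observed=True
        )["correct"]
        .agg(raw_score="mean", n_trials="size")
        .reset_index()
    )
    if (cells["n_trials"] == 0).any():
        raise ValueError("empty design cell")
    cells = cells.merge(baselines, on=["participant", "task"], validate="m:1")
    cells["chance"] = chance
    cells["score"] = normalized_score(
        cells["raw_score"].to_numpy(), cells["baseline"].to_numpy(), chance
    )
    return cells


@dataclass
class BehaviorModelResult:
    """Full-versus-reduced comparison of the behavioural interaction model."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    r2_adj: float
    vif: dict[str, float]
    full_params: pd.Series
    n_obs: int


def fit_behavior_model(scores: pd.DataFrame) -> BehaviorModelResult:
    """Linear model of normalized scores with the cutoff x task x degradation
    interaction, F-compared against the main-effects-only model.

    Cutoff enters as a 5-level categorical factor, so the full model has
    20 coefficients and the reduction tests 13 interaction terms: at
    study scale (300 observations) the comparison has (13, 280) degrees
    of freedom. Collinearity of the main effects is screened with VIFs
    on the interaction-free model.
    """
    data = scores.copy()
    for col in ("task", "degradation"):
        if data[col].nunique() < 2:
            raise ValueError(f"need at least 2 levels of {col}")
    if data["cutoff"].nunique() < 2:
        raise ValueError("need at least 2 cutoff levels")
    full = smf.ols("score ~ C(cutoff) * task * degradation", data=data).fit()
    reduced = smf.ols("score ~ C(cutoff) + task + degradation", data=data).fit()
    df_num = int(full.df_model - reduced.df_model)
    df_den = int(full.df_resid)
    f_stat = (
        (reduced.ssr - full.ssr) / df_num
    ) / (full.ssr / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    vifs = _vif(data, ["C(cutoff)", "task", "degradation"], response="score")
    return BehaviorModelResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        r2_adj=float(full.rsquared_adj),
        vif=vifs,
        full_params=full.params,
        n_obs=int(full.nobs),
    )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the noncentral-F power computation for a regression omnibus test."""

    r_squared: float
    u: int  # numerator df (tested predictors)
    n: int  # observations
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.r_squared < 1.0:
            raise ValueError("r_squared must lie in (0, 1)")
        if self.n - self.u - 1 < 1:
            raise ValueError("denominator df n - u - 1 must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def f2(self) -> float:
        """Cohen's effect size f^2 = R^2 / (1 - R^2)."""
        return self.r_squared / (1.0 - self.r_squared)

    @property
    def v(self) -> int:
        return self.n - self.u - 1

    @property
    def noncentrality(self) -> float:
        return self.f2 * (self.u + self.v + 1)


def power_f2(spec: PowerSpec) -> float:
    """Power of the F-test of ``u`` predictors at effect size f^2.

    ``power = P[F'(u, v, lambda) > F_crit(1 - alpha; u, v)]`` with
    ``lambda = f^2 (u + v + 1)``. With lambda = 0 this equals alpha.
    """
    f_crit = stats.f.ppf(1.0 - spec.alpha, spec.u, spec.v)
    return float(stats.ncf.sf(f_crit, spec.u, spec.v, spec.noncentrality))
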