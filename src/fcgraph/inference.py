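"""Mixed-model inference on metric tables.

The core question is whether a graph metric (AUC-integrated over
densities) varies with the attention x degradation x cutoff design.
Each response is modelled with a Gaussian linear mixed model: fixed
effects are the full factorial interaction, the random part is a
per-participant intercept, optionally extended with random slopes of
the fixed effects. Inference is by likelihood-ratio tests of models fit
with maximum likelihood: the full model against an intercept-only null
(same random structure), then single-term deletions respecting
marginality. Per-ROI analyses run one such model per node and control
the false discovery rate across ROIs with Benjamini-Hochberg; FDR
survivors get post-hoc per-condition cutoff-slope models (cutoff
numeric 1..5, participant random intercept) with their own FDR.

Diagnostics mirror standard mixed-model practice: generalized variance
inflation factors on the interaction-free fixed design, leave-one-
participant-out stability of the fixed estimates, parametric bootstrap
confidence intervals, and Nakagawa-Schielzeth marginal/conditional R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "RoiInferenceResult",
    "InferenceConfig",
    "fit_lmm",
    "lrt_full_null",
    "drop1_lrt",
    "fdr_bh",
    "posthoc_condition_slopes",
    "vif",
    "r2_mixed",
    "parametric_bootstrap_ci",
    "model_stability",
    "per_roi_pipeline",
]

CONDITION_CODES = {  # two-letter condition shorthands used in reports
    ("melody", "spectral"): "MS",
    ("melody", "temporal"): "MT",
    ("sentence", "spectral"): "SS",
    ("sentence", "temporal"): "ST",
}


@dataclass
class ModelSpec:
    """Structure of the mixed model for one metric response.

    ``cutoff_coding`` switches between a single linear cutoff slope
    (``"numeric"``) and a 5-level factor (``"categorical"``; full-null
    comparisons then have 19 fixed df at study scale). The random part
    is per-participant: ``"intercept"``, ``"uncorrelated_slopes"`` (a
    diagonal covariance over intercept + fixed-effect slopes) or
    ``"slopes"`` (unstructured covariance). Fits that fail or go
    singular fall back down this ladder, and the structure actually
    used is recorded on the result.
    """

    response: str = "value"
    cutoff_coding: str = "numeric"
    random_structure: str = "intercept"
    group: str = "participant"

    def cutoff_term(self) -> str:
        if self.cutoff_coding == "numeric":
            return "cutoff"
        if self.cutoff_coding == "categorical":
            return "C(cutoff)"
        raise ValueError(f"unknown cutoff coding {self.cutoff_coding!r}")

    def fixed_formula(self, full: bool = True) -> str:
        return f"attention * degradation * {self.cutoff_term()}" if full else "1"


@dataclass
class FitResult:
    """A fitted Gaussian LMM plus everything needed to reuse its design."""

    params: pd.Series
    loglik: float
    converged: bool
    singular: bool
    cov_re: np.ndarray
    scale: float
    random_structure_used: str
    exog: np.ndarray
    exog_names: list[str]
    exog_re: np.ndarray
    groups: np.ndarray
    endog: np.ndarray
    formula: str

    @property
    def n_fixed(self) -> int:
        return self.exog.shape[1]

    @property
    def aic(self) -> float:
        k = self.n_fixed + self.cov_re.shape[0] * (self.cov_re.shape[0] + 1) // 2 + 1
        return 2.0 * k - 2.0 * self.loglik


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested ML fits."""

    statistic: float
    df: int
    p: float
    aic: float
    r2m: float
    r2c: float


@dataclass
class RoiInferenceResult:
    """Per-ROI model-comparison summary."""

    roi: int | str
    full_null: LRTResult
    p_fdr: float
    significant: bool
    slope: float
    failed: bool = False
    drop1: dict[str, LRTResult] = field(default_factory=dict)
    posthoc: list[dict] = field(default_factory=list)


def _build_design(table: pd.DataFrame, formula: str):
    mat = patsy.dmatrix(formula, table, return_type="dataframe")
    return np.asarray(mat), list(mat.columns)


def _random_design(exog: np.ndarray, structure: str) -> np.ndarray:
    if structure == "intercept":
        return np.ones((exog.shape[0], 1))
    return exog  # slopes of all fixed effects (intercept included)


@dataclass
class _FitRes:
    """Back-transformed essentials of one ML fit (response was standardized)."""

    fe_params: np.ndarray
    llf: float
    converged: bool
    cov_re: np.ndarray
    scale: float


def _fit_arrays(
    y: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    structure: str,
) -> tuple[_FitRes, bool]:
    """Fit one ML LMM, returning (result, singular flag).

    The response is standardized internally for numerical stability
    (metric AUCs have variances around 1e-3, which upsets the optimizer)
    and every estimate is transformed back to the original scale; the
    log-likelihood is corrected by the Jacobian term ``-n log s`` so
    likelihood ratios between fits on the same rows are unaffected.
    """
    s = float(np.std(y))
    # an (almost) constant response has no variance to partition
    degenerate = not np.isfinite(s) or s <= 1e-12 * (abs(float(np.mean(y))) + 1.0)
    if degenerate:
        s = 1.0
    ys = y / s
    exog_re = _random_design(exog, structure)
    model = MixedLM(ys, exog, groups=groups, exog_re=exog_re)
    free = None
    if structure == "uncorrelated_slopes":
        k = exog_re.shape[1]
        free = MixedLMParams.from_components(
            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(k)
        )
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "cg"):  # retry ladder for hard fits
            try:
                res = model.fit(reml=False, free=free, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and np.isfinite(res.llf):
                break
    if res is None:
        raise np.linalg.LinAlgError("mixed-model optimization failed")
    cov_re = np.atleast_2d(np.asarray(res.cov_re)) * s**2
    diag = np.diag(cov_re)
    scale = float(res.scale) * s**2
    singular = degenerate or bool(np.any(diag <= 1e-10 * max(scale, 1e-300)))
    try:
        eigmin = np.linalg.eigvalsh(cov_re).min()
        singular = singular or eigmin <= 1e-12 * max(np.abs(diag).max(), 1e-300)
    except np.linalg.LinAlgError:
        singular = True
    out = _FitRes(
        fe_params=np.asarray(res.fe_params) * s,
        llf=float(res.llf) - len(y) * np.log(s),
        converged=bool(res.converged),
        cov_re=cov_re,
        scale=scale,
    )
    return out, singular


_FALLBACK = {"slopes": "uncorrelated_slopes", "uncorrelated_slopes": "intercept"}


def fit_lmm(table: pd.DataFrame, spec: ModelSpec, full: bool = True) -> FitResult:
    """Fit the mixed model described by ``spec`` by maximum likelihood.

    ML (not REML) estimation throughout, so that likelihood-ratio
    comparisons between fits are valid. If a slopes-structure fit fails
    to converge or is singular, the random structure falls back
    (unstructured -> uncorrelated -> intercept-only); the structure that
    produced the returned fit is recorded.
    """
    y = table[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    groups = table[spec.group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 participants")
    formula = spec.fixed_formula(full)
    exog, names = _build_design(table, formula)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    structure = spec.random_structure
    while True:
        try:
            res, singular = _fit_arrays(y, exog, groups, structure)
            ok = bool(res.converged) and np.isfinite(res.llf)
        except (np.linalg.LinAlgError, ValueError):
            ok, singular = False, True
        if ok and not singular:
            break
        if structure in _FALLBACK:
            structure = _FALLBACK[structure]
            continue
        if not ok:
            raise RuntimeError("intercept-only mixed model failed to converge")
        break  # singular but converged at the bottom of the ladder: accept
    return FitResult(
        params=pd.Series(np.asarray(res.fe_params), index=names),
        loglik=float(res.llf),
        converged=bool(res.converged),
        singular=singular,
        cov_re=np.atleast_2d(np.asarray(res.cov_re)),
        scale=float(res.scale),
        random_structure_used=structure,
        exog=exog,
        exog_names=names,
        exog_re=_random_design(exog, structure),
        groups=groups,
        endog=y,
        formula=formula,
    )


def r2_mixed(fit: FitResult) -> tuple[float, float]:
    """Nakagawa-Schielzeth marginal and conditional R² of a Gaussian LMM.

    Marginal R² is the fixed-effect variance share; conditional R² adds
    the random-effect variance. The random-effect variance is the mean
    over observations of ``z_i' G z_i`` so the result is exact under
    random slopes too.
    """
    if not fit.converged:
        raise ValueError("R² undefined for a non-converged fit")
    var_f = float(np.var(fit.exog @ fit.params.to_numpy()))
    zgz = np.einsum("ij,jk,ik->i", fit.exog_re, fit.cov_re, fit.exog_re)
    var_r = float(np.mean(zgz))
    denom = var_f + var_r + fit.scale
    return var_f / denom, (var_f + var_r) / denom


def lrt_full_null(full: FitResult, null: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on identical rows.

    ``statistic = 2 (llf_full - llf_null)`` (clipped at 0), df = the
    difference in fixed-effect parameter counts, p from the chi-squared
    upper tail. The marginal/conditional R² of the full model ride
    along.
    """
    if full.endog.shape != null.endog.shape or not np.allclose(full.endog, null.endog):
        raise ValueError("fits compare different data")
    df = full.n_fixed - null.n_fixed
    if df < 0:
        raise ValueError("models are not nested (null has more parameters)")
    statistic = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(statistic, df)) if df > 0 and statistic > 0 else 1.0
    r2m, r2c = r2_mixed(full)
    return LRTResult(statistic, df, p, full.aic, r2m, r2c)


def _maximal_terms(spec: ModelSpec) -> list[str]:
    # the full factorial has a single maximal term: the three-way interaction
    return [f"attention:degradation:{spec.cutoff_term()}"]


def drop1_lrt(
    full: FitResult, table: pd.DataFrame, spec: ModelSpec, terms=None
) -> dict[str, LRTResult]:
    """Single-term deletion tests respecting marginality.

    Only terms not contained in any retained higher-order term may be
    dropped; for the full factorial model that is the three-way
    interaction alone (its df is 1 with numeric cutoff, 4 with the
    5-level categorical coding). Each reduced model keeps the random
    structure of the full fit and is compared by an ML likelihood-ratio
    test.
    """
    maximal = _maximal_terms(spec)
    terms = list(terms) if terms is not None else maximal
    results = {}
    for term in terms:
        if term not in maximal:
            raise ValueError(
                f"cannot drop {term!r}: it is marginal to a retained interaction"
            )
        reduced_formula = f"{spec.fixed_formula(True)} - {term}"
        exog, names = _build_design(table, reduced_formula)
        y = table[spec.response].to_numpy(dtype=float)
        groups = table[spec.group].to_numpy()
        res, singular = _fit_arrays(y, exog, groups, full.random_structure_used)
        df = full.n_fixed - exog.shape[1]
        statistic = max(0.0, 2.0 * (full.loglik - float(res.llf)))
        p = float(stats.chi2.sf(statistic, df))
        r2m, r2c = r2_mixed(full)
        results[term] = LRTResult(statistic, df, p, full.aic, r2m, r2c)
    return results


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); adjusted p are monotone
    in the raw p and never smaller than them.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def posthoc_condition_slopes(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[FitResult, LRTResult]:
    """Cutoff-slope model for one ROI in one attention x degradation condition.

    ``value ~ cutoff`` with cutoff numeric 1..5 and a per-participant
    random intercept, compared against the intercept-only model. A
    negative slope means the metric decreases as degradation weakens,
    i.e. increases with degradation strength.
    """
    spec = spec or ModelSpec()
    if table["cutoff"].nunique() < 2:
        raise ValueError("need at least 2 cutoff levels")
    y = table[spec.response].to_numpy(dtype=float)
    groups = table[spec.group].to_numpy()
    x_full, names = _build_design(table, "cutoff")
    res_full, singular = _fit_arrays(y, x_full, groups, "intercept")
    res_null, _ = _fit_arrays(y, np.ones((len(y), 1)), groups, "intercept")
    fit = FitResult(
        params=pd.Series(np.asarray(res_full.fe_params), index=names),
        loglik=float(res_full.llf),
        converged=bool(res_full.converged),
        singular=singular,
        cov_re=np.atleast_2d(np.asarray(res_full.cov_re)),
        scale=float(res_full.scale),
        random_structure_used="intercept",
        exog=x_full,
        exog_names=names,
        exog_re=np.ones((len(y), 1)),
        groups=groups,
        endog=y,
        formula="cutoff",
    )
    statistic = max(0.0, 2.0 * (float(res_full.llf) - float(res_null.llf)))
    r2m, r2c = r2_mixed(fit)
    lrt = LRTResult(statistic, 1, float(stats.chi2.sf(statistic, 1)), fit.aic, r2m, r2c)
    return fit, lrt


def vif(table: pd.DataFrame, predictors, response: str | None = None) -> dict[str, float]:
    """Generalized variance inflation factors of main-effect predictors.

    Computed on the interaction-free fixed design (no random effects),
    using the determinant form of Fox & Monette so multi-column
    categorical terms get a single factor; for one-column terms this is
    the classic ``1 / (1 - R²_j)``. Orthogonal balanced factors give 1;
    exact collinearity gives infinity.
    """
    formula = " + ".join(predictors)
    mat = patsy.dmatrix(formula, table, return_type="dataframe")
    slices = {
        term.name(): mat.design_info.slice(term)
        for term in mat.design_info.terms
        if term.name() != "Intercept"
    }
    x = np.asarray(mat)[:, 1:]  # drop intercept; GVIF uses centered correlations
    offset = 1
    x = x - x.mean(axis=0)
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    det_all = np.linalg.det(corr)
    out = {}
    for name, sl in slices.items():
        idx = np.arange(sl.start - offset, sl.stop - offset)
        rest = np.setdiff1d(np.arange(x.shape[1]), idx)
        if det_all <= 1e-12:
            out[name] = np.inf
            continue
        det_term = np.linalg.det(corr[np.ix_(idx, idx)])
        det_rest = np.linalg.det(corr[np.ix_(rest, rest)]) if rest.size else 1.0
        out[name] = float(det_term * det_rest / det_all)
    return out


def parametric_bootstrap_ci(
    fit: FitResult,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for the fixed effects.

    Responses are simulated from the fitted model (fixed part + random
    effects drawn per participant + residual noise), the model refit,
    and percentile intervals taken over the refitted coefficients.
    """
    rng = np.random.default_rng(seed)
    beta = fit.params.to_numpy()
    mean = fit.exog @ beta
    group_ids, group_index = np.unique(fit.groups, return_inverse=True)
    k_re = fit.cov_re.shape[0]
    chol = np.linalg.cholesky(fit.cov_re + 1e-12 * np.eye(k_re))
    draws, failures = [], 0
    for _ in range(n_boot):
        u = (chol @ rng.standard_normal((k_re, len(group_ids)))).T
        y = (
            mean
            + np.einsum("ij,ij->i", fit.exog_re, u[group_index])
            + rng.normal(0.0, np.sqrt(fit.scale), size=len(mean))
        )
        try:
            res, _ = _fit_arrays(y, fit.exog, fit.groups, fit.random_structure_used)
            if not res.converged:
                raise ValueError
            draws.append(np.asarray(res.fe_params))
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    draws = np.vstack(draws)
    lo, hi = np.percentile(
        draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2], axis=0
    )
    return pd.DataFrame(
        {"estimate": beta, "lower": lo, "upper": hi}, index=fit.exog_names
    )


def model_stability(fit: FitResult) -> pd.DataFrame:
    """Leave-one-participant-out ranges of the fixed-effect estimates.

    One refit per excluded participant; wide ranges relative to the
    full-data estimate flag influential participants. Folds that fail to
    converge are recorded and excluded from the range.
    """
    group_ids = np.unique(fit.groups)
    if len(group_ids) < 3:
        raise ValueError("stability check needs at least 3 participants")
    estimates, failed = [], []
    for g in group_ids:
        keep = fit.groups != g
        try:
            res, _ = _fit_arrays(
                fit.endog[keep], fit.exog[keep], fit.groups[keep],
                fit.random_structure_used,
            )
            if not res.converged:
                raise ValueError
            estimates.append(np.asarray(res.fe_params))
        except Exception:
            failed.append(g)
    arr = np.vstack(estimates)
    return pd.DataFrame(
        {
            "estimate": fit.params.to_numpy(),
            "min": arr.min(axis=0),
            "max": arr.max(axis=0),
            "n_failed_folds": len(failed),
        },
        index=fit.exog_names,
    )


@dataclass
class InferenceConfig:
    """Settings of the per-ROI inference pipeline."""

    fdr_q: float = 0.05
    cutoff_coding: str = "numeric"
    random_structure: str = "intercept"
    run_drop1: bool = True
    run_posthoc: bool = True
    posthoc_all: bool = False  # post-hoc on every ROI, not only FDR survivors


def per_roi_pipeline(
    metric_table: pd.DataFrame, config: InferenceConfig | None = None
) -> list[RoiInferenceResult]:
    """Full-null LRT per ROI, BH-FDR across ROIs, drop1 + post-hoc on survivors.

    ``metric_table`` is long-format with one AUC-integrated value per
    participant x attention x degradation x cutoff x roi. Per-ROI
    failures are flagged (p = NaN) and the pipeline continues; flagged
    ROIs count as non-significant. Post-hoc per-condition cutoff-slope
    models run on FDR survivors and receive their own BH correction
    across all ROI x condition tests.
    """
    config = config or InferenceConfig()
    spec = ModelSpec(
        cutoff_coding=config.cutoff_coding, random_structure=config.random_structure
    )
    results: list[RoiInferenceResult] = []
    fits: dict = {}
    for roi, sub in metric_table.groupby("roi", sort=True):
        try:
            full = fit_lmm(sub, spec, full=True)
            null = fit_lmm(sub, spec, full=False)
            lrt = lrt_full_null(full, null)
            slope = float(full.params.get("cutoff", np.nan))
            results.append(
                RoiInferenceResult(
                    roi=roi, full_null=lrt, p_fdr=np.nan, significant=False,
                    slope=slope,
                )
            )
            fits[roi] = (full, sub)
        except Exception:
            results.append(
                RoiInferenceResult(
                    roi=roi,
                    full_null=LRTResult(np.nan, 0, np.nan, np.nan, np.nan, np.nan),
                    p_fdr=np.nan, significant=False, slope=np.nan, failed=True,
                )
            )
    ok = [r for r in results if not r.failed]
    if ok:
        reject, p_adj = fdr_bh([r.full_null.p for r in ok], config.fdr_q)
        for r, rej, pa in zip(ok, reject, p_adj):
            r.p_fdr, r.significant = float(pa), bool(rej)
    posthoc_jobs = []
    for r in ok:
        if not (r.significant or config.posthoc_all):
            continue
        full, sub = fits[r.roi]
        if config.run_drop1:
            try:
                r.drop1 = drop1_lrt(full, sub, spec)
            except Exception:
                r.drop1 = {}
        if config.run_posthoc:
            for (att, deg), code in CONDITION_CODES.items():
                cell = sub[(sub["attention"] == att) & (sub["degradation"] == deg)]
                if cell.empty:
                    continue
                fit, lrt = posthoc_condition_slopes(cell, spec)
                entry = {
                    "roi": r.roi, "condition": code,
                    "intercept": float(fit.params.iloc[0]),
                    "slope": float(fit.params.get("cutoff", np.nan)),
                    "chi2": lrt.statistic, "df": lrt.df, "p": lrt.p,
                    "r2m": lrt.r2m, "r2c": lrt.r2c,
                }
                r.posthoc.append(entry)
                posthoc_jobs.append(entry)
    if posthoc_jobs:
        _, p_adj = fdr_bh([e["p"] for e in posthoc_jobs], config.fdr_q)
        for e, pa in zip(posthoc_jobs, p_adj):
            e["p_fdr"] = float(pa)
    return results


def inference_summary(results: list[RoiInferenceResult]) -> pd.DataFrame:
    """Tabular view of per-ROI full-null comparisons."""
    return pd.DataFrame(
        {
            "roi": [r.roi for r in results],
            "chi2": [r.full_null.statistic for r in results],
            "df": [r.full_null.df for r in results],
            "p": [r.full_null.p for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "significant": [r.significant for r in results],
            "slope": [r.slope for r in results],
            "r2m": [r.full_null.r2m for r in results],
            "r2c": [r.full_null.r2c for r in results],
            "failed": [r.failed for r in results],
        }
    )
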