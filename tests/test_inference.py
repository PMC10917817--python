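"""Mixed-model machinery: fits, LRTs, FDR, diagnostics, per-ROI pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fcgraph.inference import (
    InferenceConfig,
    ModelSpec,
    drop1_lrt,
    fdr_bh,
    fit_lmm,
    inference_summary,
    lrt_full_null,
    model_stability,
    parametric_bootstrap_ci,
    per_roi_pipeline,
    posthoc_condition_slopes,
    r2_mixed,
    vif,
)


def design_table(n_participants=15, response=None, rng=None):
    """Balanced attention x degradation x cutoff table, optionally with data."""
    rows = []
    for p in range(n_participants):
        for att in ("melody", "sentence"):
            for deg in ("spectral", "temporal"):
                for cut in range(1, 6):
                    rows.append((f"sub-{p:02d}", att, deg, cut))
    df = pd.DataFrame(rows, columns=["participant", "attention", "degradation", "cutoff"])
    if response is not None:
        df["value"] = response
    elif rng is not None:
        df["value"] = rng.normal(size=len(df))
    return df


def simulate_lmm(n_participants=15, slope=-0.005, part_sd=0.01, resid_sd=0.005,
                 seed=0):
    """Data from a known random-intercept LMM with a cutoff slope."""
    rng = np.random.default_rng(seed)
    df = design_table(n_participants)
    intercepts = {f"sub-{p:02d}": rng.normal(0, part_sd) for p in range(n_participants)}
    df["value"] = (
        0.1
        + slope * df["cutoff"]
        + df["participant"].map(intercepts)
        + rng.normal(0, resid_sd, size=len(df))
    )
    return df


class TestFitLmm:
    def test_constant_response_degenerate(self):
        df = design_table(5, response=0.7)
        fit = fit_lmm(df, ModelSpec())
        assert fit.params.iloc[0] == pytest.approx(0.7, abs=1e-6)
        assert np.allclose(fit.params.iloc[1:], 0.0, atol=1e-6)
        assert fit.singular

    def test_parameter_recovery_within_3se(self):
        df = simulate_lmm(seed=1)
        fit = fit_lmm(df, ModelSpec())
        # analytic slope SE for the balanced design: sigma / sqrt(N var(x))
        se = 0.005 / np.sqrt(len(df) * 2.0)
        assert fit.params["cutoff"] == pytest.approx(-0.005, abs=3 * se)

    def test_random_slopes_never_fit_worse(self):
        rng = np.random.default_rng(2)
        df = design_table(8, rng=rng)
        spec_int = ModelSpec(random_structure="intercept")
        spec_slp = ModelSpec(random_structure="slopes")
        ll_int = fit_lmm(df, spec_int, full=False).loglik
        fit_slp = fit_lmm(df, spec_slp, full=False)
        if fit_slp.random_structure_used != "intercept":
            assert fit_slp.loglik >= ll_int - 1e-6

    def test_nonfinite_response_rejected(self):
        df = design_table(3, response=1.0)
        df.loc[0, "value"] = np.nan
        with pytest.raises(ValueError):
            fit_lmm(df, ModelSpec())

    def test_single_participant_rejected(self):
        df = design_table(1, response=1.0)
        with pytest.raises(ValueError):
            fit_lmm(df, ModelSpec())

    def test_fallback_recorded_on_slope_structures(self):
        df = simulate_lmm(seed=3)
        fit = fit_lmm(df, ModelSpec(random_structure="slopes"))
        assert fit.random_structure_used in {"slopes", "uncorrelated_slopes", "intercept"}


class TestLrtFullNull:
    def test_identical_models_zero_statistic(self):
        df = simulate_lmm(seed=4)
        fit = fit_lmm(df, ModelSpec())
        res = lrt_full_null(fit, fit)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_study_design_categorical_df_19(self):
        df = simulate_lmm(seed=5)
        spec = ModelSpec(cutoff_coding="categorical")
        full = fit_lmm(df, spec, full=True)
        null = fit_lmm(df, spec, full=False)
        assert lrt_full_null(full, null).df == 19

    def test_numeric_cutoff_df_7(self):
        df = simulate_lmm(seed=6)
        full = fit_lmm(df, ModelSpec(), full=True)
        null = fit_lmm(df, ModelSpec(), full=False)
        assert lrt_full_null(full, null).df == 7

    def test_different_data_rejected(self):
        a = fit_lmm(simulate_lmm(seed=7), ModelSpec())
        b = fit_lmm(simulate_lmm(seed=8), ModelSpec())
        with pytest.raises(ValueError):
            lrt_full_null(a, b)

    def test_type_one_error_controlled_on_null_simulations(self):
        """Rejection rate at alpha=.05 stays at or below nominal + MC error."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 120
        spec = ModelSpec()
        for _ in range(n_rep):
            df = design_table(8, rng=rng)
            full = fit_lmm(df, spec, True)
            null = fit_lmm(df, spec, False)
            rejections += lrt_full_null(full, null).p < 0.05
        rate = rejections / n_rep
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestDrop1:
    def test_df_numeric_vs_categorical(self):
        df = simulate_lmm(seed=10)
        spec_num = ModelSpec(cutoff_coding="numeric")
        full_num = fit_lmm(df, spec_num)
        res_num = drop1_lrt(full_num, df, spec_num)
        assert res_num["attention:degradation:cutoff"].df == 1
        spec_cat = ModelSpec(cutoff_coding="categorical")
        full_cat = fit_lmm(df, spec_cat)
        res_cat = drop1_lrt(full_cat, df, spec_cat)
        assert res_cat["attention:degradation:C(cutoff)"].df == 4

    def test_marginality_violation_rejected(self):
        df = simulate_lmm(seed=11)
        spec = ModelSpec()
        full = fit_lmm(df, spec)
        with pytest.raises(ValueError, match="marginal"):
            drop1_lrt(full, df, spec, terms=["attention"])

    def test_planted_threeway_effect_detected(self):
        rng = np.random.default_rng(12)
        df = design_table(15)
        effect = (
            (df.attention == "sentence").astype(float)
            * (df.degradation == "temporal").astype(float)
            * df.cutoff
        )
        df["value"] = 0.02 * effect + rng.normal(0, 0.02, len(df))
        spec = ModelSpec()
        full = fit_lmm(df, spec)
        res = drop1_lrt(full, df, spec)
        assert res["attention:degradation:cutoff"].p < 0.01


class TestFdrBh:
    def test_step_up_rule_by_hand(self):
        reject, adj = fdr_bh([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        assert reject.tolist() == [True, True, True, True, False]

    def test_all_ones_nothing_rejected(self):
        reject, adj = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any() and np.all(adj == 1.0)

    def test_single_p_unchanged(self):
        _, adj = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_monotone_and_at_least_raw(self, pvals):
        _, adj = fdr_bh(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestPosthocSlopes:
    @staticmethod
    def one_condition_table(slope, seed, n_participants=15, resid_sd=0.01):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_participants):
            off = rng.normal(0, 0.01)
            for cut in range(1, 6):
                rows.append((f"s{p}", "sentence", "temporal", cut,
                             0.06 + slope * cut + off + rng.normal(0, resid_sd)))
        return pd.DataFrame(rows, columns=["participant", "attention",
                                           "degradation", "cutoff", "value"])

    def test_planted_negative_slope_recovered(self):
        hits = 0
        for seed in range(20):
            df = self.one_condition_table(-0.005, seed)
            fit, lrt = posthoc_condition_slopes(df)
            hits += (fit.params["cutoff"] < 0) and (lrt.p < 0.05)
        assert hits >= 16  # >= 80% of seeds

    def test_zero_slope_rejection_near_alpha(self):
        rejections = sum(
            posthoc_condition_slopes(self.one_condition_table(0.0, 100 + s))[1].p < 0.05
            for s in range(40)
        )
        assert rejections <= 7  # binomial(40, .05) upper tail

    def test_result_shape(self):
        fit, lrt = posthoc_condition_slopes(self.one_condition_table(-0.004, 3))
        assert {"Intercept", "cutoff"} <= set(fit.params.index)
        assert lrt.df == 1 and 0 <= lrt.p <= 1
        assert lrt.r2m <= lrt.r2c

    def test_single_cutoff_level_rejected(self):
        df = self.one_condition_table(0.0, 0)
        with pytest.raises(ValueError):
            posthoc_condition_slopes(df[df.cutoff == 3])


class TestVif:
    def test_orthogonal_balanced_factors_are_one(self):
        df = design_table(4)
        out = vif(df, ["attention", "degradation", "C(cutoff)"])
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in out.values())

    def test_duplicated_predictor_infinite(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = df["x"]
        out = vif(df, ["x", "y"])
        assert np.isinf(list(out.values())).all()

    def test_correlated_continuous_closed_form(self, rng):
        n = 200_000
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        out = vif(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert out["x"] == pytest.approx(1 / (1 - 0.64), rel=0.02)


class TestR2Mixed:
    def test_zero_fixed_effects(self):
        df = simulate_lmm(slope=0.0, seed=13)
        fit = fit_lmm(df, ModelSpec(), full=False)
        r2m, r2c = r2_mixed(fit)
        assert r2m == pytest.approx(0.0, abs=1e-6)
        assert r2c > r2m

    def test_known_variance_partition(self):
        # fixed 50%, random intercept 25%, residual 25% of total variance
        rng = np.random.default_rng(14)
        n_part, n_obs = 60, 40
        rows = []
        for p in range(n_part):
            u = rng.normal(0, np.sqrt(0.25))
            x = rng.standard_normal(n_obs)
            y = np.sqrt(0.5) * x + u + rng.normal(0, np.sqrt(0.25), n_obs)
            rows.extend(zip([f"s{p}"] * n_obs, x, y))
        df = pd.DataFrame(rows, columns=["participant", "cutoff", "value"])
        fit, _ = posthoc_condition_slopes(df)
        r2m, r2c = r2_mixed(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)

    def test_r2m_never_exceeds_r2c(self):
        df = simulate_lmm(seed=15)
        fit = fit_lmm(df, ModelSpec())
        r2m, r2c = r2_mixed(fit)
        assert r2m <= r2c <= 1.0


class TestBootstrapCI:
    def test_reproducible_and_contains_estimate(self):
        df = simulate_lmm(seed=16)
        fit = fit_lmm(df, ModelSpec())
        ci1 = parametric_bootstrap_ci(fit, n_boot=40, seed=5)
        ci2 = parametric_bootstrap_ci(fit, n_boot=40, seed=5)
        pd.testing.assert_frame_equal(ci1, ci2)
        assert (ci1["lower"] <= ci1["estimate"]).all()
        assert (ci1["estimate"] <= ci1["upper"]).all()

    def test_intervals_shrink_with_tiny_noise(self):
        wide = simulate_lmm(resid_sd=0.02, part_sd=0.0001, seed=17)
        tight = simulate_lmm(resid_sd=0.0005, part_sd=0.0001, seed=17)
        w_ci = parametric_bootstrap_ci(fit_lmm(wide, ModelSpec()), n_boot=40, seed=1)
        t_ci = parametric_bootstrap_ci(fit_lmm(tight, ModelSpec()), n_boot=40, seed=1)
        assert (t_ci["upper"] - t_ci["lower"]).mean() < (
            w_ci["upper"] - w_ci["lower"]
        ).mean()


class TestModelStability:
    def test_fifteen_participants_narrow_ranges(self):
        df = simulate_lmm(seed=18)
        fit = fit_lmm(df, ModelSpec())
        stab = model_stability(fit)
        assert (stab["min"] <= stab["estimate"] + 1e-9).all()
        assert (stab["estimate"] <= stab["max"] + 1e-9).all()
        assert (stab["n_failed_folds"] == 0).all()

    def test_planted_outlier_widens_range(self):
        base = simulate_lmm(seed=19)
        outlier = base.copy()
        mask = outlier.participant == "sub-00"
        outlier.loc[mask, "value"] += 0.08 * outlier.loc[mask, "cutoff"]
        r_base = model_stability(fit_lmm(base, ModelSpec()))
        r_out = model_stability(fit_lmm(outlier, ModelSpec()))
        spread = lambda r: (r.loc["cutoff", "max"] - r.loc["cutoff", "min"])
        assert spread(r_out) > 3 * spread(r_base)

    def test_too_few_participants_rejected(self):
        df = simulate_lmm(n_participants=2, seed=20)
        fit = fit_lmm(df, ModelSpec())
        with pytest.raises(ValueError):
            model_stability(fit)


class TestPerRoiPipeline:
    def test_planted_rois_flagged_null_rois_mostly_not(self):
        rng = np.random.default_rng(21)
        frames = []
        for roi in range(16):
            df = design_table(15)
            df["roi"] = roi
            signal = 0.0
            if roi < 3:  # planted: negative cutoff slope in ST and MS only
                flagged = (
                    ((df.attention == "sentence") & (df.degradation == "temporal"))
                    | ((df.attention == "melody") & (df.degradation == "spectral"))
                ).astype(float)
                signal = -0.01 * flagged * df.cutoff
            df["value"] = 0.2 + signal + rng.normal(0, 0.01, len(df))
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        results = per_roi_pipeline(table, InferenceConfig())
        summary = inference_summary(results)
        flagged = set(summary[summary.significant].roi)
        assert {0, 1, 2} <= flagged
        assert len(flagged - {0, 1, 2}) <= 2

    def test_posthoc_only_on_survivors_with_own_fdr(self):
        rng = np.random.default_rng(22)
        frames = []
        for roi in range(6):
            df = design_table(10)
            df["roi"] = roi
            eff = -0.02 * df.cutoff if roi == 0 else 0.0
            df["value"] = 0.2 + eff + rng.normal(0, 0.01, len(df))
            frames.append(df)
        results = per_roi_pipeline(pd.concat(frames, ignore_index=True), InferenceConfig())
        sig = [r for r in results if r.significant]
        assert all(r.posthoc for r in sig)
        assert all(not r.posthoc for r in results if not r.significant)
        for r in sig:
            for entry in r.posthoc:
                assert {"condition", "intercept", "slope", "chi2", "p", "p_fdr"} <= set(entry)

    def test_failed_roi_flagged_not_fatal(self):
        rng = np.random.default_rng(23)
        good = design_table(10)
        good["roi"] = 0
        good["value"] = rng.normal(size=len(good))
        bad = design_table(10)
        bad["roi"] = 1
        bad["value"] = np.nan
        results = per_roi_pipeline(pd.concat([good, bad], ignore_index=True),
                                   InferenceConfig())
        by_roi = {r.roi: r for r in results}
        assert by_roi[1].failed and not by_roi[0].failed
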