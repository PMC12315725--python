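"""Statistical stage: OLS oracles, FDR, elimination, moderation, outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netseg import models as mdl
from netseg.cohort import CohortSpec, generate_cohort

from conftest import ols_oracle


def aic_oracle(y, X):
    """Gaussian-ML AIC computed from scratch (matches OLS likelihood AIC)."""
    X = np.asarray(X, float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = np.sum((y - X @ beta) ** 2)
    n = len(y)
    llf = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
    return -2 * llf + 2 * X.shape[1]


class TestOlsAgainstNormalEquations:
    @pytest.mark.parametrize("seed", range(6))
    def test_params_se_cov_agree_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(12, 50)
        p = rng.integers(1, 4)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = rng.normal(size=n)
        fit = mdl.fit_ols(y, X)
        Xd = np.column_stack([np.ones(n), X.values])
        beta, _, cov = ols_oracle(y, Xd)
        np.testing.assert_allclose(fit.params.values, beta, atol=1e-10)
        np.testing.assert_allclose(fit.bse.values, np.sqrt(np.diag(cov)),
                                   atol=1e-10)
        np.testing.assert_allclose(fit.cov_params.values, cov, atol=1e-10)

    def test_saturated_fit_refused(self):
        with pytest.raises(ValueError, match="too small"):
            mdl.fit_ols([1.0, 2.0, 3.0], pd.DataFrame({"x": [1, 2, 3]}))

    def test_rank_deficient_design_refused(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="rank"):
            mdl.fit_ols(np.random.default_rng(0).normal(size=10), X)


class TestResidualizeFD:
    def test_exact_multiple_of_fd_residualizes_to_zero(self):
        df = pd.DataFrame({"rms_fd": [0.1, 0.2, 0.3, 0.4, 0.5]})
        df["m"] = 2 * df.rms_fd
        out = mdl.residualize_fd(df, ["m"])
        np.testing.assert_allclose(out["m"], 0.0, atol=1e-12)

    def test_uncorrelated_measure_just_demeaned(self):
        rng = np.random.default_rng(0)
        fd = np.tile([0.1, 0.3], 10)
        m = np.tile([1.0, 1.0, 3.0, 3.0], 5)  # orthogonal to fd pattern
        df = pd.DataFrame({"rms_fd": fd, "m": m})
        out = mdl.residualize_fd(df, ["m"])
        np.testing.assert_allclose(out["m"], m - m.mean(), atol=1e-12)

    def test_five_subject_toy_matches_oracle(self):
        df = pd.DataFrame({"rms_fd": [0.11, 0.25, 0.09, 0.33, 0.18],
                           "m": [0.7, 0.5, 0.75, 0.42, 0.6]})
        out = mdl.residualize_fd(df, ["m"])
        X = np.column_stack([np.ones(5), df.rms_fd])
        _, resid, _ = ols_oracle(df.m.values, X)
        np.testing.assert_allclose(out["m"], resid, atol=1e-12)

    def test_constant_fd_skipped_with_warning(self):
        df = pd.DataFrame({"rms_fd": [0.2] * 5, "m": [1, 2, 3, 4, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = mdl.residualize_fd(df, ["m"])
        np.testing.assert_array_equal(out["m"], df["m"])


class TestStandardizeAge:
    def test_published_cohort_anchor(self):
        scale = mdl.AgeScale(mean=34.06, sd=21.06)
        assert mdl.standardize_age([55.12], scale)[0] == pytest.approx(1.0)
        assert mdl.standardize_age([34.06], scale)[0] == pytest.approx(0.0)
        assert mdl.unstandardize_age(1.0, scale) == pytest.approx(55.12)

    def test_sample_statistics_by_default(self):
        ages = np.array([10.0, 20.0, 30.0, 40.0])
        z = mdl.standardize_age(ages)
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            mdl.AgeScale(mean=30.0, sd=0.0)


class TestAgeModel:
    def test_noiseless_linear_recovery_drops_quadratic(self):
        a = np.linspace(-2, 2, 30)
        fit = mdl.fit_age_model(3 * a, a, quadratic="auto")
        assert "age_z2" not in fit.terms
        assert fit.params["age_z"] == pytest.approx(3.0, abs=1e-10)

    def test_pure_quadratic_selected(self):
        a = np.linspace(-2, 2, 30)
        rng = np.random.default_rng(0)
        fit = mdl.fit_age_model(-a**2 + rng.normal(0, 1e-6, 30), a)
        assert "age_z2" in fit.terms
        assert fit.params["age_z2"] == pytest.approx(-1.0, abs=1e-4)

    def test_eight_point_toy_matches_oracle(self):
        a = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([2.0, 1.2, 0.8, 0.5, 0.9, 1.4, 2.2, 3.5])
        fit = mdl.fit_age_model(y, a, quadratic="on")
        X = np.column_stack([np.ones(8), a, a**2])
        beta, *_ = ols_oracle(y, X)
        np.testing.assert_allclose(fit.params.values, beta, atol=1e-10)


def bh_oracle(p):
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestFDR:
    def test_textbook_example(self):
        np.testing.assert_allclose(mdl.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert mdl.fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(mdl.fdr_adjust([0.2] * 12), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mdl.fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_step_up_definition(self, p):
        np.testing.assert_allclose(mdl.fdr_adjust(p), bh_oracle(p), atol=1e-12)
        adj = mdl.fdr_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)


class TestBiasModel:
    def test_null_predictor_has_zero_coefficient(self):
        a = np.linspace(-2, 2, 40)
        bias = 50 + 5 * a
        pred = pd.DataFrame({"p0": np.zeros(40) + 0.3})
        with pytest.raises(ValueError, match="rank"):
            # constant predictor is collinear with the intercept
            mdl.fit_bias_model(bias, pred, a)

    def test_toy_matches_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        x = rng.normal(size=30)
        y = 50 + 4 * a + 10 * x + rng.normal(size=30)
        fit = mdl.fit_bias_model(y, pd.DataFrame({"x": x}), a)
        beta, *_ = ols_oracle(y, np.column_stack([np.ones(30), a, x]))
        np.testing.assert_allclose(fit.params.values, beta, atol=1e-10)


class TestBackwardElimination:
    def test_true_effect_kept_noise_removed(self):
        kept_true, removed_noise = 0, []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            cands = pd.DataFrame(rng.normal(size=(n, 11)),
                                 columns=[f"c{i:02d}" for i in range(11)])
            age = pd.DataFrame({"age_z": rng.normal(size=n)})
            y = 1.0 * cands["c05"] + 0.5 * age["age_z"] + rng.normal(0, 0.5, n)
            trace, fit = mdl.backward_eliminate(y.values, cands, age)
            kept_true += "c05" in trace.final_terms
            removed_noise.append(10 - (len(trace.final_terms) - 2
                                       + ("c05" not in trace.final_terms)))
        assert kept_true == 20
        assert np.mean(removed_noise) >= 8

    def test_all_noise_final_aic_not_above_full(self):
        rng = np.random.default_rng(3)
        n = 500
        cands = pd.DataFrame(rng.normal(size=(n, 6)),
                             columns=[f"c{i}" for i in range(6)])
        forced = pd.DataFrame({"age_z": rng.normal(size=n)})
        y = rng.normal(size=n)
        trace, fit = mdl.backward_eliminate(y, cands, forced)
        full = mdl.fit_ols(y, pd.concat([forced, cands], axis=1))
        assert fit.aic <= full.aic

    def test_forced_terms_never_removed(self):
        rng = np.random.default_rng(4)
        n = 80
        cands = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        forced = pd.DataFrame({"age_z": rng.normal(size=n)})
        y = rng.normal(size=n)  # age has no effect, must still survive
        trace, fit = mdl.backward_eliminate(y, cands, forced)
        assert "age_z" in trace.final_terms
        assert all(s[1] != "age_z" for s in trace.steps)

    @pytest.mark.parametrize("seed", range(4))
    def test_trace_matches_greedy_aic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        cands = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        forced = pd.DataFrame({"age_z": rng.normal(size=n)})
        y = (0.8 * cands["b"] + rng.normal(size=n))
        trace, fit = mdl.backward_eliminate(y.values, cands, forced)

        # independent greedy search over backward-reachable subsets
        current = list("abc")
        path = []
        def design(terms):
            return np.column_stack([np.ones(n), forced.values,
                                    cands[terms].values])
        cur_aic = aic_oracle(y.values, design(current))
        while current:
            opts = sorted((aic_oracle(y.values, design(
                [t for t in current if t != drop])), drop)
                for drop in current)
            if opts[0][0] >= cur_aic:
                break
            path.append(opts[0][1])
            current.remove(opts[0][1])
            cur_aic = opts[0][0]
        assert [s[1] for s in trace.steps] == path
        assert trace.final_terms == ["age_z"] + current
        assert fit.aic == pytest.approx(cur_aic, abs=1e-8)

    def test_aic_nonincreasing_along_trace(self):
        rng = np.random.default_rng(9)
        n = 60
        cands = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"c{i}" for i in range(5)])
        forced = pd.DataFrame({"age_z": rng.normal(size=n)})
        trace, _ = mdl.backward_eliminate(rng.normal(size=n), cands, forced)
        for _, _, before, after in trace.steps:
            assert after < before


class TestScreenInteractions:
    def sim(self, seed, b_int, n=250):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        x = rng.normal(size=n)
        y = 50 + 2 * a + 1.0 * x + b_int * x * a + rng.normal(0, 2, n)
        forced = pd.DataFrame({"age_z": a})
        sel = pd.DataFrame({"x": x})
        return mdl.screen_interactions(y, sel, forced)

    def test_planted_interaction_retained(self):
        hits = sum("x:age_z" in self.sim(seed, b_int=-0.8)[1]
                   for seed in range(50))
        assert hits >= 45  # ample power at this effect size

    def test_no_interaction_false_positive_near_alpha(self):
        hits = sum("x:age_z" in self.sim(seed, b_int=0.0)[1]
                   for seed in range(200))
        assert 0.01 <= hits / 200 <= 0.10

    def test_empty_selection_returns_forced_model(self):
        rng = np.random.default_rng(0)
        forced = pd.DataFrame({"age_z": rng.normal(size=40)})
        fit, kept = mdl.screen_interactions(rng.normal(size=40),
                                            pd.DataFrame(index=forced.index),
                                            forced)
        assert kept == []
        assert fit.terms == ["Intercept", "age_z"]


class TestSimpleSlopes:
    def make_fit(self, cov_fi=0.0):
        params = {"Intercept": 65.418, "age_z": 4.819, "DMN-CO": 18.889,
                  "DMN-VAN": 7.609, "DMN-Reward": -6.435,
                  "DMN-Reward:age_z": -9.029}
        bse = {"Intercept": 4.580, "age_z": 1.285, "DMN-CO": 6.927,
               "DMN-VAN": 3.904, "DMN-Reward": 4.311,
               "DMN-Reward:age_z": 4.218}
        fit = mdl.FitResult.from_coefficients(params, bse, df_resid=215)
        fit.cov_params.loc["DMN-Reward", "DMN-Reward:age_z"] = cov_fi
        fit.cov_params.loc["DMN-Reward:age_z", "DMN-Reward"] = cov_fi
        return fit

    def test_published_model_slope_anchors(self):
        s = mdl.simple_slopes(self.make_fit(), "DMN-Reward",
                              "DMN-Reward:age_z", (-1.0, 0.0, 1.0))
        assert s.slope[s.moderator == 1.0].iloc[0] == pytest.approx(-15.464)
        assert s.slope[s.moderator == 0.0].iloc[0] == pytest.approx(-6.435)
        assert s.slope[s.moderator == -1.0].iloc[0] == pytest.approx(2.594)

    def test_se_at_zero_equals_focal_se(self):
        s = mdl.simple_slopes(self.make_fit(cov_fi=2.0), "DMN-Reward",
                              "DMN-Reward:age_z", (0.0,))
        assert s.se.iloc[0] == pytest.approx(4.311)

    def test_missing_term_raises(self):
        with pytest.raises(KeyError):
            mdl.simple_slopes(self.make_fit(), "nope", "DMN-Reward:age_z")


class TestJohnsonNeyman:
    def fit_interaction_data(self, seed=0, n=200, yscale=1.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        x = rng.normal(size=n)
        y = (1.0 + 0.5 * x - 0.8 * x * a + 2 * a + rng.normal(size=n)) * yscale
        X = pd.DataFrame({"age_z": a, "x": x, "x:age_z": x * a})
        return mdl.fit_ols(y, X)

    def test_boundary_t_equals_critical_t(self):
        fit = self.fit_interaction_data()
        res = mdl.johnson_neyman(fit, "x", "x:age_z")
        assert len(res.boundaries_z) >= 1
        for a in res.boundaries_z:
            s = mdl.simple_slopes(fit, "x", "x:age_z", (a,))
            assert abs(s.t.iloc[0]) == pytest.approx(res.t_crit, abs=1e-6)

    def test_toy_quadratic_matches_grid_search(self):
        fit = mdl.FitResult.from_coefficients(
            {"x": 0.0, "x:age_z": 1.0},
            {"x": 0.1, "x:age_z": 0.1})
        res = mdl.johnson_neyman(fit, "x", "x:age_z")
        grid = np.linspace(-10, 10, 2_000_001)
        tt = np.abs(0.0 + 1.0 * grid) / np.sqrt(0.01 + 0.01 * grid**2)
        crossings = grid[np.flatnonzero(np.diff(np.sign(tt - res.t_crit)))]
        assert len(res.boundaries_z) == len(crossings)
        for b, g in zip(res.boundaries_z, crossings):
            assert b == pytest.approx(g, abs=1e-4)

    def test_boundaries_invariant_to_outcome_rescaling(self):
        r1 = mdl.johnson_neyman(self.fit_interaction_data(yscale=1.0),
                                "x", "x:age_z")
        r2 = mdl.johnson_neyman(self.fit_interaction_data(yscale=37.5),
                                "x", "x:age_z")
        np.testing.assert_allclose(r1.boundaries_z, r2.boundaries_z,
                                   atol=1e-8)

    def test_raw_unit_conversion_uses_age_scale(self):
        fit = self.fit_interaction_data()
        scale = mdl.AgeScale(34.06, 21.06)
        res = mdl.johnson_neyman(fit, "x", "x:age_z", age_scale=scale)
        for z, raw in zip(res.boundaries_z, res.boundaries_raw):
            assert raw == pytest.approx(34.06 + z * 21.06)
        assert mdl.unstandardize_age(1.0, scale) == pytest.approx(55.12)

    def test_no_moderation_degenerate_case(self):
        fit = mdl.FitResult.from_coefficients(
            {"x": 2.0, "x:age_z": 0.0}, {"x": 0.1, "x:age_z": 0.0})
        res = mdl.johnson_neyman(fit, "x", "x:age_z")
        assert res.boundaries_z == ()
        assert res.everywhere and not res.nowhere


class TestOutliers:
    def test_identical_values_no_outliers(self):
        assert len(mdl.detect_outliers([2.0] * 10)) == 0

    def test_single_extreme_value_flagged(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.standard_normal(100), [50.0]])
        assert list(mdl.detect_outliers(v)) == [100]

    def test_rule_is_sign_symmetric(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.standard_normal(80), [30.0, -30.0]])
        flagged = set(mdl.detect_outliers(v))
        assert flagged == {80, 81}
        flagged_neg = set(mdl.detect_outliers(-v))
        assert flagged_neg == flagged

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mdl.detect_outliers([1.0, 2.0, 3.0])


class TestPlantedCoefficientRecovery:
    """Fast-route properties on the generator's planted subject quantities."""

    @staticmethod
    def planted_design(cohort):
        spec = cohort.spec
        t = cohort.subject_table()
        a = t.age_z.values
        base = (spec.z_between0 + spec.beta_between_lin * a
                + spec.beta_between_quad * a**2)
        d_co = t.true_dmn_co_z.values - base
        d_van = t.true_dmn_van_z.values - base
        d_rew = t.true_dmn_reward_z.values - base
        X = pd.DataFrame({"age_z": a, "d_co": d_co, "d_van": d_van,
                          "d_rew": d_rew, "d_rew:age_z": d_rew * a})
        return X, t.true_bias.values

    def test_ci_coverage_of_planted_gammas(self):
        """95% CIs cover the planted generative coefficients (pooled over
        the five model terms) in 93-97% of 200 seeded cohorts."""
        hits, total = 0, 0
        for seed in range(200):
            c = generate_cohort(CohortSpec(n_subjects=250, seed=seed))
            X, y = self.planted_design(c)
            fit = mdl.fit_ols(y, X)
            truth = {"age_z": c.spec.beta_bias_age, "d_co": c.spec.gamma_co,
                     "d_van": c.spec.gamma_van, "d_rew": c.spec.gamma_reward,
                     "d_rew:age_z": c.spec.gamma_reward_by_age}
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            for term, tv in truth.items():
                lo = fit.params[term] - tcrit * fit.bse[term]
                hi = fit.params[term] + tcrit * fit.bse[term]
                hits += lo <= tv <= hi
                total += 1
        assert 0.93 <= hits / total <= 0.97

    def test_null_effects_reject_at_nominal_rate(self):
        """With every planted effect zero, the age and bias models reject
        at the nominal 5% level (within +/-2%) over 400 seeded cohorts."""
        null = dict(n_subjects=100, beta_age_seg=0.0, beta_between_lin=0.0,
                    beta_between_quad=0.0, beta_bias_age=0.0, gamma_co=0.0,
                    gamma_van=0.0, gamma_reward=0.0, gamma_reward_by_age=0.0)
        rej_age, rej_bias = 0, 0
        for seed in range(400):
            c = generate_cohort(CohortSpec(seed=seed, **null))
            t = c.subject_table()
            w = np.array([s.true_within.mean() for s in c.subjects])
            fit_age = mdl.fit_ols(w, pd.DataFrame({"age_z": t.age_z.values}))
            rej_age += fit_age.pvalues["age_z"] < 0.05
            X, y = self.planted_design(c)
            fit_bias = mdl.fit_ols(y, X[["age_z", "d_co"]])
            rej_bias += fit_bias.pvalues["d_co"] < 0.05
        assert 0.03 <= rej_age / 400 <= 0.07
        assert 0.03 <= rej_bias / 400 <= 0.07
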