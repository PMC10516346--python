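"""ANOVA/Tukey, the factorial interaction model, crossed-random-intercept
mixed models, pseudo-R² and model comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from fungalcomp.inference import (
    LMMResult,
    LMMSpec,
    anova_oneway,
    compare_models,
    distance_correlation_check,
    fit_interaction_lm,
    fit_lmm,
    pseudo_r2,
    tukey_hsd,
)
from fungalcomp.metrics import growth_distance
from fungalcomp.phylo import DistanceMatrix

from conftest import make_config, run_to_eoc


class TestAnovaOneway:
    def test_identical_groups_flagged_degenerate(self):
        res = anova_oneway([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert res.degenerate and np.isnan(res.f_stat)

    def test_two_groups_equals_squared_t(self):
        y = np.array([1.1, 2.0, 2.9, 4.2, 5.1, 6.3])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = anova_oneway(y, g)
        t, p_t = st.ttest_ind(y[g == "a"], y[g == "b"])
        assert res.f_stat == pytest.approx(t**2, rel=1e-12)
        assert res.p_value == pytest.approx(p_t, rel=1e-12)
        assert (res.df_num, res.df_den) == (1, 4)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(123)
        alpha, reps = 0.05, 2000
        rejections = 0
        groups = np.repeat(["a", "b", "c"], 8)
        for _ in range(reps):
            y = rng.normal(size=24)
            if anova_oneway(y, groups).p_value < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) <= 3 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            anova_oneway([1.0], ["a"])


class TestTukeyHsd:
    def test_two_groups_matches_t_test(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 12)])
        g = np.repeat(["a", "b"], 12)
        (res,) = tukey_hsd(y, g)
        _, p_t = st.ttest_ind(y[g == "a"], y[g == "b"])
        assert res.adjusted_p == pytest.approx(p_t, rel=1e-6)

    def test_shifted_group_flagged_only(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(5, 1, 15)])
        g = np.repeat(["a", "b", "c"], 15)
        results = {(r.group_a, r.group_b): r for r in tukey_hsd(y, g)}
        assert not results[("a", "b")].significant
        assert results[("a", "c")].significant
        assert results[("b", "c")].significant

    def test_mean_diff_sign_convention(self):
        y = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        g = np.repeat(["a", "b"], 3)
        (res,) = tukey_hsd(y, g)
        assert res.mean_diff == pytest.approx(-1.0)


class TestInteractionLm:
    def test_perfect_fit_adjusted_r2_one(self):
        eoc = run_to_eoc(make_config(sigma_obs=0.0, sigma_resid=0.0, sigma_plate=0.0))[4]
        res = fit_interaction_lm(eoc)
        assert res.adj_r_squared == pytest.approx(1.0, abs=1e-9)

    def test_df_structure_matches_cell_count(self, default_run):
        eoc = default_run["eoc"]
        res = fit_interaction_lm(eoc)
        # 5x4 ordered species pairs x 2 pH = 40 cells
        assert res.df_num == 39
        assert res.df_den == res.n_obs - 40
        assert res.aliased  # self-pairings are unobserved, hence aliasing
        assert res.p_value < 1e-6

    def test_no_interaction_data_gives_nonsignificant_interactions(self):
        # response depends on focal and pH only; the extra interaction terms
        # of the factorial model should not improve the main-effects fit
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        focal = np.repeat(list("ABC"), 40)
        opponent = np.tile(np.repeat(list("XY"), 20), 3)
        ph = np.tile([5.6, 7.0], 60)
        base = {"A": 1.0, "B": 0.8, "C": 1.2}
        y = np.array([base[f] for f in focal]) + 0.1 * (ph == 7.0) + rng.normal(0, 0.05, 120)
        eoc = pd.DataFrame({"focal": focal, "opponent": opponent, "ph": ph, "eoc": y})
        full = smf.ols("eoc ~ C(focal) * C(opponent) * C(ph)", eoc).fit()
        reduced = smf.ols("eoc ~ C(focal) + C(opponent) + C(ph)", eoc).fit()
        _, p_int, _ = full.compare_f_test(reduced)
        assert p_int > 0.05


def _no_random_effect_data(seed=0, n=120):
    rng = np.random.default_rng(seed)
    species = list("ABCD")
    rows = []
    for k in range(n // 2):
        i, j = rng.choice(4, 2, replace=False)
        ph = 5.6 if k % 2 else 7.0
        d = 0.3 * abs(i - j)
        for f, o in [(i, j), (j, i)]:
            y = 0.1 - 0.4 * d - 0.2 * (ph == 7.0) + rng.normal(0, 0.05)
            rows.append(
                {
                    "plate_id": f"p{k}",
                    "focal": species[f],
                    "opponent": species[o],
                    "ph": ph,
                    "log_eoc": y,
                    "eoc": np.exp(y),
                }
            )
    df = pd.DataFrame(rows)
    dist = DistanceMatrix(
        tuple(species),
        0.3 * np.abs(np.subtract.outer(np.arange(4), np.arange(4))).astype(float),
        kind="patristic",
    )
    return df, dist


class TestFitLmm:
    def test_zero_random_variance_matches_ols(self):
        df, dist = _no_random_effect_data()
        spec = LMMSpec(distance_kind="patristic", interaction=False)
        res = fit_lmm(df, dist, spec)
        d = np.array([dist[f, o] for f, o in zip(df["focal"], df["opponent"])])
        X = sm.add_constant(np.column_stack([(df["ph"] == 7.0).astype(float), d]))
        ols = sm.OLS(df["log_eoc"], X).fit()
        est = res.coefficients
        assert est["Intercept"]["estimate"] == pytest.approx(ols.params[0], abs=1e-6)
        assert est["C(ph_level)[T.7.0]"]["estimate"] == pytest.approx(ols.params[1], abs=1e-6)
        assert est["distance"]["estimate"] == pytest.approx(ols.params[2], abs=1e-6)
        assert res.boundary  # variance components collapse to zero

    def test_study_scale_recovery_single_replicate(self, default_run):
        truth = default_run["truth"]
        cfg = default_run["config"]
        spec = LMMSpec(distance_kind="patristic", interaction=False)
        res = fit_lmm(default_run["eoc"], truth.patristic, spec)
        c = res.coefficients["distance"]
        assert abs(c["estimate"] - cfg.beta_dist) < 4 * c["se"]
        c_ph = res.coefficients["C(ph_level)[T.7.0]"]
        assert abs(c_ph["estimate"] - cfg.beta_ph) < 4 * c_ph["se"]
        assert res.n_obs == len(default_run["eoc"])

    def test_growth_spec_has_no_interaction_term(self, default_run):
        svs = default_run["svs"]
        dists = [growth_distance(svs, ph) for ph in (5.6, 7.0)]
        res = fit_lmm(default_run["eoc"], dists, LMMSpec(distance_kind="growth_rate"))
        assert not any("distance:" in t for t in res.fixed_names)

    def test_patristic_spec_keeps_interaction_term(self, default_run):
        res = fit_lmm(
            default_run["eoc"],
            default_run["truth"].patristic,
            LMMSpec(distance_kind="patristic"),
        )
        assert any("distance:" in t for t in res.fixed_names)

    def test_unjoinable_record_is_error(self, default_run):
        small = default_run["truth"].patristic.subset(
            default_run["truth"].patristic.labels[:3]
        )
        with pytest.raises(KeyError, match="not joinable"):
            fit_lmm(default_run["eoc"], small, LMMSpec(distance_kind="patristic"))

    def test_aic_consistent_with_loglik(self, default_run):
        res = fit_lmm(
            default_run["eoc"],
            default_run["truth"].patristic,
            LMMSpec(distance_kind="patristic"),
        )
        assert res.aic == pytest.approx(-2 * res.log_lik + 2 * res.n_params)
        assert res.bic == pytest.approx(-2 * res.log_lik + res.n_params * np.log(res.n_obs))


class TestPseudoR2:
    @staticmethod
    def _result_with(var_f_target, s_u, s_w, s_e, n=101):
        eta = np.linspace(0, 1, n)
        eta = eta * np.sqrt(var_f_target / np.var(eta, ddof=1))
        return LMMResult(
            spec=LMMSpec(),
            coefficients={},
            variance_components={"fungal_id": s_u, "plate_id": s_w, "residual": s_e},
            log_lik=0.0,
            aic=0.0,
            bic=0.0,
            r2_marginal=np.nan,
            r2_conditional=np.nan,
            n_obs=n,
            n_params=4,
            converged=True,
            boundary=False,
            _design=eta[:, None],
            _fe_params=np.array([1.0]),
        )

    def test_textbook_partition(self):
        res = self._result_with(2.0, 0.6, 0.4, 1.0)
        marg, cond = pseudo_r2(res)
        assert marg == pytest.approx(0.5)
        assert cond == pytest.approx(0.75)

    def test_no_random_effects_marginal_equals_conditional(self):
        res = self._result_with(1.5, 0.0, 0.0, 0.5)
        marg, cond = pseudo_r2(res)
        assert marg == pytest.approx(cond)

    def test_zero_total_variance_flagged(self):
        res = self._result_with(0.0, 0.0, 0.0, 0.0)
        res._design = np.zeros((10, 1))
        with pytest.raises(ValueError, match="undefined"):
            pseudo_r2(res)

    def test_ordering_invariant_on_fit(self, default_run):
        res = fit_lmm(
            default_run["eoc"],
            default_run["truth"].patristic,
            LMMSpec(distance_kind="patristic"),
        )
        assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0


class TestCompareModels:
    def test_identical_models_delta_zero_p_one(self, default_run):
        res = fit_lmm(
            default_run["eoc"],
            default_run["truth"].patristic,
            LMMSpec(distance_kind="patristic"),
        )
        cmp = compare_models(res, res)
        assert cmp.delta_aic == 0.0
        assert cmp.chi_square == 0.0
        assert cmp.p_value == 1.0

    def test_different_n_refused(self, default_run):
        spec = LMMSpec(distance_kind="patristic")
        res = fit_lmm(default_run["eoc"], default_run["truth"].patristic, spec)
        res2 = fit_lmm(default_run["eoc"].iloc[:-4], default_run["truth"].patristic, spec)
        with pytest.raises(ValueError, match="different observation sets"):
            compare_models(res, res2)

    def test_extra_useless_parameter_null_distribution(self):
        # 2*(ll_full - ll_reduced) for one superfluous fixed effect should
        # behave like chi-square(1) under ML.  The chi-square behaviour is
        # checked at scale on an independent OLS likelihood-ratio oracle
        # (the generating model has no random effects, so OLS is exact),
        # and the mixed-model likelihoods are checked against that oracle.
        import statsmodels.formula.api as smf

        ols_stats = []
        for rep in range(400):
            df, dist = _no_random_effect_data(seed=rep, n=80)
            df = df.assign(
                distance=[dist[f, o] for f, o in zip(df["focal"], df["opponent"])]
            )
            r0 = smf.ols("log_eoc ~ distance + C(ph)", df).fit()
            r1 = smf.ols("log_eoc ~ distance * C(ph)", df).fit()
            ols_stats.append(2 * (r1.llf - r0.llf))
        ks = st.kstest(ols_stats, st.chi2(1).cdf)
        assert ks.pvalue > 0.001

        lmm_stats = []
        for rep in range(20):
            df, dist = _no_random_effect_data(seed=rep, n=80)
            base = fit_lmm(df, dist, LMMSpec("patristic", interaction=False, estimation="ML"))
            full = fit_lmm(df, dist, LMMSpec("patristic", interaction=True, estimation="ML"))
            lmm_stats.append(2 * (full.log_lik - base.log_lik))
        # with variance components at zero the mixed LRT collapses to OLS's
        diffs = np.abs(np.array(lmm_stats) - np.array(ols_stats[:20]))
        assert np.median(diffs) < 0.05
        assert np.corrcoef(lmm_stats, ols_stats[:20])[0, 1] > 0.98

    def test_ml_aic_invariant_to_distance_rescaling(self, default_run):
        # ML log-likelihood does not depend on an affine rescaling of a
        # fixed-effect column (REML's does, through its log|X'V^-1X| term),
        # so rescaling the distance never flips an ML AIC comparison
        truth = default_run["truth"]
        spec = LMMSpec(distance_kind="patristic", estimation="ML")
        res1 = fit_lmm(default_run["eoc"], truth.patristic, spec)
        scaled = DistanceMatrix(truth.patristic.labels, truth.patristic.values * 3.7, kind="patristic")
        res2 = fit_lmm(default_run["eoc"], scaled, spec)
        assert res2.aic == pytest.approx(res1.aic, abs=1e-3)

        svs = default_run["svs"]
        growth = [growth_distance(svs, ph) for ph in (5.6, 7.0)]
        res_g = fit_lmm(default_run["eoc"], growth, LMMSpec("growth_rate", estimation="ML"))
        ordering = res_g.aic < res1.aic
        ordering_scaled = res_g.aic < res2.aic
        assert ordering == ordering_scaled


def _symmetrize(a):
    out = (a + a.T) / 2
    np.fill_diagonal(out, 0.0)
    return out


class TestDistanceCorrelationCheck:
    def test_exact_collinearity_flagged(self):
        labels = ("A", "B", "C", "D")
        rng = np.random.default_rng(0)
        g = _symmetrize(rng.uniform(0.1, 0.5, (4, 4)))
        growth = [DistanceMatrix(labels, g, kind="growth_rate", ph=ph) for ph in (5.6, 7.0)]
        phylo = DistanceMatrix(labels, 2 * g, kind="patristic")
        res = distance_correlation_check(growth, phylo)
        assert res.collinear
        assert res.slope == pytest.approx(2.0, rel=1e-6)

    def test_study_scale_smoke(self, default_run):
        growth = [growth_distance(default_run["svs"], ph) for ph in (5.6, 7.0)]
        res = distance_correlation_check(growth, default_run["truth"].patristic)
        assert np.isfinite(res.p_value)
        assert res.n_pairs == 10

    def test_too_few_pairs_rejected(self):
        labels = ("A", "B")
        m = DistanceMatrix(labels, np.array([[0.0, 1.0], [1.0, 0.0]]), ph=5.6, kind="growth_rate")
        p = DistanceMatrix(labels, np.array([[0.0, 2.0], [2.0, 0.0]]), kind="patristic")
        with pytest.raises(ValueError, match="pairs"):
            distance_correlation_check([m], p)

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(99)
        labels = tuple("ABCDE")
        rejections = 0
        reps = 200
        for _ in range(reps):
            g = _symmetrize(rng.uniform(0.1, 1.0, (5, 5)))
            ph_mats = [DistanceMatrix(labels, g, kind="growth_rate", ph=ph) for ph in (5.6, 7.0)]
            p_mat = DistanceMatrix(labels, _symmetrize(rng.uniform(0.1, 1.0, (5, 5))), kind="patristic")
            res = distance_correlation_check(ph_mats, p_mat)
            rejections += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= 4 * se
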