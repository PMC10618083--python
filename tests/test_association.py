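"""Logistic fitting, liability-scale R^2, threshold scan, permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from trscore import (
    SeparationError,
    ValidationError,
    best_threshold_scan,
    cox_snell_r2,
    empirical_from_minima,
    empirical_pvalue,
    fit_logistic,
    lee_liability_r2,
    lrt_compare,
    quintile_odds_ratios,
    score_increment_r2,
    standardize,
    trs_prs_correlation,
)
from trscore.association import _batch_score_wald_p, covariate_design, quintile_bins
from trscore.simulate import SimulationConfig, make_truth, simulate_cohort, simulate_twas_panels

from _oracles import pearson_direct


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # cells: a=20 (y=1,x=1), b=10 (y=1,x=0), c=10 (y=0,x=1), d=20
        y = np.r_[np.ones(30), np.zeros(30)]
        x = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        fit = fit_logistic(y, score=x)
        assert fit.estimate == pytest.approx(np.log(4), abs=1e-6)

    def test_perfect_separation_raises(self):
        with pytest.raises(SeparationError):
            fit_logistic([1, 1, 0, 0], score=[1, 1, 0, 0])

    def test_constant_score_is_rank_deficient(self):
        y = [1, 0, 1, 0, 1, 0]
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_logistic(y, score=np.full(6, 3.0))

    def test_one_class_only_rejected(self):
        with pytest.raises(ValidationError, match="both phenotype classes"):
            fit_logistic([1, 1, 1], score=[0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        score = rng.standard_normal(n)
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 60, n), "pc": rng.standard_normal(n)}
        )
        eta = -0.3 + 0.5 * score + 0.02 * (cov["age"] - 40)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, score=score, covariates=cov)
        X = sm.add_constant(np.column_stack([score, cov.to_numpy()]))
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)
        assert fit.score_pvalue == pytest.approx(np.asarray(ref.pvalues)[1], abs=1e-6)

    def test_batched_matches_scalar_path(self):
        rng = np.random.default_rng(7)
        n, B = 90, 40
        X = np.column_stack(
            [np.ones(n), rng.standard_normal(n), rng.standard_normal(n)]
        )
        Y = (rng.random((n, B)) < 0.5).astype(float)
        batched = _batch_score_wald_p(X, Y)
        cov = pd.DataFrame({"c": X[:, 2]})
        scalar = np.array(
            [fit_logistic(Y[:, b], score=X[:, 1], covariates=cov).score_pvalue for b in range(B)]
        )
        assert np.nanmax(np.abs(batched - scalar)) < 1e-10


class TestCoxSnell:
    def _fit_like(self, llf, n):
        from trscore.association import LogisticFit

        s = pd.Series(dtype=float)
        return LogisticFit(params=s, bse=s, pvalues=s, llf=llf, n=n, converged=True)

    def test_zero_when_no_improvement(self):
        assert cox_snell_r2(self._fit_like(-50, 100), self._fit_like(-50, 100)) == 0.0

    def test_direct_evaluation(self):
        r2 = cox_snell_r2(self._fit_like(-45, 100), self._fit_like(-50, 100))
        assert r2 == pytest.approx(1 - np.exp(-0.1), rel=1e-12)

    def test_full_below_null_rejected(self):
        with pytest.raises(ValidationError, match="not nested"):
            cox_snell_r2(self._fit_like(-51, 100), self._fit_like(-50, 100))

    def test_bounded_by_null_likelihood(self):
        ll0, n = -60.0, 100
        r2 = cox_snell_r2(self._fit_like(-1.0, n), self._fit_like(ll0, n))
        assert 0 < r2 < 1 - np.exp(2 * ll0 / n)


class TestLeeLiability:
    def test_zero_maps_to_zero(self):
        assert lee_liability_r2(0.0, 0.05, 0.45).r2_liab == 0.0

    def test_balanced_half_prevalence(self):
        out = lee_liability_r2(0.1, K=0.5, P=0.5)
        assert out.theta == pytest.approx(0.0, abs=1e-12)
        assert out.r2_liab == pytest.approx(0.15708, abs=5e-6)

    def test_five_percent_unascertained(self):
        out = lee_liability_r2(0.01, K=0.05, P=0.05)
        assert out.t == pytest.approx(1.6449, abs=1e-4)
        assert out.z == pytest.approx(0.10314, abs=1e-5)
        assert out.r2_liab == pytest.approx(0.04465, abs=5e-5)

    def test_small_r2_limit_is_linear(self):
        out = lee_liability_r2(1e-4, K=0.05, P=0.45)
        assert abs(out.r2_liab - out.C * 1e-4) / (out.C * 1e-4) < 0.01

    def test_monotone_in_r2_cs(self):
        grid = [lee_liability_r2(r, 0.05, 0.45).r2_liab for r in np.linspace(0, 0.5, 20)]
        assert np.all(np.diff(grid) > 0)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            lee_liability_r2(1.0, 0.05, 0.45)
        with pytest.raises(ValidationError):
            lee_liability_r2(0.1, 0.0, 0.45)


class TestScoreIncrement:
    def test_null_increment_near_zero(self):
        rng = np.random.default_rng(5)
        incs = []
        for _ in range(200):
            n = 500
            y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
            score = rng.standard_normal(n)
            incs.append(score_increment_r2(y, score, None, K=0.05))
        assert np.mean(incs) < 0.01

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(6)
        means = []
        for effect in (0.1, 0.4, 0.8):
            vals = []
            for _ in range(40):
                n = 400
                y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
                score = effect * y + rng.standard_normal(n)
                vals.append(score_increment_r2(y, score, None, K=0.05))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_noise_covariate_barely_moves_increment(self):
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(100):
            n = 400
            y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
            score = 0.3 * y + rng.standard_normal(n)
            noise = pd.DataFrame({"noise": rng.standard_normal(n)})
            a = score_increment_r2(y, score, None, K=0.05)
            b = score_increment_r2(y, score, noise, K=0.05)
            diffs.append(b - a)
        assert abs(np.mean(diffs)) < 0.005

    def test_relative_method_close_to_default(self):
        rng = np.random.default_rng(8)
        n = 400
        y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
        score = 0.4 * y + rng.standard_normal(n)
        a = score_increment_r2(y, score, None, K=0.05, method="transform-then-subtract")
        b = score_increment_r2(y, score, None, K=0.05, method="relative")
        assert a == pytest.approx(b, rel=0.25)


def _signal_setup(seed, **overrides):
    kwargs = dict(
        n_genes=150, n_tissues=1, n_cases=75, n_controls=75,
        causal_fraction=0.1, expr_effect=0.6, twas_effect=5.0,
        covariate_effects=(0.0, 0.0), prs_effect=0.0, n_pcs=2, seed=seed,
    )
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    truth = make_truth(cfg)
    panel = simulate_twas_panels(cfg, truth)[0]
    expr, cohort = simulate_cohort(cfg, truth)
    return panel, standardize(expr), cohort


def _sparse_strong_setup(seed):
    # few very strong TWAS genes among many nulls: the Bonferroni set is
    # (almost surely) exactly the signal, looser thresholds only dilute
    kwargs = dict(
        n_genes=3000, n_tissues=1, n_cases=200, n_controls=200,
        causal_fraction=2 / 3000, expr_effect=0.5, twas_effect=7.0,
        covariate_effects=(0.0, 0.0), prs_effect=0.0, n_pcs=2, seed=seed,
    )
    cfg = SimulationConfig(**kwargs)
    truth = make_truth(cfg)
    panel = simulate_twas_panels(cfg, truth)[0]
    expr, cohort = simulate_cohort(cfg, truth)
    return panel, standardize(expr), cohort


class TestBestThresholdScan:
    def test_single_threshold_identity(self):
        panel, expr_std, cohort = _signal_setup(1)
        scan = best_threshold_scan(panel, expr_std, cohort, thresholds=("0.5",))
        assert scan.best.best_threshold_label == "0.5"
        assert len(scan.rows) == 1

    def test_bonferroni_wins_under_concentrated_signal(self):
        wins = 0
        for rep in range(100):
            panel, expr_std, cohort = _sparse_strong_setup(3000 + rep)
            scan = best_threshold_scan(panel, expr_std, cohort)
            wins += scan.best.best_threshold_label == "BF"
        assert wins >= 80

    def test_all_thresholds_empty_raises(self):
        panel, expr_std, cohort = _signal_setup(2)
        with pytest.raises(ValidationError, match="yields a scoreable"):
            best_threshold_scan(
                panel, expr_std, cohort, thresholds=("0.001",), alpha=0.05,
                transform=lambda sel: type(sel)(
                    tissue=sel.tissue, threshold_label=sel.threshold_label,
                    threshold_value=sel.threshold_value, gene_ids=[], weights=[],
                ),
            )


class TestEmpiricalPvalue:
    def test_lowest_attainable_value(self):
        assert empirical_from_minima(1e-10, np.linspace(0.01, 0.99, 99)) == pytest.approx(0.01)

    def test_median_observed_gives_half(self):
        minima = np.linspace(0.001, 0.999, 100)
        obs = 0.5005  # larger than exactly 50 of the permuted minima
        assert empirical_from_minima(obs, minima) == pytest.approx(51 / 101)

    def test_floor_is_one_over_b_plus_one(self):
        panel, expr_std, cohort = _signal_setup(4)
        emp = empirical_pvalue(panel, expr_std, cohort, B=49, seed=0)
        assert emp >= 1 / 50
        assert emp == pytest.approx(1 / 50)  # strong planted signal

    def test_uniform_under_null(self):
        """TRS association p-values are U(0,1) under the synthetic null."""
        rng_seed = 9000
        pvals = []
        for rep in range(500):
            cfg = SimulationConfig(
                n_genes=40, n_tissues=1, n_cases=50, n_controls=50,
                causal_fraction=0.0, expr_effect=0.0, covariate_effects=(0.0, 0.0),
                prs_effect=0.0, n_pcs=2, seed=rng_seed + rep,
            )
            truth = make_truth(cfg)
            panel = simulate_twas_panels(cfg, truth)[0]
            expr, cohort = simulate_cohort(cfg, truth)
            scan = best_threshold_scan(
                panel, standardize(expr), cohort, thresholds=("1",)
            )
            pvals.append(scan.best.pvalue)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01


class TestQuintiles:
    def test_equal_count_split_n10(self):
        assert np.array_equal(quintile_bins(10), [2, 2, 2, 2, 2])

    def test_remainder_goes_to_lower_bins(self):
        assert np.array_equal(quintile_bins(13), [3, 3, 3, 2, 2])

    def test_q5_vs_q1_matches_contingency_table(self):
        rng = np.random.default_rng(11)
        n = 200
        score = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-score))).astype(float)
        res = quintile_odds_ratios(score, y)
        order = np.argsort(score, kind="mergesort")
        q1, q5 = order[:40], order[-40:]
        a, b = y[q5].sum(), 40 - y[q5].sum()
        c, d = y[q1].sum(), 40 - y[q1].sum()
        assert res.odds_ratios["Q5"] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_per_quintile_coverage(self):
        rng = np.random.default_rng(12)
        cover = np.zeros(4)
        reps = 100
        for _ in range(reps):
            n = 400
            score = rng.standard_normal(n)
            y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
            res = quintile_odds_ratios(score, y)
            for k, q in enumerate(["Q2", "Q3", "Q4", "Q5"]):
                cover[k] += res.ci_low[q] <= 1 <= res.ci_high[q]
        assert (cover / reps >= 0.9).all()

    def test_single_class_quintile_rejected(self):
        score = np.arange(100, dtype=float)
        y = np.r_[np.zeros(20), np.ones(80)]  # Q1 all controls
        with pytest.raises(ValidationError, match="single phenotype class"):
            quintile_odds_ratios(score, y)

    def test_minimum_sample_size(self):
        with pytest.raises(ValidationError, match="n >= 50"):
            quintile_odds_ratios(np.arange(30), np.tile([0, 1], 15))


class TestCorrelation:
    def test_self_and_negation(self, rng):
        v = rng.standard_normal(40)
        out = trs_prs_correlation({"a": v, "b": -v}, v)
        assert out.set_index("trs").loc["a", "r"] == pytest.approx(1.0)
        assert out.set_index("trs").loc["b", "r"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        out = trs_prs_correlation({"x": x}, y)
        assert out.loc[0, "r"] == pytest.approx(pearson_direct(x, y), abs=1e-12)

    def test_bonferroni_column(self, rng):
        out = trs_prs_correlation(
            {f"t{i}": rng.standard_normal(30) for i in range(4)},
            rng.standard_normal(30),
        )
        assert np.allclose(
            out["pvalue_bonferroni"], np.minimum(out["pvalue"] * 4, 1.0)
        )

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValidationError, match="zero variance"):
            trs_prs_correlation({"a": np.ones(10)}, rng.standard_normal(10))


class TestLrt:
    def test_identical_models(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 80).astype(float)
        y[0], y[1] = 0, 1
        fit = fit_logistic(y, score=rng.standard_normal(80))
        stat, df, p = lrt_compare(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_df_counts_added_columns(self, rng):
        n = 120
        y = rng.permutation(np.r_[np.ones(60), np.zeros(60)])
        cov = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        null = fit_logistic(y, covariates=cov[["a"]])
        full = fit_logistic(y, covariates=cov)
        _, df, _ = lrt_compare(null, full)
        assert df == 2

    def test_different_n_rejected(self, rng):
        y1 = np.tile([0, 1], 30).astype(float)
        y2 = np.tile([0, 1], 20).astype(float)
        f1 = fit_logistic(y1, score=rng.standard_normal(60))
        f2 = fit_logistic(y2, score=rng.standard_normal(40))
        with pytest.raises(ValidationError, match="identical samples"):
            lrt_compare(f1, f2)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(500):
            n = 100
            y = rng.permutation(np.r_[np.ones(50), np.zeros(50)])
            noise = rng.standard_normal(n)
            null = fit_logistic(y)
            full = fit_logistic(y, score=noise)
            pvals.append(lrt_compare(null, full)[2])
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_wald_lrt_agree_at_large_n(self):
        rng = np.random.default_rng(15)
        n = 4000
        score = rng.standard_normal(n)
        eta = -0.1 + 0.12 * score
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        full = fit_logistic(y, score=score)
        null = fit_logistic(y)
        lrt_p = lrt_compare(null, full)[2]
        wald_p = full.score_pvalue
        ratio = -np.log10(wald_p) / -np.log10(lrt_p)
        assert 1 / 1.5 < ratio < 1.5
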