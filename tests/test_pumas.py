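"""Summary-statistic partitioning and approximate R^2."""

import numpy as np
import pytest

from netprs.ld import LDMatrix
from netprs.pumas import (approx_r2, estimate_xty, evaluate_repeated,
                          subsample_sumstats)
from netprs.sumstats import SummaryStats


def stats_with_z(z, n):
    m = len(z)
    se = np.full(m, 0.1)
    beta = np.asarray(z) * se
    pval = np.full(m, 0.5)
    return SummaryStats.from_arrays([f"s{j}" for j in range(m)], beta, se,
                                    pval, np.full(m, n))


class TestEstimateXty:
    def test_arithmetic(self):
        xty = estimate_xty(stats_with_z([2.0, 0.0], 10_000))
        np.testing.assert_allclose(xty, [200.0, 0.0])

    def test_matches_dot_product_on_simulated_data(self):
        from netprs.simulate import marginal_gwas
        r = np.random.default_rng(1)
        n, m = 50_000, 8
        x = r.binomial(2, 0.4, size=(n, m)).astype(float)
        y = r.standard_normal(n)
        xty = estimate_xty(marginal_gwas(x, y))
        xs = (x - x.mean(0)) / x.std(0)
        ys = (y - y.mean()) / y.std()
        np.testing.assert_allclose(xty, xs.T @ ys, atol=n * 1e-6)


class TestSubsample:
    def test_zero_covariance_is_deterministic_proportional(self):
        xty = np.array([10.0, -4.0, 2.0])
        part = subsample_sumstats(xty, 1000, ld=None, seed=0)
        np.testing.assert_allclose(part.xty_train, 0.6 * xty)
        np.testing.assert_allclose(part.xty_test, 0.2 * xty)

    def test_partitions_sum_exactly(self):
        rng = np.random.default_rng(2)
        xty = rng.normal(scale=50, size=40)
        part = subsample_sumstats(xty, 5000, ld=LDMatrix.identity(40),
                                  seed=3)
        np.testing.assert_allclose(
            part.xty_train + part.xty_valid + part.xty_test, xty,
            atol=1e-12)
        assert part.n_train + part.n_valid + part.n_test == 5000

    def test_seed_reproducibility(self):
        xty = np.arange(10.0)
        a = subsample_sumstats(xty, 1000, ld=LDMatrix.identity(10), seed=7)
        b = subsample_sumstats(xty, 1000, ld=LDMatrix.identity(10), seed=7)
        np.testing.assert_array_equal(a.xty_train, b.xty_train)
        np.testing.assert_array_equal(a.xty_test, b.xty_test)

    def test_monte_carlo_moments_identity_sigma(self):
        # light version of the sampler-moment check (500 draws, 10 SNPs)
        xty = np.linspace(-30, 30, 10)
        N, draws = 2000, 500
        n_tr = 1200
        samples = np.stack([
            subsample_sumstats(xty, N, ld=LDMatrix.identity(10),
                               seed=s).xty_train
            for s in range(draws)
        ])
        target_var = n_tr * (N - n_tr) / N
        mc_se = samples.std(0, ddof=1) / np.sqrt(draws)
        assert (np.abs(samples.mean(0) - 0.6 * xty) < 4 * mc_se).all()
        assert np.allclose(samples.var(0, ddof=1), target_var, rtol=0.25)

    def test_literal_mean_mode_preserved(self):
        xty = np.array([10.0])
        part = subsample_sumstats(xty, 1000, ld=None, seed=0,
                                  mean_mode="literal")
        np.testing.assert_allclose(part.xty_train, 0.4 * xty)

    def test_bad_fractions_error(self):
        with pytest.raises(ValueError):
            subsample_sumstats(np.ones(3), 100, fractions=(0.5, 0.5, 0.5))


class TestApproxR2:
    def test_zero_weights_give_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            est = approx_r2(np.zeros(3), np.ones(3), 100,
                            np.full(3, 0.01), 1000)
        assert est.value == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=6)
        xty = rng.normal(scale=10, size=6)
        se = np.full(6, 0.02)
        a = approx_r2(w, xty, 200, se, 1000)
        b = approx_r2(2 * w, xty, 200, se, 1000)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_value_nonnegative_and_components(self):
        est = approx_r2(np.array([1.0, -1.0]), np.array([5.0, 3.0]), 100,
                        np.full(2, 0.05), 1000)
        assert est.value >= 0
        assert est.var_y > 0 and est.var_prs > 0

    def test_trimmed_max_guards_outlier_se(self):
        se = np.full(100, 0.01)
        se[0] = 10.0  # absurd outlier
        w = np.ones(100)
        xty = np.ones(100)
        raw = approx_r2(w, xty, 100, se, 1000)
        trimmed = approx_r2(w, xty, 100, se, 1000, trim_max=99.0)
        assert trimmed.var_y < raw.var_y

    def test_tracks_realized_holdout_r2(self):
        # approximate R^2 and realized holdout R^2 rank weights similarly
        from netprs.model import score_prs
        from netprs.simulate import SimConfig, marginal_gwas, simulate_traits
        cfg = SimConfig(n_traits=1, n_samples=4000, n_snps=120,
                        causal_prop=0.05, h2=0.5, rg=0.0, re=0.0,
                        overlap="none", ld_rho=0.0, seed=5)
        cohort = simulate_traits(cfg)
        x, y = cohort.genotypes[0], cohort.Y[0]
        stats = marginal_gwas(x[:3000], y[:3000])
        bt = stats.z / np.sqrt(stats.n)
        se_std = 1.0 / np.sqrt(stats.n)
        hold_x, hold_y = x[3000:], y[3000:]
        xty_hold = estimate_xty(
            marginal_gwas(hold_x, hold_y, trait="holdout"))
        approx, realized = [], []
        for thresh in (0.0, 0.01, 0.02, 0.05):
            w = np.where(np.abs(bt) > thresh, bt, 0.0)
            if not w.any():
                continue
            approx.append(approx_r2(w, xty_hold, 1000, se_std, 1000).value)
            prs = score_prs(hold_x, w, cohort.freqs[0])
            realized.append(np.corrcoef(prs, hold_y)[0, 1] ** 2)
        assert np.corrcoef(approx, realized)[0, 1] > 0.7


class TestEvaluateRepeated:
    def test_constant_w_zero_noise_has_zero_sd(self):
        xty = np.array([50.0, -20.0])
        res = evaluate_repeated(lambda part: np.array([0.01, -0.004]),
                                xty, 1000, ld=None,
                                se=np.full(2, 0.03), n_repeats=4, seed=0)
        assert res["sd"] == 0.0

    def test_single_repeat_mean_is_value(self):
        xty = np.array([50.0, -20.0])
        res = evaluate_repeated(lambda part: np.array([0.01, -0.004]),
                                xty, 1000, ld=LDMatrix.identity(2),
                                se=np.full(2, 0.03), n_repeats=1, seed=1)
        assert res["mean"] == pytest.approx(res["values"][0])

    def test_failing_repeat_recorded_missing(self):
        calls = {"k": 0}

        def flaky(part):
            calls["k"] += 1
            if calls["k"] == 1:
                raise RuntimeError("fit failed")
            return np.array([0.01, 0.01])

        with pytest.warns(UserWarning):
            res = evaluate_repeated(flaky, np.array([5.0, 5.0]), 1000,
                                    ld=None, se=np.full(2, 0.03),
                                    n_repeats=3, seed=2)
        assert np.isnan(res["values"][0])
        assert np.isfinite(res["mean"])
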