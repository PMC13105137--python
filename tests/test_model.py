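"""Coordinate-descent solver, PRS scoring, and grid tuning."""

import numpy as np
import pytest

from conftest import make_panel, random_psd_ld
from netprs.ld import LDMatrix
from netprs.model import (NetPRSModel, PenaltyConfig, fit_netprs, score_prs,
                          soft_threshold, tune_grid)
from oracles import l1_quadratic_oracle


class TestSoftThreshold:
    @pytest.mark.parametrize("w,tau,expected", [
        (0.5, 1.0, 0.0),
        (2.0, 0.5, 1.5),
        (-3.0, 1.0, -2.0),
        (1.0, 1.0, 0.0),
    ])
    def test_values(self, w, tau, expected):
        assert soft_threshold(w, tau) == pytest.approx(expected)

    def test_negative_tau_errors(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestPenaltyConfig:
    def test_tau_inverse_form(self):
        pen = PenaltyConfig(0.1, 0.2, np.array([1.0, 0.5, 0.1]))
        np.testing.assert_allclose(pen.tau, [0.3, 0.5, 2.1])
        assert (pen.tau >= pen.lambda0).all()

    def test_times_form(self):
        pen = PenaltyConfig(0.1, 0.2, np.array([1.0, 0.5]),
                            penalty_form="times")
        np.testing.assert_allclose(pen.tau, [0.3, 0.2])

    def test_rejects_nonpositive_annotation(self):
        with pytest.raises(ValueError):
            PenaltyConfig(0.1, 0.2, np.array([1.0, 0.0]))

    def test_rejects_negative_lambdas(self):
        with pytest.raises(ValueError):
            PenaltyConfig(-0.1, 0.0, np.ones(2))


def uniform_penalty(m, lam0, lam1=0.0):
    return PenaltyConfig(lam0, lam1, np.ones(m))


class TestFitNetPRS:
    def test_single_coordinate_closed_form(self):
        ld = LDMatrix.identity(1)
        model = fit_netprs(np.array([0.3]), ld, uniform_penalty(1, 0.1))
        assert model.beta_hat[0] == pytest.approx(0.2)
        assert model.converged

    def test_full_shrinkage_to_zero(self):
        bt = np.array([0.1, -0.2, 0.05])
        model = fit_netprs(bt, LDMatrix.identity(3),
                           uniform_penalty(3, 0.25))
        np.testing.assert_array_equal(model.beta_hat, 0.0)

    def test_identity_ld_closed_form(self):
        rng = np.random.default_rng(0)
        bt = rng.normal(scale=0.3, size=20)
        tau = rng.uniform(0.01, 0.2, 20)
        pen = PenaltyConfig(0.0, 1.0, 1.0 / tau)  # tau_m = 1/s_m
        model = fit_netprs(bt, LDMatrix.identity(20), pen)
        expected = np.sign(bt) * np.maximum(np.abs(bt) - tau, 0.0)
        np.testing.assert_allclose(model.beta_hat, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_convex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 11))
        ld = random_psd_ld(m, seed=seed + 100)
        bt = rng.normal(scale=0.5, size=m)
        tau = rng.uniform(0.01, 0.3, m)
        pen = PenaltyConfig(0.0, 1.0, 1.0 / tau)
        model = fit_netprs(bt, ld, pen, tol=1e-10, max_iter=5000)
        oracle = l1_quadratic_oracle(ld.dense(), bt, tau)
        np.testing.assert_allclose(model.beta_hat, oracle, atol=1e-5)

    def test_objective_trace_monotone(self):
        rng = np.random.default_rng(11)
        ld = random_psd_ld(40, seed=12, n_blocks=2)
        bt = rng.normal(scale=0.3, size=40)
        model = fit_netprs(bt, ld, uniform_penalty(40, 0.02))
        diffs = np.diff(model.objective_trace)
        assert (diffs <= 1e-10).all()

    def test_annotation_monotonicity_single_sweep(self):
        # larger s -> smaller tau -> weakly larger |beta| after one sweep
        bt = np.array([0.3])
        ld = LDMatrix.identity(1)
        betas = [
            abs(fit_netprs(bt, ld, PenaltyConfig(0.05, 0.1,
                                                 np.array([s])),
                           max_iter=1).beta_hat[0])
            for s in (0.5, 0.8, 1.0)
        ]
        assert betas == sorted(betas)

    def test_warm_start_reaches_same_solution(self):
        rng = np.random.default_rng(13)
        ld = random_psd_ld(15, seed=14)
        bt = rng.normal(scale=0.3, size=15)
        pen = uniform_penalty(15, 0.05)
        cold = fit_netprs(bt, ld, pen, tol=1e-10)
        warm = fit_netprs(bt, ld, pen, tol=1e-10,
                          beta_init=rng.normal(scale=0.1, size=15))
        np.testing.assert_allclose(cold.beta_hat, warm.beta_hat, atol=1e-8)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            fit_netprs(np.zeros(3), LDMatrix.identity(4),
                       uniform_penalty(3, 0.1))


class TestScorePRS:
    def test_zero_weights_zero_scores(self, small_panel):
        prs = score_prs(small_panel.genotypes, np.zeros(10),
                        small_panel.freq)
        np.testing.assert_array_equal(prs, 0.0)

    def test_single_snp_equals_standardized_dosage(self, small_panel):
        beta = np.zeros(10)
        beta[3] = 1.0
        prs = score_prs(small_panel.genotypes, beta, small_panel.freq)
        f = small_panel.freq[3]
        expected = (small_panel.genotypes[:, 3] - 2 * f) / np.sqrt(
            2 * f * (1 - f))
        np.testing.assert_allclose(prs, expected)

    def test_missing_dosages_imputed_at_mean(self):
        panel = make_panel(n=30, m=5, seed=20, missing=0.2)
        prs = score_prs(panel.genotypes, np.ones(5), panel.freq)
        assert np.isfinite(prs).all()

    def test_snp_mismatch_reported(self):
        model = NetPRSModel(beta_hat=np.ones(2),
                            penalty=uniform_penalty(2, 0.0), n_iter=1,
                            converged=True, objective_trace=np.zeros(1),
                            snp_ids=np.array(["a", "b"]))
        with pytest.raises(ValueError, match="b"):
            score_prs(np.zeros((3, 2)), model, np.full(2, 0.3),
                      snp_ids=["a", "c"])

    def test_true_effect_scores_track_genetic_component(self):
        from netprs.simulate import SimConfig, simulate_traits
        cfg = SimConfig(n_traits=1, n_samples=5000, n_snps=200,
                        causal_prop=0.05, h2=0.6, rg=0.0, re=0.0,
                        overlap="none", seed=21)
        cohort = simulate_traits(cfg)
        x = cohort.genotypes[0]
        xs = (x - x.mean(0)) / x.std(0)
        genetic = xs @ cohort.B[:, 0]
        prs = score_prs(x, cohort.B[:, 0], cohort.freqs[0])
        assert np.corrcoef(prs, genetic)[0, 1] > 0.99


class TestTuneGrid:
    def evaluator_factory(self, bt, ld):
        dense = ld.dense()

        def evaluator(model):
            b = model.beta_hat
            num = (bt @ b) ** 2
            den = b @ dense @ b
            return 0.0 if den == 0 else num / den
        return evaluator

    def test_single_cell_returned(self):
        rng = np.random.default_rng(30)
        ld = random_psd_ld(8, seed=31)
        bt = rng.normal(scale=0.3, size=8)
        best, table = tune_grid(bt, ld, np.ones(8), [0.05], [0.0],
                                self.evaluator_factory(bt, ld))
        assert len(table) == 1
        assert best.penalty.lambda0 == 0.05

    def test_degenerate_cell_loses_to_signal(self):
        rng = np.random.default_rng(32)
        ld = random_psd_ld(8, seed=33)
        bt = rng.normal(scale=0.3, size=8)
        big = float(np.abs(bt).max()) + 1.0  # all-zero fit
        best, table = tune_grid(bt, ld, np.ones(8), [big, 0.01], [0.0],
                                self.evaluator_factory(bt, ld))
        assert best.penalty.lambda0 == 0.01
        assert len(best.support) > 0

    def test_failing_cells_excluded(self):
        rng = np.random.default_rng(34)
        ld = random_psd_ld(6, seed=35)
        bt = rng.normal(scale=0.3, size=6)

        def flaky(model):
            if model.penalty.lambda0 < 0.05:
                raise RuntimeError("boom")
            return 1.0

        with pytest.warns(UserWarning, match="boom"):
            best, table = tune_grid(bt, ld, np.ones(6), [0.1, 0.01], [0.0],
                                    flaky)
        assert best.penalty.lambda0 == 0.1
        assert table["valid"].sum() == 1

    def test_all_cells_failing_errors(self):
        ld = LDMatrix.identity(3)
        with pytest.raises(ValueError, match="all tuning-grid cells"):
            tune_grid(np.ones(3), ld, np.ones(3), [0.1], [0.0],
                      lambda model: float("nan"))

    def test_ties_break_to_sparser_model(self):
        ld = LDMatrix.identity(4)
        bt = np.full(4, 0.5)
        best, _ = tune_grid(bt, ld, np.ones(4), [0.2, 0.1], [0.1, 0.0],
                            lambda model: 1.0)  # constant evaluator
        assert best.penalty.lambda0 == 0.2
        assert best.penalty.lambda1 == 0.1
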