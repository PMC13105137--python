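"""Reference PRS methods for benchmarking: C+T, lasso, LDpred-inf.

* Clumping + thresholding: greedy LD clumping (visit SNPs by ascending
  p; keep a SNP unless it is in LD r^2 > r2_max with an already-kept
  SNP in its block), then zero out kept SNPs above each p threshold.
* Summary-statistic lasso: the annotation-free special case of the
  network-weighted solver (lambda1 = 0, s = 1), exposed independently.
* LDpred-inf: closed-form posterior mean under an infinitesimal model,
  per LD block: w = (R + m/(n h2) I)^{-1} beta_tilde.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from netprs.ld import LDMatrix
from netprs.model import PenaltyConfig, fit_netprs
from netprs.sumstats import SummaryStats, standardized_marginal_effects


@dataclass
class BaselineResult:
    """Weight vector from one baseline method at one tuning value."""

    method: str
    weights: np.ndarray
    tuning: float


DEFAULT_P_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def clump_threshold(stats: SummaryStats, ld: LDMatrix,
                    r2_max: float = 0.1,
                    p_grid: Sequence[float] = DEFAULT_P_GRID) -> list:
    """Greedy clumping + p-value thresholding.

    SNPs are visited by ascending p-value; a SNP becomes an index SNP if
    no already-kept SNP within its LD block has r^2 > r2_max with it.
    For each threshold in ``p_grid``, the weights are the standardized
    marginal effects of kept SNPs passing the threshold, zero elsewhere.
    Returns one :class:`BaselineResult` per threshold.
    """
    if not len(p_grid):
        raise ValueError("p_grid must be non-empty")
    pvals = stats.pval
    bt = standardized_marginal_effects(stats)
    m = len(pvals)
    if ld.n_snps != m:
        raise ValueError("summary statistics and LD matrix disagree on SNPs")
    block_of = np.empty(m, int)
    for i, (a, b) in enumerate(ld.bounds):
        block_of[a:b] = i

    kept = np.zeros(m, bool)
    kept_by_block: dict = {}
    for j in np.argsort(pvals, kind="stable"):
        blk_idx = block_of[j]
        blk = ld.blocks[blk_idx]
        a = ld.bounds[blk_idx][0]
        clash = any(blk[j - a, i - a] ** 2 > r2_max
                    for i in kept_by_block.get(blk_idx, ()))
        if not clash:
            kept[j] = True
            kept_by_block.setdefault(blk_idx, []).append(j)

    results = []
    for p_thr in p_grid:
        w = np.where(kept & (pvals < p_thr), bt, 0.0)
        results.append(BaselineResult(method="ct", weights=w,
                                      tuning=float(p_thr)))
    return results


def ldpred_inf(beta_tilde: np.ndarray, ld: LDMatrix, h2: float,
               n: float, m: int | None = None) -> BaselineResult:
    """Infinitesimal-model posterior mean effects, blockwise.

    Solves (R_B + (m/(n h2)) I) w_B = beta_tilde_B in each LD block.
    """
    if not (0.0 < h2):
        raise ValueError("h2 must be positive")
    bt = np.asarray(beta_tilde, float)
    m_total = m if m is not None else len(bt)
    ridge = m_total / (n * h2)
    w = np.empty_like(bt)
    for (a, b), blk in zip(ld.bounds, ld.blocks):
        system = blk + ridge * np.eye(b - a)
        try:
            w[a:b] = sla.solve(system, bt[a:b], assume_a="pos")
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"singular LDpred-inf system in block [{a},{b})") from exc
    return BaselineResult(method="ldpred_inf", weights=w, tuning=float(h2))


def lasso_sumstats(beta_tilde: np.ndarray, ld: LDMatrix,
                   lambda_grid: Sequence[float], tol: float = 1e-4,
                   max_iter: int = 1000) -> list:
    """Plain summary-statistic lasso: the lambda1 = 0 solver path.

    Delegates to the coordinate-descent solver with a uniform penalty
    (s = 1), warm-starting along decreasing lambda. Returns one
    :class:`BaselineResult` per lambda.
    """
    if not len(lambda_grid):
        raise ValueError("lambda_grid must be non-empty")
    bt = np.asarray(beta_tilde, float)
    ones = np.ones_like(bt)
    results = {}
    warm = None
    for lam in sorted(set(float(v) for v in lambda_grid), reverse=True):
        pen = PenaltyConfig(lambda0=lam, lambda1=0.0, s=ones)
        model = fit_netprs(bt, ld, pen, tol=tol, max_iter=max_iter,
                           beta_init=warm)
        warm = model.beta_hat.copy()
        results[lam] = BaselineResult(method="lasso",
                                      weights=model.beta_hat, tuning=lam)
    return [results[float(v)] for v in lambda_grid]
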