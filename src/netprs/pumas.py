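"""Summary-statistic model tuning and evaluation by subsampling X'y.

When individual-level data are unavailable, train/validation/test
pseudo-datasets are drawn from the distribution of the sufficient
statistic X'y. On the standardized scale X_m'y = n_m * beta_tilde_m
= sqrt(n_m) * z_m is computable directly from summary statistics, and a
random subsample of n of the N individuals gives

    X_tr'y_tr | X'y  ~  N( (n/N) X'y,  n(N-n)/N * Sigma )

where Sigma is the per-observation covariance of x_j y, proxied here by
the blockwise reference LD matrix with unit diagonal. Drawing the
training statistic from this conditional and defining the remaining
partitions by subtraction makes the three parts sum *exactly* to the
full statistic.

Prediction R^2 for a weight vector w is approximated without phenotypes:

    R^2  ~=  [ (1/n_eval) sum_m w_m (X_eval'y_eval)_m ]^2
             / ( N max_m(SE_m^2 sigma_m^2) * sum_m w_m^2 sigma_m^2 )

with sigma_m^2 = 2 f_m (1 - f_m) a MAF-based proxy for E[X_m^2]
(identically 1 on the standardized scale). The numerator estimates the
squared trait-score covariance; the denominator's first factor proxies
Var(y) and the second Var(PRS) (no LD term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from netprs.ld import LDMatrix
from netprs.sumstats import SummaryStats, standardized_marginal_effects


@dataclass
class SumstatPartition:
    """Train/validation/test decomposition of the X'y vector.

    Invariants: xty_train + xty_valid + xty_test == xty_full exactly and
    n_train + n_valid + n_test == n_total.
    """

    xty_full: np.ndarray
    xty_train: np.ndarray
    xty_valid: np.ndarray
    xty_test: np.ndarray
    n_train: int
    n_valid: int
    n_test: int
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_valid + self.n_test


@dataclass
class R2Estimate:
    """Approximate prediction R^2 with its components."""

    value: float
    n_eval: int
    numerator: float
    var_y: float
    var_prs: float


def estimate_xty(stats: SummaryStats) -> np.ndarray:
    """Per-SNP X'y on the standardized scale: n_m * beta_tilde_m."""
    bt = standardized_marginal_effects(stats)
    return stats.n * bt


def _block_factors(ld: LDMatrix) -> list:
    """PSD factor L per block with L L' = block (eigendecomposition)."""
    factors = []
    for blk in ld.blocks:
        w, v = np.linalg.eigh(blk)
        factors.append(v * np.sqrt(np.clip(w, 0.0, None)))
    return factors


def _draw_noise(ld: LDMatrix | None, m: int,
                rng: np.random.Generator) -> np.ndarray:
    if ld is None:
        return np.zeros(m)
    if ld.n_snps != m:
        raise ValueError("LD matrix and X'y vector disagree on SNP count")
    out = np.empty(m)
    for (a, b), factor in zip(ld.bounds, _block_factors(ld)):
        out[a:b] = factor @ rng.standard_normal(factor.shape[1])
    return out


def subsample_sumstats(xty_full: np.ndarray, n_total: int,
                       fractions: Sequence[float] = (0.6, 0.2, 0.2),
                       ld: LDMatrix | None = None,
                       seed: int | None = None,
                       mean_mode: str = "subsample") -> SumstatPartition:
    """Draw a train/validation/test partition of the X'y statistic.

    The training part is drawn from the conditional normal with mean
    (n_train/N) * xty_full and covariance n_train(N-n_train)/N * Sigma
    (Sigma = blockwise ``ld``, or 0 when ``ld`` is None, giving the
    deterministic proportional split). The test part is drawn the same
    way from the remainder; validation is the residual, so the parts sum
    exactly. ``mean_mode="literal"`` keeps the (N-n)/N mean scaling of
    the source rendering for sensitivity analysis.
    """
    xty_full = np.asarray(xty_full, float)
    fr = np.asarray(fractions, float)
    if len(fr) != 3 or (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive values summing to 1")
    if mean_mode not in ("subsample", "literal"):
        raise ValueError("mean_mode must be 'subsample' or 'literal'")
    m = len(xty_full)
    n_train = int(round(fr[0] * n_total))
    n_test = int(round(fr[2] * n_total))
    n_valid = n_total - n_train - n_test
    if min(n_train, n_valid, n_test) <= 0:
        raise ValueError("each partition must contain at least one sample")
    rng = np.random.default_rng(seed)

    def draw(stat: np.ndarray, n_part: int, n_pool: int) -> np.ndarray:
        frac = n_part / n_pool
        mean_frac = frac if mean_mode == "subsample" else (n_pool - n_part) / n_pool
        sd = np.sqrt(n_part * (n_pool - n_part) / n_pool)
        return mean_frac * stat + sd * _draw_noise(ld, m, rng)

    xty_train = draw(xty_full, n_train, n_total)
    remainder = xty_full - xty_train
    xty_test = draw(remainder, n_test, n_total - n_train)
    xty_valid = remainder - xty_test
    return SumstatPartition(xty_full=xty_full, xty_train=xty_train,
                            xty_valid=xty_valid, xty_test=xty_test,
                            n_train=n_train, n_valid=n_valid,
                            n_test=n_test, seed=seed)


def approx_r2(w: np.ndarray, xty_eval: np.ndarray, n_eval: int,
              se: np.ndarray, n_total: int,
              sigma2: np.ndarray | None = None,
              trim_max: float | None = None) -> R2Estimate:
    """Summary-statistic approximation of prediction R^2.

    ``se`` are the per-SNP standard errors on the same scale as ``w``
    and ``xty_eval`` (standardized scale throughout the package, where
    ``sigma2`` defaults to 1). ``trim_max`` replaces the max over
    SE^2 sigma^2 by that percentile (e.g. 99.9) to guard outlier SEs.
    The value is invariant to rescaling w.
    """
    w = np.asarray(w, float)
    xty_eval = np.asarray(xty_eval, float)
    se = np.asarray(se, float)
    s2 = np.ones_like(w) if sigma2 is None else np.asarray(sigma2, float)
    var_prs = float(np.sum(w * w * s2))
    scaled = se * se * s2
    var_y = float(n_total * (np.max(scaled) if trim_max is None
                             else np.percentile(scaled, trim_max)))
    if var_prs == 0.0:
        warnings.warn("all-zero weight vector; approximate R^2 is 0")
        return R2Estimate(value=0.0, n_eval=n_eval, numerator=0.0,
                          var_y=var_y, var_prs=0.0)
    numerator = float((w @ xty_eval) / n_eval) ** 2
    return R2Estimate(value=numerator / (var_y * var_prs), n_eval=n_eval,
                      numerator=numerator, var_y=var_y, var_prs=var_prs)


def evaluate_repeated(fit_fn: Callable[[SumstatPartition], np.ndarray],
                      xty_full: np.ndarray, n_total: int,
                      fractions: Sequence[float] = (0.6, 0.2, 0.2),
                      ld: LDMatrix | None = None, se: np.ndarray = None,
                      n_repeats: int = 10, seed: int | None = None) -> dict:
    """Mean and SD of test R^2 over repeated random partitions.

    ``fit_fn`` receives each :class:`SumstatPartition` (train on
    xty_train, tune on xty_valid internally) and returns the weight
    vector to evaluate on the test partition. A failing repeat is
    recorded as missing with a warning; the mean is over completed
    repeats. Identical seeds give bit-identical results.
    """
    if se is None:
        raise ValueError("per-SNP standard errors are required")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats)
    values = np.full(n_repeats, np.nan)
    for i in range(n_repeats):
        part = subsample_sumstats(xty_full, n_total, fractions, ld,
                                  seed=int(child_seeds[i] % (2 ** 31)))
        try:
            w = fit_fn(part)
            values[i] = approx_r2(w, part.xty_test, part.n_test, se,
                                  n_total).value
        except Exception as exc:  # noqa: BLE001 - repeat-level isolation
            warnings.warn(f"repeat {i} failed: {exc}")
    done = values[np.isfinite(values)]
    if len(done) < n_repeats:
        warnings.warn(f"{n_repeats - len(done)} of {n_repeats} repeats "
                      "failed; mean over completed repeats")
    return {"mean": float(done.mean()) if len(done) else np.nan,
            "sd": float(done.std(ddof=1)) if len(done) > 1 else 0.0,
            "values": values}
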