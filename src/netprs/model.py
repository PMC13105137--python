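"""Annotation-weighted L1 penalized regression on summary statistics.

With genotypes and phenotype standardized, the lasso-type objective

    f(beta) = 1/2 beta' R beta - beta_tilde' beta + sum_m tau_m |beta_m|

depends on the data only through the standardized marginal effects
beta_tilde (from summary statistics) and the SNP correlation matrix R
(from a reference panel, block-banded). The per-SNP threshold is

    tau_m = lambda0 + lambda1 / s_m

so SNPs with a larger network annotation s_m are penalized less.
Cyclic coordinate descent solves the problem exactly per coordinate via
soft-thresholding; PSD LD blocks make the objective convex and the
per-sweep objective trace non-increasing. Cross-block LD is zero by
construction, so blocks decouple but are swept in genomic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from netprs.errors import SolverError
from netprs.gpn import AnnotationVector
from netprs.ld import LDMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


def soft_threshold(w: float, tau: float) -> float:
    """Proximal map of the L1 penalty: shrink w toward 0 by tau."""
    if tau < 0:
        raise ValueError("threshold tau must be non-negative")
    if abs(w) <= tau:
        return 0.0
    return np.sign(w) * (abs(w) - tau)


@dataclass
class PenaltyConfig:
    """Penalty (lambda0, lambda1, s) defining tau_m = lambda0 + lambda1/s_m.

    ``penalty_form="times"`` switches to the alternative reading
    tau_m = lambda0 + lambda1 * s_m for sensitivity analysis.
    """

    lambda0: float
    lambda1: float
    s: np.ndarray
    penalty_form: str = "inverse"

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("lambda0 and lambda1 must be non-negative")
        self.s = np.asarray(self.s, float)
        if (self.s <= 0).any():
            raise ValueError("annotation s must be strictly positive; "
                             "apply normalize_annotation with a floor first")
        if self.penalty_form not in ("inverse", "times"):
            raise ValueError("penalty_form must be 'inverse' or 'times'")

    @property
    def tau(self) -> np.ndarray:
        if self.penalty_form == "inverse":
            return self.lambda0 + self.lambda1 / self.s
        return self.lambda0 + self.lambda1 * self.s

    @classmethod
    def from_annotation(cls, lambda0: float, lambda1: float,
                        ann: AnnotationVector, **kw) -> "PenaltyConfig":
        if ann.s is None:
            raise ValueError("annotation is not normalized; call "
                             "normalize_annotation first")
        return cls(lambda0, lambda1, ann.s, **kw)


@dataclass
class NetPRSModel:
    """Fitted standardized effect sizes and solver diagnostics."""

    beta_hat: np.ndarray
    penalty: PenaltyConfig
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    snp_ids: np.ndarray | None = None

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta_hat)


@njit(cache=False)
def _cd_sweep(R, bt, tau, beta, r):  # pragma: no cover - exercised via wrapper
    """One cyclic sweep over a block; updates beta and r = R @ beta in place.

    Relies on R having unit diagonal: the partial residual is
    w_m = bt_m - (r_m - beta_m).
    """
    mb = beta.shape[0]
    maxd = 0.0
    for m in range(mb):
        w = bt[m] - r[m] + beta[m]
        if w > tau[m]:
            b_new = w - tau[m]
        elif w < -tau[m]:
            b_new = w + tau[m]
        else:
            b_new = 0.0
        d = b_new - beta[m]
        if d != 0.0:
            for j in range(mb):
                r[j] += R[j, m] * d
            beta[m] = b_new
            if d < 0.0:
                d = -d
            if d > maxd:
                maxd = d
    return maxd


def _cd_sweep_numpy(R, bt, tau, beta, r):
    mb = beta.shape[0]
    maxd = 0.0
    for m in range(mb):
        w = bt[m] - r[m] + beta[m]
        b_new = soft_threshold(w, tau[m])
        d = b_new - beta[m]
        if d != 0.0:
            r += R[:, m] * d
            beta[m] = b_new
            maxd = max(maxd, abs(d))
    return maxd


def fit_netprs(beta_tilde: np.ndarray, ld: LDMatrix, penalty: PenaltyConfig,
               tol: float = 1e-4, max_iter: int = 1000,
               beta_init: np.ndarray | None = None,
               snp_ids: np.ndarray | None = None) -> NetPRSModel:
    """Cyclic coordinate descent for the annotation-weighted lasso.

    Sweeps all SNPs in genomic order; within a sweep, coordinate m is set
    to S(w_m, tau_m) with w_m = beta_tilde_m - sum_{l != m, same block}
    R_lm beta_l. Starts at beta = 0 (or ``beta_init`` for warm starts)
    and stops when the largest coordinate change in a sweep drops below
    ``tol`` or after ``max_iter`` sweeps. The pseudo-objective
    f(beta) = 1/2 beta'R beta - beta_tilde'beta + sum tau|beta| is
    recorded once per sweep.
    """
    bt = np.ascontiguousarray(beta_tilde, dtype=float)
    m = bt.shape[0]
    if ld.n_snps != m:
        raise ValueError("beta_tilde and LD matrix disagree on SNP count")
    tau = np.ascontiguousarray(penalty.tau, dtype=float)
    if tau.shape[0] != m:
        raise ValueError("penalty annotation and beta_tilde disagree on "
                         "SNP count")
    beta = (np.zeros(m) if beta_init is None
            else np.array(beta_init, dtype=float))
    sweep = _cd_sweep if _HAVE_NUMBA else _cd_sweep_numpy

    blocks = [np.ascontiguousarray(b) for b in ld.blocks]
    bounds = ld.bounds
    r_parts = [blk @ beta[a:b] for (a, b), blk in zip(bounds, blocks)]

    trace = []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        maxd = 0.0
        for (a, b), blk, r in zip(bounds, blocks, r_parts):
            d = sweep(blk, bt[a:b], tau[a:b], beta[a:b], r)
            maxd = max(maxd, d)
        quad = 0.5 * sum(float(beta[a:b] @ r)
                         for (a, b), r in zip(bounds, r_parts))
        obj = quad - float(bt @ beta) + float(tau @ np.abs(beta))
        if not np.isfinite(obj):
            bad = int(np.flatnonzero(~np.isfinite(beta))[0]) \
                if not np.all(np.isfinite(beta)) else -1
            raise SolverError(
                f"non-finite update at SNP index {bad}; increase the LD "
                "shrinkage on the reference panel")
        trace.append(obj)
        if maxd < tol:
            converged = True
            break
    return NetPRSModel(beta_hat=beta, penalty=penalty, n_iter=n_iter,
                       converged=converged,
                       objective_trace=np.asarray(trace), snp_ids=snp_ids)


def score_prs(genotypes: np.ndarray, model: "NetPRSModel | np.ndarray",
              freq: np.ndarray,
              snp_ids: Sequence | None = None) -> np.ndarray:
    """PRS = X_std beta_hat with dosages standardized by reference frequency.

    Dosage m is centered at 2 f_m and scaled by sqrt(2 f_m (1 - f_m));
    missing dosages are imputed at the mean 2 f_m. ``snp_ids`` (column
    ids of ``genotypes``) is checked against the model's SNPs when both
    are available.
    """
    beta = model.beta_hat if isinstance(model, NetPRSModel) else np.asarray(model)
    model_ids = model.snp_ids if isinstance(model, NetPRSModel) else None
    if snp_ids is not None and model_ids is not None:
        given = list(snp_ids)
        missing = [s for s in model_ids if s not in set(given)]
        if missing or len(given) != len(model_ids) or \
                any(a != b for a, b in zip(given, model_ids)):
            raise ValueError(
                f"genotype SNPs do not match model SNPs; missing from "
                f"genotypes: {missing[:10]}")
    freq = np.asarray(freq, float)
    x = np.array(genotypes, dtype=float)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(2.0 * freq, np.nonzero(nan_mask)[1])
    x = (x - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    return x @ beta


def tune_grid(beta_tilde: np.ndarray, ld: LDMatrix, s: np.ndarray,
              lambda0_grid: Sequence[float], lambda1_grid: Sequence[float],
              evaluator: Callable[[NetPRSModel], float],
              tol: float = 1e-4, max_iter: int = 1000,
              penalty_form: str = "inverse") -> tuple:
    """Fit every (lambda0, lambda1) cell and pick the best validation R^2.

    Within each lambda1, lambda0 is traversed in decreasing order with
    warm starts (cold start at beta = 0 for the first cell). Cells where
    the evaluator raises are marked invalid and excluded from the argmax;
    ties break toward larger lambda0 then larger lambda1 (sparser model).
    Returns (best_model, grid_table).
    """
    l0s = sorted(set(float(v) for v in lambda0_grid), reverse=True)
    l1s = sorted(set(float(v) for v in lambda1_grid), reverse=True)
    if not l0s or not l1s:
        raise ValueError("lambda grids must be non-empty")
    rows = []
    best = None  # (r2, lambda0, lambda1, model)
    for l1 in l1s:
        warm = None
        for l0 in l0s:
            pen = PenaltyConfig(l0, l1, s, penalty_form=penalty_form)
            model = fit_netprs(beta_tilde, ld, pen, tol=tol,
                               max_iter=max_iter, beta_init=warm)
            warm = model.beta_hat.copy()
            try:
                r2 = float(evaluator(model))
                valid = np.isfinite(r2)
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                warnings.warn(f"evaluator failed at (lambda0={l0}, "
                              f"lambda1={l1}): {exc}")
                r2, valid = np.nan, False
            rows.append({"lambda0": l0, "lambda1": l1, "r2": r2,
                         "n_iter": model.n_iter, "valid": valid})
            if valid:
                key = (r2, l0, l1)
                if best is None or key > (best[0], best[1], best[2]):
                    best = (r2, l0, l1, model)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("all tuning-grid cells failed evaluation")
    return best[3], table
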