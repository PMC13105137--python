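"""Cross-trait LD score regression for trait selection.

Under a polygenic model, the expected product of two traits' z-scores at
SNP j is

    E[z1_j z2_j | l_j] = sqrt(N1 N2) rho_g l_j / M + rho N_s / sqrt(N1 N2)

where l_j is the LD score, rho_g the genetic covariance, and the
intercept absorbs phenotypic correlation among N_s overlapping samples.
Regressing z1 z2 on sqrt(N1 N2) l / M therefore estimates rho_g robustly
to sample overlap; the univariate specialization (z1 = z2) estimates
heritability. Standard errors come from a delete-one block jackknife
over contiguous SNP blocks, and a candidate trait is declared relevant
to the target when its genetic-covariance p-value clears a Bonferroni
threshold alpha / K.

The estimator here is deliberately plain: unweighted least squares with
a free intercept (an optional 1/l weighting flag), no iterative
reweighting or partitioned heritability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class LdscFit:
    """Result of one LD score regression."""

    slope: float
    intercept: float
    se: float
    pval: float
    n_blocks: int
    rho_g: float | None = None     # cross-trait mode
    h2: float | None = None        # univariate mode


def _block_slices(m: int, n_blocks: int) -> list:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _jackknife(estimator: Callable[[np.ndarray], float],
               m: int, n_blocks: int) -> tuple:
    """Delete-one-block jackknife of a statistic of SNP-index masks."""
    full = estimator(np.ones(m, bool))
    blocks = _block_slices(m, n_blocks)
    nb = len(blocks)
    deletes = np.empty(nb)
    for i, sl in enumerate(blocks):
        mask = np.ones(m, bool)
        mask[sl] = False
        deletes[i] = estimator(mask)
    pseudo = nb * full - (nb - 1) * deletes
    se = float(np.sqrt(np.var(pseudo, ddof=1) / nb))
    return full, se, nb


def _ols(y: np.ndarray, x: np.ndarray, weights: np.ndarray | None = None):
    design = np.column_stack([x, np.ones_like(x)])
    if weights is not None:
        w = np.sqrt(weights)
        design = design * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef  # (slope, intercept)


def _ldsc_core(y, x, n_blocks, weights):
    if np.ptp(x) == 0:
        raise ValueError("LD scores have zero variance; regression undefined")
    m = len(y)
    if m < 10 * n_blocks:
        raise ValueError(
            f"need at least {10 * n_blocks} SNPs for {n_blocks} jackknife "
            "blocks; reduce n_blocks")

    def slope_of(mask):
        w = weights[mask] if weights is not None else None
        return _ols(y[mask], x[mask], w)[0]

    slope, se, nb = _jackknife(slope_of, m, n_blocks)
    intercept = _ols(y, x, weights)[1]
    z = slope / se if se > 0 else np.inf * np.sign(slope)
    pval = float(min(max(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    return slope, intercept, se, pval, nb


def univariate_ldsc(z: np.ndarray, l: np.ndarray, n: float,
                    n_blocks: int = 200, m_snps: int | None = None,
                    weighted: bool = False) -> LdscFit:
    """Heritability from regressing z^2 on n*l/M with a free intercept."""
    z = np.asarray(z, float)
    l = np.asarray(l, float)
    m = m_snps if m_snps is not None else len(z)
    weights = 1.0 / np.maximum(l, 1.0) if weighted else None
    slope, icpt, se, pval, nb = _ldsc_core(z * z, n * l / m, n_blocks, weights)
    return LdscFit(slope=slope, intercept=icpt, se=se, pval=pval,
                   n_blocks=nb, h2=slope)


def cross_trait_ldsc(z1: np.ndarray, z2: np.ndarray, l: np.ndarray,
                     n1: float, n2: float, n_blocks: int = 200,
                     m_snps: int | None = None,
                     weighted: bool = False) -> LdscFit:
    """Genetic covariance from regressing z1*z2 on sqrt(n1 n2)*l/M.

    The free intercept estimates rho*N_s/sqrt(n1 n2) and absorbs sample
    overlap; the p-value tests rho_g = 0 via the jackknife normal
    approximation.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    l = np.asarray(l, float)
    if not (len(z1) == len(z2) == len(l)):
        raise ValueError("z1, z2 and l must share the common SNP set")
    m = m_snps if m_snps is not None else len(z1)
    weights = 1.0 / np.maximum(l, 1.0) if weighted else None
    x = np.sqrt(n1 * n2) * l / m
    slope, icpt, se, pval, nb = _ldsc_core(z1 * z2, x, n_blocks, weights)
    return LdscFit(slope=slope, intercept=icpt, se=se, pval=pval,
                   n_blocks=nb, rho_g=slope)


def genetic_correlation(z1: np.ndarray, z2: np.ndarray, l: np.ndarray,
                        n1: float, n2: float, n_blocks: int = 200,
                        m_snps: int | None = None) -> tuple:
    """Genetic correlation rho_g / sqrt(h1^2 h2^2) with joint jackknife SE.

    All three regressions (cross, and both univariate) are re-fit inside
    each delete-one-block replicate so the SE propagates the shared
    sampling noise. Returns (rg, se).
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    l = np.asarray(l, float)
    m = m_snps if m_snps is not None else len(z1)
    x_cross = np.sqrt(n1 * n2) * l / m
    x1 = n1 * l / m
    x2 = n2 * l / m
    tiny = 1e-8

    def rg_of(mask):
        cov = _ols((z1 * z2)[mask], x_cross[mask])[0]
        h1 = max(_ols((z1 * z1)[mask], x1[mask])[0], tiny)
        h2 = max(_ols((z2 * z2)[mask], x2[mask])[0], tiny)
        return cov / np.sqrt(h1 * h2)

    rg, se, _nb = _jackknife(rg_of, len(z1), n_blocks)
    return rg, se


def select_relevant_traits(target_z: np.ndarray,
                           candidates: Mapping[str, tuple],
                           l: np.ndarray, n_target: float,
                           alpha: float = 0.05, n_blocks: int = 200,
                           m_snps: int | None = None) -> list:
    """Bonferroni selection of traits genetically correlated with the target.

    ``candidates`` maps trait name -> (z-scores, sample size) on the
    common SNP set. A candidate is selected when its cross-trait
    rho_g p-value < alpha / K (K = number of candidates). Returns
    [(name, LdscFit), ...] ordered by ascending p-value.
    """
    if not candidates:
        raise ValueError("candidate trait list is empty")
    k = len(candidates)
    fits = []
    for name, (z, n) in candidates.items():
        fit = cross_trait_ldsc(target_z, z, l, n_target, n,
                               n_blocks=n_blocks, m_snps=m_snps)
        fits.append((name, fit))
    selected = [(name, fit) for name, fit in fits if fit.pval < alpha / k]
    selected.sort(key=lambda item: item[1].pval)
    return selected
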