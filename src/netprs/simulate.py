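"""Matrix-normal multi-trait simulator: genotypes, phenotypes, GWAS.

Phenotypes for K correlated quantitative traits follow Y = X B + E with
standardized genotypes X. Effect sizes B are zero outside a random set
of ceil(p*M) causal SNPs; causal rows are i.i.d. multivariate normal
with covariance Sigma_g / (p*M), where Sigma_g[k,s] =
rg_ks * sqrt(h_k^2 h_s^2) so each trait's realized genetic variance is
h_k^2. Environmental noise rows have covariance Sigma_e with diagonal
1 - h_k^2 and off-diagonal re_ks * sqrt((1-h_k^2)(1-h_s^2)); the
cross-trait noise correlation applies only to individuals shared across
cohorts (overlap "partial"/"complete") — disjoint individuals get
independent noise.

Genotypes come from a Gaussian-copula generator: per-block latent AR(1)
vectors thresholded to Hardy-Weinberg dosages at per-SNP minor allele
frequencies. LD realism is configurable (block size, AR(1) rho), fully
seeded and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from netprs.sumstats import SummaryStats


def _as_corr_matrix(value, k: int, name: str) -> np.ndarray:
    """Scalar off-diagonal value or full matrix -> unit-diagonal matrix."""
    if np.isscalar(value):
        mat = np.full((k, k), float(value))
        np.fill_diagonal(mat, 1.0)
    else:
        mat = np.array(value, float)
        if mat.shape != (k, k):
            raise ValueError(f"{name} must be a {k}x{k} matrix")
        np.fill_diagonal(mat, 1.0)
    if np.abs(mat).max() > 1.0:
        raise ValueError(f"{name} entries must lie in [-1, 1]")
    return mat


def _check_psd(mat: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(mat)
    if w[0] < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite "
                         f"(min eigenvalue {w[0]:.3g})")


@dataclass
class SimConfig:
    """Study-design parameters for one simulated multi-trait dataset.

    Defaults mirror a typical multi-trait GWAS simulation: polygenic
    sparse architecture (1% causal), moderate within-block LD, common
    variants only, environmental correlation 0.1 among overlapping
    samples. ``h2``, ``rg`` and ``re`` accept scalars (shared value) or
    full vectors/matrices.
    """

    n_traits: int = 5
    n_samples: int = 5000
    n_snps: int = 5000
    causal_prop: float = 0.01
    h2: float | Sequence[float] = 0.6
    rg: float | np.ndarray = 0.6
    re: float | np.ndarray = 0.1
    overlap: str = "partial"
    n_shared: int | None = 2000
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 25
    ld_rho: float = 0.5
    seed: int | None = None

    h2_vec: np.ndarray = field(init=False)
    sigma_g: np.ndarray = field(init=False)
    sigma_e: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = self.n_traits
        if k < 1:
            raise ValueError("need at least one trait")
        if not (0.0 < self.causal_prop <= 1.0):
            raise ValueError("causal_prop must lie in (0, 1]")
        h2 = np.full(k, float(self.h2)) if np.isscalar(self.h2) \
            else np.asarray(self.h2, float)
        if h2.shape != (k,) or (h2 < 0).any() or (h2 >= 1).any():
            raise ValueError("h2 must be K values in [0, 1)")
        self.h2_vec = h2
        rg = _as_corr_matrix(self.rg, k, "rg")
        re = _as_corr_matrix(self.re, k, "re")
        self.sigma_g = rg * np.sqrt(np.outer(h2, h2))
        self.sigma_e = re * np.sqrt(np.outer(1.0 - h2, 1.0 - h2))
        np.fill_diagonal(self.sigma_g, h2)
        np.fill_diagonal(self.sigma_e, 1.0 - h2)
        _check_psd(self.sigma_g, "genetic covariance")
        _check_psd(self.sigma_e, "environmental covariance")
        if self.overlap not in ("none", "partial", "complete"):
            raise ValueError("overlap must be none|partial|complete")
        if self.overlap == "partial":
            if self.n_shared is None:
                raise ValueError("partial overlap requires n_shared")
            if self.n_shared > self.n_samples:
                raise ValueError("n_shared cannot exceed n_samples")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")

    @property
    def n_causal(self) -> int:
        return int(np.ceil(self.causal_prop * self.n_snps))


@dataclass
class SimCohort:
    """Simulated genotypes, effects and phenotypes for K traits.

    ``genotypes[k]`` is the dosage matrix for trait k's cohort (the same
    array object is shared across traits where cohorts overlap fully).
    ``B`` is the M x K effect matrix with exactly ceil(p*M) nonzero
    rows; ``Y[k]`` the phenotype vector; ``E`` the noise matrix list.
    """

    genotypes: list
    Y: list
    B: np.ndarray
    E: list
    causal_idx: np.ndarray
    mafs: np.ndarray
    freqs: list
    config: SimConfig


def simulate_genotypes(n: int, m: int, maf_range: tuple = (0.05, 0.5),
                       ld_block_size: int = 25, ld_rho: float = 0.5,
                       seed=None, mafs: np.ndarray | None = None):
    """Hardy-Weinberg dosages with block-AR(1) latent LD.

    Latent per-block Gaussian AR(1)(ld_rho) vectors are thresholded at
    the HWE genotype-class quantiles of each SNP's MAF, giving dosages
    in {0, 1, 2} that count the minor allele. Passing ``mafs`` reuses
    frequencies from an earlier call so independent cohorts and
    reference panels come from the same population. Returns
    (dosages, realized_freq, mafs).
    """
    if n < 1 or m < 1:
        raise ValueError("need at least one individual and one SNP")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lo, hi = maf_range
    if mafs is None:
        mafs = rng.uniform(lo, hi, size=m)
    mafs = np.asarray(mafs, float)
    block = min(max(int(ld_block_size), 1), m)

    z = rng.standard_normal((n, m))
    if ld_rho > 0.0:
        innov = np.sqrt(1.0 - ld_rho ** 2)
        for start in range(0, m, block):
            stop = min(start + block, m)
            for j in range(start + 1, stop):
                z[:, j] = ld_rho * z[:, j - 1] + innov * z[:, j]
    # HWE class thresholds: P(0)=(1-f)^2, P(1)=2f(1-f), P(2)=f^2
    t_lower = sps.norm.ppf((1.0 - mafs) ** 2)
    t_upper = sps.norm.ppf(1.0 - mafs ** 2)
    dosage = (z > t_lower).astype(np.float64) + (z > t_upper)
    freq = dosage.mean(axis=0) / 2.0
    return dosage, freq, mafs


def simulate_effects(m: int, config: SimConfig, seed=None):
    """Sparse matrix-normal effect sizes.

    ceil(p*m) causal SNPs are drawn uniformly without replacement; each
    causal row is i.i.d. N(0, Sigma_g / (p*m)) so per-trait genetic
    variance sums to h_k^2. Returns (B, causal_idx).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = config.n_traits
    n_causal = int(np.ceil(config.causal_prop * m))
    causal = np.sort(rng.choice(m, size=n_causal, replace=False))
    cov = config.sigma_g / (config.causal_prop * m)
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    B = np.zeros((m, k))
    B[causal] = rng.standard_normal((n_causal, k)) @ factor.T
    return B, causal


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_traits(config: SimConfig) -> SimCohort:
    """Full multi-trait cohort under the configured overlap scheme.

    overlap="complete" shares one genotype matrix across all traits;
    "partial" shares the first ``n_shared`` individuals and draws the
    rest independently (from the same MAF/LD population); "none" draws
    every cohort independently. Y_k = X_k_std B_k + E_k with E rows
    jointly multivariate normal (covariance Sigma_e) on shared
    individuals and independent N(0, 1 - h_k^2) elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_samples, config.n_snps, config.n_traits
    gen_kw = dict(maf_range=config.maf_range,
                  ld_block_size=config.ld_block_size,
                  ld_rho=config.ld_rho)

    shared_x, shared_freq, mafs = simulate_genotypes(n, m, seed=rng, **gen_kw)
    genotypes, freqs = [], []
    if config.overlap == "complete":
        n_shared = n
        for _ in range(k):
            genotypes.append(shared_x)
            freqs.append(shared_freq)
    else:
        n_shared = config.n_shared if config.overlap == "partial" else 0
        for t in range(k):
            if t == 0 or n_shared == n:
                genotypes.append(shared_x)
                freqs.append(shared_freq)
                continue
            own_x, _own_freq, _ = simulate_genotypes(
                n - n_shared, m, seed=rng, mafs=mafs, **gen_kw)
            if n_shared > 0:
                x = np.vstack([shared_x[:n_shared], own_x])
            else:
                x = own_x
            genotypes.append(x)
            freqs.append(x.mean(axis=0) / 2.0)

    B, causal = simulate_effects(m, config, seed=rng)

    # noise: joint across traits on shared rows, independent elsewhere
    w, v = np.linalg.eigh(config.sigma_e)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    E = np.empty((n, k))
    shared_rows = n if config.overlap == "complete" else n_shared
    if shared_rows > 0:
        E[:shared_rows] = rng.standard_normal((shared_rows, k)) @ factor.T
    if shared_rows < n:
        E[shared_rows:] = rng.standard_normal((n - shared_rows, k)) \
            * np.sqrt(1.0 - config.h2_vec)

    Y, E_list = [], []
    for t in range(k):
        xs = _standardize(genotypes[t])
        Y.append(xs @ B[:, t] + E[:, t])
        E_list.append(E[:, t])
    return SimCohort(genotypes=genotypes, Y=Y, B=B, E=E_list,
                     causal_idx=causal, mafs=mafs, freqs=freqs,
                     config=config)


def marginal_gwas(x: np.ndarray, y: np.ndarray,
                  snp_ids: Sequence | None = None,
                  trait: str = "trait") -> SummaryStats:
    """Per-SNP simple linear regression of y on dosage.

    For each SNP: slope beta = Sxy/Sxx, residual SE on n-2 df, two-sided
    p from the t distribution. Constant dosage columns are dropped with
    a warning. Returns a :class:`SummaryStats` table (alleles A/G, the
    generator's convention; a1 is the dosage-counted allele).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.shape
    if n < 3:
        raise ValueError("marginal GWAS requires at least 3 individuals")
    ids = np.asarray(snp_ids) if snp_ids is not None \
        else np.array([f"snp{j + 1}" for j in range(m)], dtype=object)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    keep = sxx > 0
    if not keep.all():
        import warnings
        warnings.warn(f"dropped {int((~keep).sum())} constant dosage column(s)")
    xc, sxx, ids_k = xc[:, keep], sxx[keep], ids[keep]
    sxy = xc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.maximum(sigma2 / sxx, np.finfo(float).tiny))
    tstat = beta / se
    pval = np.clip(2.0 * sps.t.sf(np.abs(tstat), df=n - 2), 1e-320, 1.0)
    pos = np.flatnonzero(keep) + 1
    return SummaryStats.from_arrays(
        snp_id=ids_k, beta=beta, se=se, pval=pval,
        n=np.full(keep.sum(), n), pos=pos, trait=trait)
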