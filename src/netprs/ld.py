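"""Reference genotype panels, blockwise LD estimation, and PLINK I/O.

LD is stored block-diagonally: SNPs are split into consecutive windows
(by SNP count or base-pair span) and within-window Pearson correlations
of mean-imputed, standardized dosages are kept; cross-block correlation
is implicitly zero. Off-diagonal shrinkage plus eigenvalue clipping keep
every block positive semidefinite, which guarantees the coordinate
descent objective downstream is convex.

The PLINK bed/bim/fam reader/writer implements the 2-bit SNP-major
encoding directly (magic 0x6c 0x1b 0x01; codes 00=hom A1, 01=missing,
10=het, 11=hom A2); dosages count copies of the bim A1 allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netprs.errors import NetPRSError

# bed 2-bit code -> A1 dosage (NaN = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class ReferencePanel:
    """Genotype panel (individuals x SNPs dosages, 0/1/2, NaN = missing).

    ``meta`` has one row per SNP: snp_id, chrom, pos, a1, a2, aligned to
    the columns of ``genotypes``. ``freq`` is the A1 allele frequency
    computed over non-missing calls.
    """

    genotypes: np.ndarray
    meta: pd.DataFrame
    freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] != len(self.meta):
            raise ValueError("genotype columns and SNP metadata length differ")
        if self.freq is None:
            self.freq = np.nanmean(self.genotypes, axis=0) / 2.0

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.meta["snp_id"].to_numpy()

    def drop_monomorphic(self) -> "ReferencePanel":
        """Return a panel restricted to polymorphic SNPs (freq in (0,1))."""
        freq = np.nanmean(self.genotypes, axis=0) / 2.0
        keep = (freq > 0) & (freq < 1)
        return ReferencePanel(self.genotypes[:, keep],
                              self.meta.loc[keep].reset_index(drop=True),
                              freq[keep])

    def subset(self, snp_ids) -> "ReferencePanel":
        idx = pd.Index(self.meta["snp_id"]).get_indexer(snp_ids)
        if (idx < 0).any():
            missing = np.asarray(snp_ids)[idx < 0][:5]
            raise KeyError(f"SNPs absent from panel: {list(missing)}")
        return ReferencePanel(self.genotypes[:, idx],
                              self.meta.iloc[idx].reset_index(drop=True),
                              self.freq[idx])

    def standardized(self) -> np.ndarray:
        """Mean-imputed, zero-mean, unit-variance dosage matrix."""
        return _standardize_dosages(self.genotypes)

    @classmethod
    def from_bed(cls, prefix) -> "ReferencePanel":
        geno, meta, _fam = read_plink(prefix)
        return cls(geno, meta)


def _standardize_dosages(geno: np.ndarray) -> np.ndarray:
    x = np.array(geno, dtype=float)
    mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(mean, np.nonzero(nan_mask)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise NetPRSError("monomorphic SNP encountered; filter with "
                          "ReferencePanel.drop_monomorphic() first")
    return x / sd


@dataclass
class LDMatrix:
    """Block-diagonal SNP correlation structure.

    ``blocks[i]`` is the symmetric correlation matrix of the SNPs in
    slice ``bounds[i]``; entries outside every block are implicitly 0.
    Diagonals are exactly 1 and each block is PSD (eigenvalues clipped
    at 0 then rescaled back to unit diagonal).
    """

    blocks: list
    bounds: list
    shrinkage: float = 0.0
    n_ref: int | None = None

    @property
    def n_snps(self) -> int:
        return self.bounds[-1][1] if self.bounds else 0

    def dense(self) -> np.ndarray:
        """Materialize the full banded matrix (tests / small M only)."""
        m = self.n_snps
        out = np.zeros((m, m))
        for (a, b), blk in zip(self.bounds, self.blocks):
            out[a:b, a:b] = blk
        return out

    @classmethod
    def identity(cls, m: int) -> "LDMatrix":
        return cls(blocks=[np.eye(m)], bounds=[(0, m)], shrinkage=0.0)

    def save(self, path) -> None:
        """Write blocks to an .npz archive plus a text block index."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"block_{i}": b for i, b in enumerate(self.blocks)})
        idx = pd.DataFrame(self.bounds, columns=["start", "stop"])
        idx["shrinkage"] = self.shrinkage
        idx.to_csv(path.with_suffix(".blocks.tsv"), sep="\t", index=False)


def _block_bounds(m: int, window: int, pos: np.ndarray | None,
                  unit: str) -> list:
    if unit == "snp":
        return [(a, min(a + window, m)) for a in range(0, m, window)]
    if unit != "bp":
        raise ValueError("unit must be 'snp' or 'bp'")
    if pos is None:
        raise ValueError("base-pair windows require SNP positions")
    bounds, start = [], 0
    for j in range(1, m + 1):
        if j == m or pos[j] - pos[start] > window:
            bounds.append((start, j))
            start = j
    return bounds


def _psd_correlation(block: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to a unit-diagonal matrix."""
    w, v = np.linalg.eigh(block)
    if w[0] >= 0:
        return block
    fixed = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def compute_ld(panel: ReferencePanel, window: int = 250,
               shrinkage: float = 0.1, unit: str = "snp") -> LDMatrix:
    """Blockwise LD from a reference panel.

    ``window`` is the block width in SNPs (``unit='snp'``) or base pairs
    (``unit='bp'``, using panel positions). Off-diagonal entries are
    multiplied by (1 - shrinkage) and each block is eigenvalue-clipped
    to PSD. Raises if the panel contains a monomorphic SNP.
    """
    if panel.n_individuals < 2:
        raise ValueError("LD estimation requires at least 2 individuals")
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must lie in [0, 1]")
    x = panel.standardized()
    n, m = x.shape
    pos = panel.meta["pos"].to_numpy() if "pos" in panel.meta else None
    bounds = _block_bounds(m, window, pos, unit)
    blocks = []
    for a, b in bounds:
        blk = (x[:, a:b].T @ x[:, a:b]) / n
        blk = (blk + blk.T) / 2.0
        off = blk - np.diag(np.diag(blk))
        blk = np.eye(b - a) + (1.0 - shrinkage) * off
        blocks.append(_psd_correlation(blk))
    return LDMatrix(blocks=blocks, bounds=bounds, shrinkage=shrinkage, n_ref=n)


def compute_ld_scores(ld: LDMatrix, adjusted: bool = False) -> np.ndarray:
    """Per-SNP LD scores l_j = sum of r^2 over the SNP's block.

    Includes the self term, so l_j >= 1 unadjusted. With ``adjusted``,
    the small-sample correction r2 - (1 - r2)/(n_ref - 2) is applied to
    every term (requires the panel size recorded on the LDMatrix).
    """
    if adjusted and (ld.n_ref is None or ld.n_ref <= 2):
        raise ValueError("adjusted LD scores require n_ref > 2")
    out = np.empty(ld.n_snps)
    for (a, b), blk in zip(ld.bounds, ld.blocks):
        r2 = blk ** 2
        if adjusted:
            r2 = r2 - (1.0 - r2) / (ld.n_ref - 2)
        out[a:b] = r2.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def read_plink(prefix):
    """Read a PLINK bed/bim/fam fileset.

    Returns (dosages, bim, fam): dosages is individuals x SNPs counting
    the bim A1 allele, NaN for missing; bim has columns snp_id, chrom,
    pos, a1, a2; fam has fid, iid, phenotype.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "phenotype"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != b"\x6c\x1b\x01":
        raise NetPRSError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bpv = (n + 3) // 4
    body = raw[3:].reshape(m, bpv)
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    geno = _BED_DECODE[codes[:, :n]].T
    meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return geno, meta, fam


def write_plink(prefix, dosages: np.ndarray, meta: pd.DataFrame,
                sample_ids=None, phenotype=None) -> None:
    """Write dosages (A1 counts, NaN = missing) as PLINK bed/bim/fam."""
    prefix = Path(prefix)
    n, m = dosages.shape
    bim = pd.DataFrame({
        "chrom": meta.get("chrom", pd.Series(np.ones(m, int))).to_numpy(),
        "snp_id": meta["snp_id"].to_numpy(),
        "cm": np.zeros(m, int),
        "pos": meta.get("pos", pd.Series(np.arange(1, m + 1))).to_numpy(),
        "a1": meta.get("a1", pd.Series(["A"] * m)).to_numpy(),
        "a2": meta.get("a2", pd.Series(["G"] * m)).to_numpy(),
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    ids = sample_ids if sample_ids is not None else [f"S{i+1}" for i in range(n)]
    pheno = phenotype if phenotype is not None else np.full(n, -9)
    fam = pd.DataFrame({"fid": ids, "iid": ids, "pid": 0, "mid": 0,
                        "sex": 0, "phenotype": pheno})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # dosage -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    code = np.full(dosages.T.shape, 0b01, dtype=np.uint8)
    d = dosages.T
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate(
            [code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = np.zeros((m, code.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        packed.tofile(fh)
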