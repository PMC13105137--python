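"""Reading, harmonization and standardization of GWAS summary statistics.

A summary-statistics table carries per-SNP marginal association results for
one trait: effect size ``beta`` (per-allele scale), its standard error
``se``, two-sided p-value ``pval``, and the per-SNP sample size ``n``,
keyed by SNP identifier with the effect allele ``a1`` and other allele
``a2``. Everything downstream of this module runs on the *standardized*
scale beta_tilde = (beta/se)/sqrt(n) = z/sqrt(n), which is the marginal
effect after genotype and phenotype are scaled to unit variance, so the
per-allele scale never reaches the solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from netprs.errors import FormatError, HarmonizationError

if TYPE_CHECKING:  # pragma: no cover
    from netprs.ld import ReferencePanel

logger = logging.getLogger(__name__)

#: Canonical column -> accepted header aliases (matched case-insensitively).
COLUMN_ALIASES: Mapping[str, Sequence[str]] = {
    "snp_id": ("snp", "snp_id", "rsid", "id", "marker", "markername"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "a1": ("a1", "effect_allele", "alt", "allele1"),
    "a2": ("a2", "other_allele", "ref", "allele2", "allele0"),
    "beta": ("beta", "effect", "b", "effect_size"),
    "se": ("se", "stderr", "standard_error"),
    "pval": ("p", "pval", "p_value", "pvalue"),
    "n": ("n", "n_samples", "sample_size", "neff"),
}

MANDATORY = ("snp_id", "a1", "a2", "beta", "se", "pval", "n")

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStats:
    """Per-SNP marginal association results for a single trait.

    ``table`` holds one row per SNP with columns snp_id, chrom, pos, a1,
    a2, beta, se, pval, n. Invariants: se > 0, pval in (0, 1], n >= 2,
    snp_id unique.
    """

    table: pd.DataFrame
    trait: str = "trait"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r} in trait {self.trait!r}")
        if len(t) and ((t["se"] <= 0).any() or (t["n"] < 2).any()):
            raise FormatError("se must be > 0 and n >= 2 for every retained SNP")
        if len(t) and ((t["pval"] <= 0).any() or (t["pval"] > 1).any()):
            raise FormatError("pval must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)

    @property
    def se(self) -> np.ndarray:
        return self.table["se"].to_numpy(float)

    @property
    def pval(self) -> np.ndarray:
        return self.table["pval"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        """Per-SNP z-scores beta/se."""
        return self.beta / self.se

    @classmethod
    def from_arrays(cls, snp_id, beta, se, pval, n, a1=None, a2=None,
                    chrom=None, pos=None, trait: str = "trait") -> "SummaryStats":
        m = len(snp_id)
        table = pd.DataFrame({
            "snp_id": np.asarray(snp_id, dtype=object),
            "chrom": np.ones(m, int) if chrom is None else np.asarray(chrom),
            "pos": np.arange(1, m + 1) if pos is None else np.asarray(pos),
            "a1": np.full(m, "A") if a1 is None else np.asarray(a1, dtype=object),
            "a2": np.full(m, "G") if a2 is None else np.asarray(a2, dtype=object),
            "beta": np.asarray(beta, float),
            "se": np.asarray(se, float),
            "pval": np.asarray(pval, float),
            "n": np.asarray(n, float),
        })
        return cls(table, trait=trait)


def _resolve_columns(header: Sequence[str]) -> dict:
    lower = {c.lower(): c for c in header}
    mapping = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                mapping[canon] = lower[a]
                break
    return mapping


def read_sumstats(path, trait: str = "trait",
                  aliases: Mapping[str, Sequence[str]] | None = None) -> SummaryStats:
    """Read a tab-delimited GWAS summary-statistics file.

    The header must name at least the snp/a1/a2/beta/se/pval/n columns
    (any alias in :data:`COLUMN_ALIASES`, or the ``aliases`` override).
    Rows with missing or invalid values (se <= 0, pval outside (0, 1],
    n < 2, NaN in a mandatory field) are dropped with a logged count.
    Output is sorted by (chrom, pos).
    """
    raw = pd.read_csv(path, sep="\t")
    if raw.empty:
        raise FormatError(f"{path}: empty summary-statistics file")
    alias_map = dict(COLUMN_ALIASES)
    if aliases:
        for k, v in aliases.items():
            alias_map[k] = tuple(v) + tuple(alias_map.get(k, ()))
    lower = {c.lower(): c for c in raw.columns}
    mapping = {}
    for canon, al in alias_map.items():
        for a in al:
            if a.lower() in lower:
                mapping[canon] = lower[a.lower()]
                break
    for canon in MANDATORY:
        if canon not in mapping:
            raise FormatError(f"{path}: missing mandatory column {canon!r}")

    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    if "chrom" not in df:
        df["chrom"] = 1
    if "pos" not in df:
        df["pos"] = np.arange(1, len(df) + 1)
    for col in ("beta", "se", "pval", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()

    ok = (
        df[list(MANDATORY)].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["n"] >= 2)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    df = df.loc[ok].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if df.empty:
        raise FormatError(f"{path}: no valid rows after filtering")
    return SummaryStats(df, trait=trait, n_dropped=n_dropped)


def harmonize(stats: SummaryStats, panel: "ReferencePanel",
              drop_ambiguous: bool = True) -> SummaryStats:
    """Align summary statistics to a reference panel's SNPs and alleles.

    SNPs are restricted to the panel intersection and reordered to panel
    order. Where the effect/other alleles are swapped relative to the
    panel, the effect-size sign is flipped and the alleles relabeled.
    Strand-ambiguous palindromic SNPs (A/T, C/G) are dropped when
    ``drop_ambiguous`` is set; allele pairs irreconcilable with the panel
    are dropped and counted. The operation is idempotent.
    """
    meta = panel.meta.set_index("snp_id")
    t = stats.table
    shared = t["snp_id"].isin(meta.index)
    if not shared.any():
        raise HarmonizationError(
            f"no SNPs shared between trait {stats.trait!r} and the panel")
    t = t.loc[shared].copy()
    pa1 = meta.loc[t["snp_id"], "a1"].to_numpy(object)
    pa2 = meta.loc[t["snp_id"], "a2"].to_numpy(object)
    a1 = t["a1"].to_numpy(object)
    a2 = t["a2"].to_numpy(object)

    same = (a1 == pa1) & (a2 == pa2)
    swapped = (a1 == pa2) & (a2 == pa1)
    palindromic = np.array([(x, y) in _PALINDROMIC for x, y in zip(a1, a2)])
    keep = (same | swapped)
    if drop_ambiguous:
        keep &= ~palindromic
    n_mismatch = int((~(same | swapped)).sum())
    if n_mismatch:
        logger.info("trait %s: %d SNP(s) with irreconcilable alleles dropped",
                    stats.trait, n_mismatch)

    t = t.loc[keep].copy()
    flip = swapped[keep]
    t.loc[flip, "beta"] = -t.loc[flip, "beta"].to_numpy()
    t.loc[flip, ["a1", "a2"]] = t.loc[flip, ["a2", "a1"]].to_numpy()
    if t.empty:
        raise HarmonizationError(
            f"trait {stats.trait!r}: zero SNPs survived harmonization")
    order = pd.Index(panel.meta["snp_id"])
    kept_ids = pd.Index(t["snp_id"])
    t = t.set_index("snp_id").loc[order.intersection(kept_ids, sort=False)]
    t = t.reset_index().reset_index(drop=True)
    return SummaryStats(t, trait=stats.trait,
                        n_dropped=stats.n_dropped + n_mismatch)


def standardized_marginal_effects(stats: SummaryStats) -> np.ndarray:
    """Marginal effects on the standardized-genotype scale.

    beta_tilde_m = (beta_m / se_m) / sqrt(n_m), i.e. the z-score scaled by
    the per-SNP sample size; equals (1/n) X_m'y when genotype and
    phenotype have zero mean and unit variance.
    """
    n = stats.n
    if (n <= 0).any():
        raise ValueError("non-positive sample size in summary statistics")
    bt = stats.z / np.sqrt(n)
    if not np.all(np.isfinite(bt)):
        raise ValueError("non-finite standardized effect encountered")
    return bt
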