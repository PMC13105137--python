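"""Signed genotype-phenotype bipartite network (GPN) and SNP centralities.

The GPN links M SNPs to K traits. The edge between SNP m and trait k
carries the signed association strength

    T_mk = sign(beta_mk) * Q_chi2_1(1 - p_mk),

the 1-df chi-square quantile of the complement of the marginal p-value,
signed by the effect direction; T recovers z^2 up to sign. Two per-SNP
annotations summarize a SNP's role across traits:

* degree: d_m = sum_k |T_mk| — aggregate association strength; high
  degree marks candidate pleiotropic variants.
* approximate betweenness: on the binarized graph (edge iff
  p_mk < edge_alpha), every trait-trait shortest path has length 2
  through a SNP adjacent to both, so
  b_m = sum_{k<s} sigma_ks(m) / max(sigma_ks, 1), where sigma_ks counts
  SNPs adjacent to both traits and sigma_ks(m) is 1 iff SNP m is.

Annotations are rescaled to s_m in (0, 1] (max normalization with a
positive floor) before entering the penalty; a SNP with larger s_m
receives a smaller penalty downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from netprs.sumstats import SummaryStats

_P_CLAMP = 1e-300


@dataclass
class GPNetwork:
    """Signed SNP x trait association-strength matrix plus topology inputs."""

    T: np.ndarray                 # M x K signed strengths
    pvals: np.ndarray             # M x K marginal p-values
    snp_ids: np.ndarray
    traits: Sequence[str]
    edge_alpha: float = 0.05

    @property
    def n_snps(self) -> int:
        return self.T.shape[0]

    @property
    def n_traits(self) -> int:
        return self.T.shape[1]

    @property
    def adjacency(self) -> np.ndarray:
        """Binarized topology: edge(m, k) iff p_mk < edge_alpha."""
        return self.pvals < self.edge_alpha


@dataclass
class AnnotationVector:
    """Per-SNP raw centrality and its normalized (0, 1] version."""

    raw: np.ndarray
    kind: str                      # "degree" | "betweenness"
    s: np.ndarray | None = None    # filled by normalize_annotation


def edge_weight(beta, pval):
    """Signed association strength sign(beta) * Q_chi2_1(1 - pval).

    Accepts scalars or arrays; pval must lie in (0, 1] and is clamped
    below at 1e-300 before quantile inversion. pval == 1 maps to 0.
    """
    beta = np.asarray(beta, float)
    pval = np.asarray(pval, float)
    if np.any(pval <= 0) or np.any(pval > 1):
        raise ValueError("pval must lie in (0, 1]")
    p = np.clip(pval, _P_CLAMP, 1.0)
    strength = sps.chi2.isf(p, df=1)
    sign = np.where(beta >= 0, 1.0, -1.0)
    out = sign * strength
    return float(out) if out.ndim == 0 else out


def build_gpn(stats_list: Sequence[SummaryStats], edge_alpha: float = 0.05,
              magnitude: str = "chi2") -> GPNetwork:
    """Assemble the signed GPN from K traits' harmonized summary statistics.

    All traits must share the same SNP-id sequence. ``magnitude`` selects
    the edge scale: "chi2" (the quantile, default) or "abs_z" (its square
    root, |z|). Entries whose p-value hits the 1e-300 clamp use z^2 (or
    |z|) computed from beta/se directly, avoiding quantile saturation.
    """
    if not stats_list:
        raise ValueError("need at least one trait")
    ids = stats_list[0].snp_ids
    for st in stats_list[1:]:
        if len(st) != len(ids) or not np.array_equal(st.snp_ids, ids):
            raise ValueError(
                "traits do not share the same SNP set; intersect and "
                "harmonize all traits to a common panel first")
    if magnitude not in ("chi2", "abs_z"):
        raise ValueError("magnitude must be 'chi2' or 'abs_z'")
    m, k = len(ids), len(stats_list)
    T = np.empty((m, k))
    P = np.empty((m, k))
    for j, st in enumerate(stats_list):
        P[:, j] = st.pval
        T[:, j] = edge_weight(st.beta, st.pval)
        clamped = st.pval < _P_CLAMP
        if clamped.any():
            z2 = (st.beta[clamped] / st.se[clamped]) ** 2
            T[clamped, j] = np.sign(T[clamped, j]) * z2
        if magnitude == "abs_z":
            T[:, j] = np.sign(T[:, j]) * np.sqrt(np.abs(T[:, j]))
    traits = [st.trait for st in stats_list]
    return GPNetwork(T=T, pvals=P, snp_ids=np.asarray(ids),
                     traits=traits, edge_alpha=edge_alpha)


def degree_centrality(gpn: GPNetwork, signed: bool = False) -> AnnotationVector:
    """Weighted degree d_m = sum_k |T_mk| (signed sum behind a flag)."""
    if signed:
        raw = gpn.T.sum(axis=1)
    else:
        raw = np.abs(gpn.T).sum(axis=1)
    return AnnotationVector(raw=raw, kind="degree")


def betweenness_centrality(gpn: GPNetwork) -> AnnotationVector:
    """Approximate betweenness on the binarized bipartite graph.

    For each trait pair (k, s), every SNP adjacent to both lies on one
    shortest (length-2) path; the pair's unit mass is split evenly over
    those SNPs. Disconnected pairs contribute nothing.
    """
    adj = gpn.adjacency
    m, k = adj.shape
    b = np.zeros(m)
    for i in range(k):
        for j in range(i + 1, k):
            shared = adj[:, i] & adj[:, j]
            sigma = int(shared.sum())
            if sigma > 0:
                b[shared] += 1.0 / sigma
    return AnnotationVector(raw=b, kind="betweenness")


def normalize_annotation(raw: AnnotationVector,
                         floor: float = 0.01) -> AnnotationVector:
    """Max-normalize raw scores into s_m in (0, 1] with a positive floor.

    s_m = max(raw_m / max_l raw_l, floor). When every raw score is 0 the
    annotation carries no information and s is set to all ones, reducing
    the penalty to a uniform lasso.
    """
    if not (0.0 < floor <= 1.0):
        raise ValueError("floor must lie in (0, 1]")
    if (raw.raw < 0).any():
        raise ValueError("raw annotation scores must be non-negative")
    top = raw.raw.max() if raw.raw.size else 0.0
    if top <= 0:
        s = np.ones_like(raw.raw, dtype=float)
    else:
        s = np.maximum(raw.raw / top, floor)
    return AnnotationVector(raw=raw.raw, kind=raw.kind, s=s)
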