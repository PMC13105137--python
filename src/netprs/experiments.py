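"""End-to-end simulation experiments: the full NetPRS pipeline.

These helpers chain every stage — multi-trait simulation, per-trait
GWAS, LDSC trait selection, GPN annotation, penalized fitting, tuning
and evaluation — in the two modes the method supports:

* individual-level: samples split 60/20/20 into train/validation/test;
  the model is trained on the training split's GWAS, tuned by realized
  validation R^2, and reported as realized test R^2 (squared Pearson
  correlation between PRS and phenotype);
* summary-statistic: the full-sample GWAS is partitioned by
  conditional-normal subsampling of X'y, tuned and evaluated with the
  summary-statistic R^2 approximation.

The benchmark scale used throughout (N=2000 individuals, M=1000 SNPs,
5 repeats for the concordance grid; M=500 for the head-to-head
comparison) is the package's desk-scale study design; the simulator
accepts larger sizes unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from netprs.gpn import (betweenness_centrality, build_gpn, degree_centrality,
                        normalize_annotation)
from netprs.ld import LDMatrix, ReferencePanel, compute_ld, compute_ld_scores
from netprs.ldsc import select_relevant_traits
from netprs.model import score_prs, tune_grid
from netprs.pumas import approx_r2, estimate_xty, subsample_sumstats
from netprs.simulate import SimConfig, marginal_gwas, simulate_genotypes, \
    simulate_traits
from netprs.sumstats import standardized_marginal_effects

#: lambda grids as fractions of max |beta_tilde|
LAMBDA0_FRACS = (0.5, 0.3, 0.15, 0.08, 0.04, 0.02)
LAMBDA1_FRACS = (0.0, 0.01, 0.05, 0.15)


def spawn_seeds(seed: int | None, n: int) -> list:
    """n reproducible child seeds below 2^31."""
    return [int(s % (2 ** 31))
            for s in np.random.SeedSequence(seed).generate_state(n)]


def simulate_study(n_traits: int, n_samples: int, n_snps: int, h2: float,
                   rg: float, overlap: str = "partial",
                   n_shared: int | None = None, causal_prop: float = 0.01,
                   re: float = 0.1, n_ref: int = 500, ld_window: int = 250,
                   shrinkage: float = 0.1, seed: int | None = None) -> dict:
    """Simulate a multi-trait cohort plus a matched reference panel.

    The reference panel is an independent sample from the same
    population (same MAFs and LD structure) used for LD estimation,
    allele frequencies and LD scores, mirroring the role of an external
    panel. Returns a dict with cohort, panel, ld, ld_scores, and the
    per-trait GWAS summary statistics on the full samples.
    """
    if overlap == "partial" and n_shared is None:
        n_shared = int(round(0.4 * n_samples))
    config = SimConfig(n_traits=n_traits, n_samples=n_samples,
                       n_snps=n_snps, causal_prop=causal_prop, h2=h2,
                       rg=rg, re=re, overlap=overlap, n_shared=n_shared,
                       seed=seed)
    cohort = simulate_traits(config)
    ref_x, ref_freq, _ = simulate_genotypes(
        n_ref, n_snps, maf_range=config.maf_range,
        ld_block_size=config.ld_block_size, ld_rho=config.ld_rho,
        seed=np.random.default_rng(None if seed is None else seed + 7),
        mafs=cohort.mafs)
    meta = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(n_snps)],
        "chrom": 1, "pos": np.arange(1, n_snps + 1),
        "a1": "A", "a2": "G"})
    panel = ReferencePanel(ref_x, meta, ref_freq)
    ld = compute_ld(panel, window=ld_window, shrinkage=shrinkage)
    ld_scores = compute_ld_scores(ld, adjusted=True)
    gwas = [marginal_gwas(cohort.genotypes[t], cohort.Y[t],
                          trait=f"trait{t + 1}")
            for t in range(n_traits)]
    return {"cohort": cohort, "panel": panel, "ld": ld,
            "ld_scores": ld_scores, "gwas": gwas, "config": config}


def annotation_weights(study: dict, kind: str = "degree",
                       edge_alpha: float = 0.05, floor: float = 0.01,
                       alpha: float = 0.05, select: bool = True):
    """Normalized annotation s from the relevant traits' GPN.

    Candidate traits (all but the target, trait index 0) are screened by
    cross-trait LDSC against the target at the Bonferroni level
    alpha/K; if none clears it, all candidates are used so the
    annotation stays defined. Returns (s, selected_trait_names).
    """
    gwas = study["gwas"]
    n_snps = len(gwas[0])
    candidates = {st.trait: (st.z, float(np.median(st.n)))
                  for st in gwas[1:]}
    names = list(candidates)
    if select and len(candidates) > 1:
        n_blocks = max(10, n_snps // 20)
        picked = select_relevant_traits(
            gwas[0].z, candidates, study["ld_scores"],
            float(np.median(gwas[0].n)), alpha=alpha, n_blocks=n_blocks)
        if picked:
            names = [name for name, _fit in picked]
    stats_list = [st for st in gwas[1:] if st.trait in set(names)]
    gpn = build_gpn(stats_list, edge_alpha=edge_alpha)
    ann = degree_centrality(gpn) if kind == "degree" \
        else betweenness_centrality(gpn)
    return normalize_annotation(ann, floor=floor).s, names


def _lambda_grids(beta_tilde: np.ndarray, include_annotation: bool = True):
    top = float(np.max(np.abs(beta_tilde)))
    l0 = [f * top for f in LAMBDA0_FRACS]
    l1 = [f * top for f in (LAMBDA1_FRACS if include_annotation else (0.0,))]
    return l0, l1


def _realized_r2(prs: np.ndarray, y: np.ndarray) -> float:
    if prs.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(prs, y)[0, 1] ** 2)


def individual_level_r2(study: dict, s: np.ndarray, seed: int | None,
                        annotated: bool = True,
                        fractions=(0.6, 0.2, 0.2)) -> float:
    """Tuned NetPRS test R^2 from individual-level 60/20/20 splits."""
    cohort = study["cohort"]
    panel, ld = study["panel"], study["ld"]
    x, y = cohort.genotypes[0], cohort.Y[0]
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    idx_tr = perm[:n_tr]
    idx_va = perm[n_tr:n_tr + n_va]
    idx_te = perm[n_tr + n_va:]

    stats_tr = marginal_gwas(x[idx_tr], y[idx_tr], trait="target_train")
    bt = standardized_marginal_effects(stats_tr)
    l0, l1 = _lambda_grids(bt, include_annotation=annotated)

    def evaluator(model):
        prs = score_prs(x[idx_va], model.beta_hat, panel.freq)
        return _realized_r2(prs, y[idx_va])

    best, _table = tune_grid(bt, ld, s, l0, l1, evaluator)
    prs_te = score_prs(x[idx_te], best.beta_hat, panel.freq)
    return _realized_r2(prs_te, y[idx_te])


def sumstat_level_r2(study: dict, s: np.ndarray, seed: int | None,
                     annotated: bool = True,
                     fractions=(0.6, 0.2, 0.2)) -> float:
    """Tuned NetPRS test R^2 from PUMAS-style summary-stat partitions."""
    ld = study["ld"]
    stats = study["gwas"][0]
    n_total = int(np.median(stats.n))
    xty = estimate_xty(stats)
    part = subsample_sumstats(xty, n_total, fractions, ld, seed=seed)
    bt_train = part.xty_train / part.n_train
    se_std = 1.0 / np.sqrt(stats.n)  # SE of beta_tilde on the unit scale
    l0, l1 = _lambda_grids(bt_train, include_annotation=annotated)

    def evaluator(model):
        return approx_r2(model.beta_hat, part.xty_valid, part.n_valid,
                         se_std, n_total).value

    best, _table = tune_grid(bt_train, ld, s, l0, l1, evaluator)
    return approx_r2(best.beta_hat, part.xty_test, part.n_test,
                     se_std, n_total).value


CONCORDANCE_SETTINGS = tuple(
    {"n_traits": k, "h2": h2, "rg": rg}
    for k in (5, 10) for h2 in (0.2, 0.6) for rg in (0.1, 0.6))


def concordance_experiment(seed: int | None = None, n_repeats: int = 5,
                           n_samples: int = 2000, n_snps: int = 1000,
                           kind: str = "degree") -> dict:
    """Individual-level vs summary-statistic evaluation concordance.

    For each of 8 settings (K in {5,10} x h2 in {0.2,0.6} x rg in
    {0.1,0.6}; causal proportion 0.01, environmental correlation 0.1,
    partial overlap with 40% shared individuals), the tuned NetPRS test
    R^2 is averaged over ``n_repeats`` repeats in both evaluation
    modes; the Pearson correlation of the 8 paired averages measures
    their concordance.
    """
    seeds = spawn_seeds(seed, n_repeats * len(CONCORDANCE_SETTINGS))
    indiv, sumstat = [], []
    for i, setting in enumerate(CONCORDANCE_SETTINGS):
        vals_i, vals_s = [], []
        for r in range(n_repeats):
            sd = seeds[i * n_repeats + r]
            study = simulate_study(
                n_samples=n_samples, n_snps=n_snps, overlap="partial",
                n_shared=int(round(0.4 * n_samples)), seed=sd, **setting)
            s, _names = annotation_weights(study, kind=kind)
            vals_i.append(individual_level_r2(study, s, seed=sd))
            vals_s.append(sumstat_level_r2(study, s, seed=sd))
        indiv.append(float(np.mean(vals_i)))
        sumstat.append(float(np.mean(vals_s)))
    r = float(np.corrcoef(indiv, sumstat)[0, 1])
    return {"settings": CONCORDANCE_SETTINGS, "individual": indiv,
            "sumstat": sumstat, "pearson_r": r}


def head_to_head(seed: int | None = None, n_seeds: int = 10,
                 n_traits: int = 5, n_samples: int = 2000,
                 n_snps: int = 500, h2: float = 0.6, rg: float = 0.6,
                 kind: str = "degree", uniform: bool = False) -> dict:
    """NetPRS vs plain lasso, individual-level, over repeated seeds.

    Both methods are tuned on the same validation splits; the lasso is
    the lambda1 = 0 column of the same grid, so NetPRS's model space
    nests it. With ``uniform=True`` a third arm runs NetPRS with the
    uninformative annotation s = 1 (the annotation term inert).
    Returns per-seed and mean test R^2 for each arm.
    """
    seeds = spawn_seeds(seed, n_seeds)
    rows = {"netprs": [], "lasso": []}
    if uniform:
        rows["uniform"] = []
    for sd in seeds:
        study = simulate_study(
            n_traits=n_traits, n_samples=n_samples, n_snps=n_snps,
            h2=h2, rg=rg, overlap="partial",
            n_shared=int(round(0.4 * n_samples)), seed=sd)
        s, _names = annotation_weights(study, kind=kind)
        ones = np.ones_like(s)
        rows["netprs"].append(individual_level_r2(study, s, seed=sd))
        rows["lasso"].append(
            individual_level_r2(study, ones, seed=sd, annotated=False))
        if uniform:
            rows["uniform"].append(individual_level_r2(study, ones, seed=sd))
    out = {arm: {"values": vals, "mean": float(np.mean(vals))}
           for arm, vals in rows.items()}
    out["seeds"] = seeds
    return out
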