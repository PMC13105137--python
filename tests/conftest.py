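import numpy as np
import pandas as pd
import pytest

from netprs.ld import LDMatrix, ReferencePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_panel(n=50, m=10, seed=0, missing=0.0):
    """Small random reference panel with optional missingness."""
    r = np.random.default_rng(seed)
    freq = r.uniform(0.1, 0.5, m)
    geno = r.binomial(2, freq, size=(n, m)).astype(float)
    if missing:
        mask = r.random((n, m)) < missing
        geno[mask] = np.nan
    meta = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(m)],
        "chrom": 1,
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A",
        "a2": "G",
    })
    return ReferencePanel(geno, meta)


@pytest.fixture
def small_panel():
    return make_panel()


def random_psd_ld(m, seed, n_blocks=1):
    """Random PSD correlation blocks assembled into an LDMatrix."""
    r = np.random.default_rng(seed)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    blocks, bounds = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        k = b - a
        A = r.standard_normal((k, k + 3))
        C = A @ A.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        blocks.append(C)
        bounds.append((a, b))
    return LDMatrix(blocks=blocks, bounds=bounds)
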