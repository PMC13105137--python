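"""Independent reference computations used to check the package.

Each oracle solves the same mathematical problem as the implementation
through a different route (generic convex solver, dense linear algebra,
exhaustive enumeration) so agreement is evidence, not tautology.
"""

import numpy as np
from scipy.optimize import minimize


def l1_quadratic_oracle(R, bt, tau, tol=1e-12):
    """Minimize 1/2 b'Rb - bt'b + tau'|b| via bound-constrained L-BFGS-B.

    Uses the positive/negative split b = u - v with u, v >= 0, which
    turns the non-smooth problem into a smooth bound-constrained one.
    """
    m = len(bt)

    def fun(x):
        u, v = x[:m], x[m:]
        b = u - v
        g = R @ b - bt
        f = 0.5 * b @ (R @ b) - bt @ b + tau @ (u + v)
        grad = np.concatenate([g + tau, -g + tau])
        return f, grad

    x0 = np.zeros(2 * m)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * m),
                   options={"maxiter": 20000, "ftol": tol, "gtol": 1e-10})
    return res.x[:m] - res.x[m:]


def dense_banded_correlation(x, window):
    """Sample correlation of columns of x, zeroed outside disjoint windows."""
    c = np.corrcoef(x, rowvar=False)
    m = c.shape[1]
    keep = np.zeros_like(c, dtype=bool)
    for a in range(0, m, window):
        b = min(a + window, m)
        keep[a:b, a:b] = True
    return np.where(keep, c, 0.0)


def brute_force_centralities(adjacency, strengths):
    """Degree and betweenness by exhaustive enumeration.

    adjacency: M x K boolean; strengths: M x K signed values.
    Degree sums |strength| over traits. Betweenness enumerates every
    trait pair, lists the SNPs adjacent to both (each a length-2
    shortest path), and splits the pair's unit mass evenly among them.
    """
    m, k = adjacency.shape
    degree = np.array([sum(abs(strengths[i, j]) for j in range(k))
                       for i in range(m)])
    betweenness = np.zeros(m)
    n_connected_pairs = 0
    for a in range(k):
        for b in range(a + 1, k):
            bridges = [i for i in range(m)
                       if adjacency[i, a] and adjacency[i, b]]
            if bridges:
                n_connected_pairs += 1
                for i in bridges:
                    betweenness[i] += 1.0 / len(bridges)
    return degree, betweenness, n_connected_pairs


def ols_line(x, y):
    """Closed-form simple regression: slope, SE (n-2 df), two-sided p."""
    from scipy import stats as sps
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    beta = (xc @ yc) / sxx
    rss = yc @ yc - beta * (xc @ yc)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return beta, se, p
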