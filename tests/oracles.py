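"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package itself: the BH oracle applies the step-up
definition literally; the hypergeometric oracle enumerates draws; the
elastic-net oracle minimizes the penalized objective with a generic
bound-constrained quasi-Newton solver on a positive/negative split of the
coefficients.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import minimize


def bh_stepup_bruteforce(pvalues: np.ndarray) -> np.ndarray:
    """q_i = min over j with p_(j) >= p_i of min(1, m p_(j) / rank(j))."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[order[j]] / (j + 1))
            for j in range(m)
            if p[order[j]] >= p[i] - 1e-15
        ]
        q[i] = min(candidates)
    return q


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws of n from N with K marked."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k)
    return hits / comb(N, n)


def _enet_objective(params, X, y, lam, alpha):
    n = len(y)
    b0 = params[0]
    u, v = params[1 : 1 + X.shape[1]], params[1 + X.shape[1] :]
    beta = u - v
    resid = y - b0 - X @ beta
    l1 = np.sum(u) + np.sum(v)
    return 0.5 / n * resid @ resid + lam * (alpha * l1 + 0.5 * (1 - alpha) * (beta @ beta))


def enet_fit_generic(X, y, lam, alpha):
    """Elastic net by L-BFGS-B on the split beta = u − v, u, v >= 0."""
    p = X.shape[1]
    x0 = np.zeros(2 * p + 1)
    x0[0] = y.mean()
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        _enet_objective, x0, args=(X, y, lam, alpha), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    b0 = res.x[0]
    beta = res.x[1 : 1 + p] - res.x[1 + p :]
    return b0, beta


def enet_cv_grid_oracle(X, y, grid, fold_id):
    """Exhaustive CV-MSE over an (alpha, lambda) grid using the generic solver.

    ``grid`` is an iterable of (alpha, lam); returns the (alpha, lam) with the
    lowest fold-size-weighted CV MSE, ties broken toward larger lambda then
    larger alpha.
    """
    n = len(y)
    records = []
    for alpha, lam in grid:
        total = 0.0
        for k in np.unique(fold_id):
            tr, va = fold_id != k, fold_id == k
            b0, beta = enet_fit_generic(X[tr], y[tr], lam, alpha)
            pred = b0 + X[va] @ beta
            total += np.sum((y[va] - pred) ** 2)
        records.append((alpha, lam, total / n))
    records.sort(key=lambda t: (t[2], -t[1], -t[0]))
    return records[0][0], records[0][1]
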