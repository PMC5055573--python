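"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy's ranking
helpers) so that agreement is a genuine cross-check.
"""

import itertools
import math

import numpy as np


def riemann_add(pairs, elapsed_h: float, dt: float = 0.01) -> float:
    """Midpoint Riemann sum of max(T(t), 0)/24 over [0, elapsed_h].

    Exact for piecewise-constant profiles whose segment boundaries and
    ``elapsed_h`` lie on the ``dt`` grid.
    """
    n = int(round(elapsed_h / dt))
    if n == 0:
        return 0.0
    mids = (np.arange(n) + 0.5) * dt
    bounds = np.cumsum([d for d, _ in pairs])
    temps = np.array([t for _, t in pairs])
    idx = np.searchsorted(bounds, mids, side="left")
    temp_at = temps[np.minimum(idx, len(temps) - 1)]
    return float(np.maximum(temp_at, 0.0).sum() * dt / 24.0)


def brute_ranks(x):
    """Average-tied ranks without scipy."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_spearman(a, b) -> float:
    """Rank-then-Pearson Spearman's rho."""
    ra, rb = brute_ranks(a), brute_ranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(ra @ rb / math.sqrt((ra @ ra) * (rb @ rb)))


def brute_permutation_p(add, y) -> float:
    """Two-sided permutation p-value over every full label permutation."""
    obs = abs(brute_spearman(add, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        hits += abs(brute_spearman(add, perm)) >= obs - 1e-12
    return hits / total
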