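"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — per-pixel loops, O(n^2) scans,
exhaustive enumeration — and shares nothing with the package's code paths
except the documented RNG contract where bit-identical replay is the point.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {
    4: ((-1, 0), (0, -1), (0, 1), (1, 0)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def naive_dilate(labels, rounds, connectivity, seed):
    """Per-pixel stochastic dilation replaying the documented RNG contract:

    per round, border background pixels in row-major order, one uniform per
    border pixel, candidate = mask with the most assigned neighbours (ties
    to the smallest label), p = candidate count / in-bounds neighbour
    count, flip iff u < p, synchronous update.
    """
    rng = np.random.default_rng(seed)
    cur = np.array(labels, dtype=np.int64)
    h, w = cur.shape
    offs = OFFSETS[connectivity]
    for _ in range(rounds):
        border = []
        for r in range(h):
            for c in range(w):
                if cur[r, c] != 0:
                    continue
                touching = False
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and cur[rr, cc] > 0:
                        touching = True
                        break
                if touching:
                    border.append((r, c))
        us = rng.random(len(border))
        nxt = cur.copy()
        for (r, c), u in zip(border, us):
            counts = {}
            total = 0
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    total += 1
                    v = cur[rr, cc]
                    if v > 0:
                        counts[v] = counts.get(v, 0) + 1
            best = max(counts.values())
            candidate = min(lab for lab, n in counts.items() if n == best)
            if u < best / total:
                nxt[r, c] = candidate
        cur = nxt
    return cur


def brute_force_knn(points, k):
    """All-pairs kNN with (distance, index) ordering, one point at a time."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
            cand.append((d, j))
        cand.sort()
        idx[i] = [j for _, j in cand[:k]]
        dist[i] = [d for d, _ in cand[:k]]
    return idx, dist


def brute_force_min_distance(a_points, b_points, same_type=False):
    """Mean over A of the minimum distance to B (self excluded if same)."""
    a = np.asarray(a_points, dtype=float)
    b = np.asarray(b_points, dtype=float)
    minima = []
    for i in range(len(a)):
        best = np.inf
        for j in range(len(b)):
            if same_type and i == j:
                continue
            d = np.sqrt(((a[i] - b[j]) ** 2).sum())
            if d < best:
                best = d
        minima.append(best)
    return float(np.mean(minima))


def welch_t(x, y):
    """Closed-form Welch statistic, Welch-Satterthwaite df and 2-sided p."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's (with a small relative slack against roundoff)."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def bh_stepup(pvalues):
    """Benjamini-Hochberg q-values via the step-up recursion by hand."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


def permutation_t_pvalue(x, y, n_draws, seed):
    """Two-sided permutation p for a difference in means (vectorised draws)."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    nx = len(x)
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        if abs(perm[:nx].mean() - perm[nx:].mean()) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_draws + 1)
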