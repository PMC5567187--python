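"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the textbook definition of each quantity,
deliberately sharing no code with the package.
"""

import math

import numpy as np


def bh_stepup(p):
    """BH adjusted p-values straight from the step-up definition:
    q_(i) = min_{j>=i} m * p_(j) / j, capped at 1, in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_upper_tail_exact(M, K, N, x):
    """P(X >= x) by exact integer enumeration of the hypergeometric pmf."""
    total = math.comb(M, N)
    acc = 0
    for k in range(x, min(K, N) + 1):
        if N - k > M - K:
            continue
        acc += math.comb(K, k) * math.comb(M - K, N - k)
    return acc / total


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins
    and summing probabilities <= the observed table's probability."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)) / math.comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def spearman_rank_pearson(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def davies_bouldin_textbook(X, labels):
    """DB index from the published formula, computed pair by pair."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    cents = {c: X[labels == c].mean(axis=0) for c in clusters}
    scat = {
        c: float(np.mean([np.linalg.norm(row - cents[c]) for row in X[labels == c]]))
        for c in clusters
    }
    ratios = []
    for ci in clusters:
        best = 0.0
        for cj in clusters:
            if ci == cj:
                continue
            d = float(np.linalg.norm(cents[ci] - cents[cj]))
            best = max(best, (scat[ci] + scat[cj]) / d)
        ratios.append(best)
    return float(np.mean(ratios))


def knn_impute_bruteforce(X, k=3):
    """All-pairs-distance KNN imputation, cell by cell.

    Distance between probes p and q: Euclidean over samples observed in
    both, rescaled by sqrt(total/shared). For a missing (p, s): among
    probes observed at s and sharing >=1 sample with p, take the k closest
    and average their values at s; no candidate -> p's own mean.
    """
    X = np.asarray(X, dtype=float).copy()
    orig = X.copy()
    obs = ~np.isnan(orig)
    n, m = X.shape
    for p in range(n):
        for s in range(m):
            if obs[p, s]:
                continue
            dists = []
            for q in range(n):
                if q == p or not obs[q, s]:
                    continue
                both = obs[p] & obs[q]
                if not both.any():
                    continue
                d2 = float(np.sum((orig[p, both] - orig[q, both]) ** 2))
                dists.append((math.sqrt(d2 * m / both.sum()), q))
            if not dists:
                X[p, s] = np.nanmean(orig[p])
                continue
            dists.sort(key=lambda t: t[0])
            neighbors = [q for _, q in dists[:k]]
            X[p, s] = float(np.mean([orig[q, s] for q in neighbors]))
    return X


def pooled_t_by_hand(a, b):
    """Two-sample pooled-variance Student t and df, loop arithmetic."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df
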