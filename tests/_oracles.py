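"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: naive loops, direct
textbook formulas, exhaustive enumeration.
"""

import itertools

import numpy as np


def two_pass_anova_f(x_row, labels):
    """Textbook one-way ANOVA F for a single feature."""
    labels = np.asarray(labels)
    groups = [np.asarray(x_row)[labels == g] for g in dict.fromkeys(labels)]
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def bh_step_up(p):
    """Benjamini-Hochberg adjusted p-values, literal step-up procedure."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def hypergeom_tail(x, big_m, n, big_n):
    """P(X >= x) for Hypergeometric(M, n, N) by direct pmf summation."""
    from math import comb

    total = 0
    for k in range(x, min(n, big_n) + 1):
        total += comb(n, k) * comb(big_m - n, big_n - k)
    return total / comb(big_m, big_n)


def complete_linkage_partitions(points):
    """Brute-force O(n^3) complete-linkage agglomeration.

    Returns the partition (set of frozensets of point indices) after each
    merge, from n singletons down to one cluster.
    """
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]
    partitions = [set(clusters)]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
        partitions.append(set(frozenset(c) for c in clusters))
    return partitions


def triple_intersection(cm, score_map, serum, threshold):
    """Set-algebra candidate oracle on case-folded symbols."""
    cm_k = {g.casefold() for g in cm}
    serum_k = {g.casefold() for g in serum}
    pass_k = {g.casefold() for g, s in score_map.items() if s > threshold}
    return cm_k & pass_k & serum_k
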