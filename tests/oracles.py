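"""Brute-force reference implementations used only to cross-check the package.

These stay deliberately naive and independent of the library code paths they
verify: ranking by explicit tie scanning, the textbook covariance formula for
the rank correlation, and the Lance-Williams recurrence for Ward merges.
"""

import numpy as np


def midranks(x):
    """Average ranks with explicit tie scanning (1-based)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def brute_spearman(a, b):
    """Pearson correlation of midranks via the covariance formula."""
    ra, rb = midranks(a), midranks(b)
    da = ra - ra.mean()
    db = rb - rb.mean()
    denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0.0:
        return np.nan
    return float((da * db).sum() / denom)


def ward_merge_heights(observations):
    """Agglomerative Ward merge heights via the Lance-Williams recurrence.

    Starts from squared Euclidean distances between singletons, repeatedly
    merges the pair with minimal current (squared) inter-cluster distance,
    and updates distances with the Ward coefficients.  Returns the sqrt of
    each merge's squared distance, in merge order (the same scale scipy's
    linkage reports).
    """
    X = np.asarray(observations, dtype=float)
    n = len(X)
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(dij))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for s in active - {i, j}:
            ns = sizes[s]
            dis = d2[tuple(sorted((i, s)))]
            djs = d2[tuple(sorted((j, s)))]
            d2[tuple(sorted((new, s)))] = (
                (ns + ni) * dis + (ns + nj) * djs - ns * dij
            ) / (ns + ni + nj)
        for key in [k for k in d2 if i in k or j in k]:
            del d2[key]
        active -= {i, j}
        active.add(new)
        sizes[new] = ni + nj
    return np.array(heights)
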