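"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library code paths they check: the Ward
oracle agglomerates by exhaustive search over cluster pairs using the
minimum-variance objective directly; the PCA oracle goes through the
sample correlation matrix assembled element by element.
"""

from __future__ import annotations

from math import comb

import numpy as np


def exact_fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    nums = [comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)]
    observed = nums[a - lo]
    return sum(v for v in nums if v <= observed) / comb(r1 + r2, k)


def ward_merge_oracle(X: np.ndarray) -> list[frozenset]:
    """Exhaustive-search minimum-variance agglomeration.

    At each step every cluster pair's increase in within-cluster sum of
    squares, |A||B|/(|A|+|B|) * ||mean(A)-mean(B)||^2, is evaluated and
    the minimum merged (ties: lowest index pair).  Returns the sequence
    of merged pairs as frozensets of leaf-index frozensets.
    """
    X = np.asarray(X, dtype=float)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = np.array(sorted(clusters[i]))
                b = np.array(sorted(clusters[j]))
                ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
                delta = (len(a) * len(b) / (len(a) + len(b))) * float(
                    ((ca - cb) ** 2).sum()
                )
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        _, i, j = best
        merges.append(frozenset([clusters[i], clusters[j]]))
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
    return merges


def correlation_pca_oracle(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and loadings of the sample correlation
    matrix, assembled from pairwise Pearson correlations."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    R = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            R[i, j] = np.corrcoef(X[:, i], X[:, j])[0, 1]
    w, V = np.linalg.eig(R)
    order = np.argsort(w.real)[::-1]
    return w.real[order], V.real[:, order]


def rand_index(labels_a, labels_b) -> float:
    """Pair-counting Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)
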