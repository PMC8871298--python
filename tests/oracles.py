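"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the algorithms and code paths of the package:
DTW is a top-down recursion over alignment paths, the agglomeration oracle
recomputes every inter-cluster dissimilarity from the original matrix
instead of using the Lance-Williams recurrence, ReliefF is a plain-loop
reimplementation, and the score/orthogonal distances come from an explicit
eigendecomposition of the covariance matrix.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def dtw_brute(a, b) -> float:
    """Minimum alignment-path cost by top-down recursion over all paths."""
    a = tuple(float(x) for x in a)
    b = tuple(float(x) for x in b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        candidates = []
        if i > 0:
            candidates.append(best(i - 1, j))
        if j > 0:
            candidates.append(best(i, j - 1))
        if i > 0 and j > 0:
            candidates.append(best(i - 1, j - 1))
        return cost + min(candidates)

    return best(len(a) - 1, len(b) - 1)


def _complete_from_scratch(S: np.ndarray, A: list[int], B: list[int]) -> float:
    return float(max(S[a, b] for a in A for b in B))


def _ward_height_sq_from_scratch(S: np.ndarray, A: list[int], B: list[int]) -> float:
    """Squared Ward merge height from the original distance matrix.

    For Euclidean-embeddable distances the squared distance between cluster
    centroids can be written purely in terms of pairwise squared distances:
    cross-pair mean minus half the within-pair means.  The reported height
    convention makes two singletons merge at their plain distance.
    """
    S2 = S**2
    nA, nB = len(A), len(B)
    cross = float(np.mean([S2[a, b] for a in A for b in B]))
    within_A = float(np.sum([S2[a, a2] for a in A for a2 in A])) / (2 * nA * nA)
    within_B = float(np.sum([S2[b, b2] for b in B for b2 in B])) / (2 * nB * nB)
    centroid_sq = cross - within_A - within_B
    return 2.0 * nA * nB / (nA + nB) * centroid_sq


def naive_agglomeration(S: np.ndarray, method: str):
    """O(n^3) agglomeration recomputing dissimilarities from scratch.

    Returns (heights, merged_sets): the height of each merge and the frozenset
    of original items in the cluster formed at that step.  Slots mirror the
    convention that a merged cluster occupies the lower of its two slot
    positions, so tie-breaking is by lowest (slot_i, slot_j) pair.
    """
    n = S.shape[0]
    slots: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    merged_sets = []
    for _ in range(n - 1):
        best = None
        positions = sorted(slots)
        for ai, i in enumerate(positions):
            for j in positions[ai + 1:]:
                if method == "complete":
                    d = _complete_from_scratch(S, slots[i], slots[j])
                else:
                    d = np.sqrt(max(_ward_height_sq_from_scratch(S, slots[i], slots[j]), 0.0))
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        slots[i] = slots[i] + slots[j]
        del slots[j]
        merged_sets.append(frozenset(slots[i]))
    return np.array(heights), merged_sets


def merge_sets_from_Z(Z: np.ndarray) -> list[frozenset]:
    """Original-item member sets of the cluster formed at each merge step."""
    n = Z.shape[0] + 1
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step in range(n - 1):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        merged = members[a] | members[b]
        members[n + step] = merged
        out.append(merged)
    return out


def relieff_brute(X: np.ndarray, y: np.ndarray, kinds, k: int) -> np.ndarray:
    """Plain-loop ReliefF over all instances (reference for small inputs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    ranges = X.max(axis=0) - X.min(axis=0)

    def diff(f: int, a: int, b: int) -> float:
        if kinds[f] == "nominal":
            return float(X[a, f] != X[b, f])
        if ranges[f] == 0:
            return 0.0
        return abs(X[a, f] - X[b, f]) / ranges[f]

    def dist(a: int, b: int) -> float:
        return sum(diff(f, a, b) for f in range(p))

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    k_eff = min(k, int(counts.min()) - 1)
    W = np.zeros(p)
    for i in range(n):
        for c in classes:
            idx = [j for j in range(n) if y[j] == c and j != i]
            idx.sort(key=lambda j: (dist(i, j), j))
            near = idx[:k_eff]
            for f in range(p):
                s = sum(diff(f, i, j) for j in near)
                if c == y[i]:
                    W[f] -= s
                else:
                    W[f] += priors[c] / (1.0 - priors[y[i]]) * s
    return W / (n * k_eff)


def sd_od_eigen(X: np.ndarray, var_explained: float = 0.95):
    """Score and orthogonal distances via explicit covariance eigendecomposition."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    cum = np.cumsum(eigvals) / eigvals.sum()
    q = int(np.searchsorted(cum, var_explained) + 1)
    q = max(1, min(q, n - 1, int(np.sum(eigvals > 1e-12 * eigvals[0]))))
    scores = Xc @ eigvecs[:, :q]
    sd = np.sqrt(np.sum(scores**2 / eigvals[:q], axis=1))
    od = np.linalg.norm(Xc - scores @ eigvecs[:, :q].T, axis=1)
    return sd, od
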