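"""Filter feature selection: Information Gain, symmetrical uncertainty, ReliefF.

All three filters score a feature column against the binary class label;
selection keeps either the ``top_m`` highest-scoring columns (default
m = 26, one informative column per sensor as a neutral budget) or every
column with a strictly positive score.  Numeric columns are discretized for
the entropy-based filters with 10-bin equal-frequency binning whose edges
are always fitted on training data.

ReliefF runs over all instances (no subsampling) for determinism, with
k = 10 nearest hits/misses under the standard range-scaled Manhattan diff
metric (nominal features contribute 0/1 diffs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .common_features import FeatureTable

METHODS = ("infogain", "relieff", "symm_unc")


@dataclass
class FeatureScore:
    feature_id: str
    method: str
    score: float


def _entropy(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(feature: Sequence, labels: Sequence) -> float:
    """Reduction in class entropy given the (nominal) feature, in bits."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain at least 2 classes")
    h_class = _entropy(labels)
    n = labels.size
    h_cond = 0.0
    for v in np.unique(feature):
        mask = feature == v
        h_cond += (mask.sum() / n) * _entropy(labels[mask])
    return h_class - h_cond


def symmetrical_uncertainty(feature: Sequence, labels: Sequence) -> float:
    """2·IG / (H(feature) + H(class)); 0 when both entropies vanish."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    ig = info_gain(feature, labels)
    denom = _entropy(feature) + _entropy(labels)
    if denom == 0:
        return 0.0
    return 2.0 * ig / denom


def fit_equal_frequency_bins(
    column: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Interior bin edges at training-data quantiles (duplicates collapsed)."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(column, qs))
    return edges


def discretize(column: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, column, side="left")


def relieff(
    features: np.ndarray,
    labels: Sequence,
    kinds: Sequence[str] | None = None,
    k_neighbors: int = 10,
    sample_size: int | None = None,
) -> np.ndarray:
    """Standard ReliefF weights for a mixed nominal/numeric feature matrix.

    For every instance, the diffs to its k nearest same-class neighbours
    (near hits) are subtracted and the class-prior-weighted diffs to the
    k nearest neighbours of each other class (near misses) are added, all
    averaged over n·k.  Numeric diffs are |a−b| scaled by the feature range;
    nominal diffs are 0/1.  ``sample_size=None`` iterates over every
    instance, which makes the weights deterministic.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    y = np.asarray(labels)
    n, p = X.shape
    if y.size != n:
        raise ValueError("labels length mismatch")
    kinds = list(kinds) if kinds is not None else ["numeric"] * p
    classes, class_counts = np.unique(y, return_counts=True)
    if np.any(class_counts < 2):
        raise ValueError("every class needs at least 2 members")
    k = min(k_neighbors, int(class_counts.min()) - 1)
    priors = {c: cnt / n for c, cnt in zip(classes, class_counts)}

    # per-feature diff matrices collapse to range-scaled |a-b|; nominal 0/1
    ranges = X.max(axis=0) - X.min(axis=0)
    scale = np.where(ranges > 0, ranges, 1.0)

    def diffs(a: np.ndarray, B: np.ndarray) -> np.ndarray:
        d = np.abs(B - a) / scale
        for j, kind in enumerate(kinds):
            if kind == "nominal":
                d[:, j] = (B[:, j] != a[j]).astype(float)
        return d

    order = np.arange(n) if sample_size is None else np.arange(min(sample_size, n))
    W = np.zeros(p)
    for i in order:
        d_all = diffs(X[i], X)
        dist = d_all.sum(axis=1)
        for c in classes:
            mask = y == c
            idx = np.flatnonzero(mask)
            idx = idx[idx != i]
            # stable sort: equidistant neighbours resolve by index
            near = idx[np.argsort(dist[idx], kind="stable")[:k]]
            contribution = d_all[near].sum(axis=0)
            if c == y[i]:
                W -= contribution
            else:
                W += (priors[c] / (1.0 - priors[y[i]])) * contribution
    return W / (len(order) * k)


def score_features(
    table: FeatureTable,
    method: str,
    k_neighbors: int = 10,
    n_bins: int = 10,
) -> list[FeatureScore]:
    """Score every column of a feature table on its (training) labels."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = table.labels.to_numpy()
    if method == "relieff":
        kinds = [table.kind] * len(table.feature_ids)
        weights = relieff(
            table.df.to_numpy(dtype=float), y, kinds=kinds, k_neighbors=k_neighbors
        )
        return [
            FeatureScore(fid, method, float(w))
            for fid, w in zip(table.feature_ids, weights)
        ]
    scorer = info_gain if method == "infogain" else symmetrical_uncertainty
    out = []
    for fid in table.feature_ids:
        col = table.df[fid].to_numpy()
        if table.kind == "numeric":
            edges = fit_equal_frequency_bins(col.astype(float), n_bins=n_bins)
            col = discretize(col.astype(float), edges)
        out.append(FeatureScore(fid, method, float(scorer(col, y))))
    return out


def select_features(
    scores: Sequence[FeatureScore],
    policy: str = "top_m",
    m: int = 26,
) -> list[str]:
    """Deterministic selection: ``top_m`` highest scores or all positive ones.

    Ties break lexicographically by feature_id.
    """
    if not scores:
        raise ValueError("no scores")
    ordered = sorted(scores, key=lambda s: (-s.score, s.feature_id))
    if policy == "top_m":
        selected = [s.feature_id for s in ordered[:m]]
    elif policy == "positive":
        if any(s.method == "relieff" for s in scores):
            raise ValueError("policy 'positive' applies to infogain/symm_unc only")
        selected = [s.feature_id for s in ordered if s.score > 0]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if not selected:
        raise ValueError("no informative features")
    return selected


def scores_frame(scores: Sequence[FeatureScore], selected: Sequence[str]) -> pd.DataFrame:
    sel = set(selected)
    return pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "method": s.method,
                "score": s.score,
                "selected": s.feature_id in sel,
            }
            for s in scores
        ]
    )
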