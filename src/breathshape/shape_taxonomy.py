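"""Cluster taxonomies of sensor response curve shapes.

Instead of reducing a response curve to scalar summaries, the curve *shape*
itself becomes the feature: per sensor, all training curves are clustered
hierarchically (agglomerative, Euclidean or dynamic-time-warping
dissimilarity, complete or Ward linkage) and the dendrogram is cut at every
k from 2 to 10.  Each cut yields a partition whose clusters are represented
by *characteristic curves* — the pointwise means of their members — and a
measurement's cluster membership at each cut becomes one nominal attribute
for classification.  Unseen curves are assigned to the nearest
characteristic curve under the taxonomy's own distance.

Conventions (fixed for determinism):

* DTW uses steps {(1,0),(0,1),(1,1)}, local cost |a−b|, unnormalized path
  sum, optional Sakoe–Chiba band, no slope weighting.
* Ward linkage runs the Lance–Williams recurrence on *squared* input
  dissimilarities and reports square-root heights (so that for two singleton
  points the merge height equals their distance).  Applying this to DTW
  dissimilarities is the standard heuristic in time-series clustering even
  though Ward's variance interpretation presumes Euclidean geometry.
* All ties break toward the lowest index (lowest (row, column) pair for
  merges, lowest cluster index for assignments).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import CurvePanel

DISTANCES = ("euclidean", "dtwarp")
LINKAGES = ("complete", "ward")
DEFAULT_K_RANGE = tuple(range(2, 11))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def euclidean_distance(ts1: Sequence[float], ts2: Sequence[float]) -> float:
    """Pointwise L2 distance between two equal-length series."""
    a = np.asarray(ts1, dtype=float)
    b = np.asarray(ts2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def dtw_distance(
    ts1: Sequence[float], ts2: Sequence[float], band: int | None = None
) -> float:
    """Dynamic-time-warping dissimilarity.

    Minimum over monotone alignment paths of the summed local costs |a−b|,
    with steps (1,0), (0,1) and (1,1).  ``band`` restricts alignment to a
    Sakoe–Chiba window |i−j| ≤ band.
    """
    a = np.asarray(ts1, dtype=float)
    b = np.asarray(ts2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sequence")
    n, m = a.size, b.size
    if band is not None:
        if band < abs(n - m):
            raise ValueError(f"band {band} cannot align lengths {n} and {m}")
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[:] = np.inf
        lo, hi = 1, m
        if band is not None:
            lo = max(1, i - band)
            hi = min(m, i + band)
        for j in range(lo, hi + 1):
            cost = abs(a[i - 1] - b[j - 1])
            cur[j] = cost + min(prev[j], cur[j - 1], prev[j - 1])
        prev, cur = cur, prev
    return float(prev[m])


def pairwise_distances(
    curves: np.ndarray, distance: str, band: int | None = None
) -> np.ndarray:
    """Condensed pairwise dissimilarity vector over the rows of ``curves``."""
    if distance == "euclidean":
        return pdist(curves, metric="euclidean")
    if distance == "dtwarp":
        n = curves.shape[0]
        out = np.empty(n * (n - 1) // 2)
        idx = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                out[idx] = dtw_distance(curves[i], curves[j], band=band)
                idx += 1
        return out
    raise ValueError(f"unknown distance {distance!r}")


# ---------------------------------------------------------------------------
# agglomerative linkage
# ---------------------------------------------------------------------------

def linkage_cluster(D: np.ndarray, linkage: str) -> np.ndarray:
    """Agglomerative clustering of a pairwise dissimilarity matrix.

    ``D`` may be condensed (1-D, scipy convention) or square symmetric with a
    zero diagonal.  Returns a scipy-style merge table Z of shape (n−1, 4):
    each row [id_a, id_b, height, size] merges two clusters (original items
    are 0..n−1, the cluster formed at step t gets id n+t).

    Complete linkage tracks the maximum inter-cluster dissimilarity; Ward
    applies the Lance–Williams recurrence to squared dissimilarities and
    reports square-root heights.  When several pairs attain the minimal
    dissimilarity, the pair with the lowest (row, column) index merges first.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        S = squareform(D, checks=False)
    elif D.ndim == 2:
        if D.shape[0] != D.shape[1]:
            raise ValueError("square distance matrix must be n x n")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        S = D.copy()
        np.fill_diagonal(S, 0.0)
    else:
        raise ValueError("D must be 1-D condensed or 2-D square")
    if np.any(S < 0):
        raise ValueError("distances must be non-negative")
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items")

    ward = linkage == "ward"
    W = S**2 if ward else S            # working dissimilarities
    np.fill_diagonal(W, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=int)
    cluster_id = np.arange(n)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        # row-major argmin over the upper triangle gives the lowest-index pair
        masked = np.where(
            active[:, None] & active[None, :] & np.triu(np.ones_like(W, bool), 1),
            W,
            np.inf,
        )
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        d = masked[i, j]
        height = float(np.sqrt(d)) if ward else float(d)
        Z[step] = [cluster_id[i], cluster_id[j], height, sizes[i] + sizes[j]]

        others = np.flatnonzero(active & (np.arange(n) != i) & (np.arange(n) != j))
        if ward:
            ni, nj, nk = sizes[i], sizes[j], sizes[others]
            tot = ni + nj + nk
            new = ((ni + nk) * W[i, others] + (nj + nk) * W[j, others] - nk * d) / tot
        else:
            new = np.maximum(W[i, others], W[j, others])
        W[i, others] = new
        W[others, i] = new
        active[j] = False
        sizes[i] += sizes[j]
        cluster_id[i] = n + step
    return Z


def cut_dendrogram(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    """Labels 1..k from cutting the merge table at ``n_clusters`` clusters.

    Cluster indices are assigned by order of first appearance over the item
    rows, so the labelling is deterministic.
    """
    n = Z.shape[0] + 1
    if not 1 <= n_clusters <= n:
        raise ValueError(f"cannot cut {n} items into {n_clusters} clusters")
    parent = np.arange(n + Z.shape[0], dtype=int)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - n_clusters):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        root = n + step
        parent[find(a)] = root
        parent[find(b)] = root
    roots = np.array([find(i) for i in range(n)])
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass
class ClusterLevel:
    """One horizontal dendrogram cut: assignments plus characteristic curves."""

    k: int
    assignment: dict[str, int]            # measurement_id -> cluster index 1..k
    characteristic_curves: np.ndarray     # k x T pointwise means

    def __post_init__(self) -> None:
        self.characteristic_curves = np.asarray(self.characteristic_curves, dtype=float)
        if self.characteristic_curves.shape[0] != self.k:
            raise ValueError("characteristic_curves row count must equal k")
        if set(self.assignment.values()) != set(range(1, self.k + 1)):
            raise ValueError("assignment must use every cluster index 1..k")


@dataclass
class ShapeTaxonomy:
    """Per-sensor nested family of shape partitions from one dendrogram."""

    sensor_id: str
    distance: str
    linkage: str
    merge_tree: np.ndarray                # scipy-style Z
    levels: dict[int, ClusterLevel] = field(default_factory=dict)
    band: int | None = None

    @property
    def T(self) -> int:
        ks = sorted(self.levels)
        return self.levels[ks[0]].characteristic_curves.shape[1]

    def to_dict(self) -> dict:
        return {
            "sensor_id": self.sensor_id,
            "distance": self.distance,
            "linkage": self.linkage,
            "band": self.band,
            "merge_tree": self.merge_tree.tolist(),
            "levels": {
                str(k): {
                    "assignment": lvl.assignment,
                    "characteristic_curves": lvl.characteristic_curves.tolist(),
                }
                for k, lvl in self.levels.items()
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeTaxonomy":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        levels = {
            int(k): ClusterLevel(
                k=int(k),
                assignment={m: int(c) for m, c in v["assignment"].items()},
                characteristic_curves=np.array(v["characteristic_curves"]),
            )
            for k, v in doc["levels"].items()
        }
        return cls(
            sensor_id=doc["sensor_id"],
            distance=doc["distance"],
            linkage=doc["linkage"],
            merge_tree=np.array(doc["merge_tree"]),
            levels=levels,
            band=doc.get("band"),
        )


def build_taxonomy(
    panel: CurvePanel,
    distance: str = "euclidean",
    linkage: str = "ward",
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    band: int | None = None,
    condensed: np.ndarray | None = None,
) -> ShapeTaxonomy:
    """Cluster one sensor's curves and cut the dendrogram at each k.

    ``condensed`` may supply precomputed pairwise dissimilarities for the
    panel rows (in scipy condensed order) to avoid recomputation across
    repeated evaluation runs; it must match ``distance``.
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2 or above")
    X = panel.curve_matrix
    n = X.shape[0]
    if condensed is None:
        condensed = pairwise_distances(X, distance, band=band)
    if np.all(condensed < 1e-12) and condensed.size:
        warnings.warn(
            f"sensor {panel.sensor_id!r}: all curves identical, degenerate merges",
            stacklevel=2,
        )
    Z = linkage_cluster(condensed, linkage)
    levels: dict[int, ClusterLevel] = {}
    for k in k_range:
        if k > n:
            warnings.warn(
                f"sensor {panel.sensor_id!r}: only {n} curves, omitting k={k}",
                stacklevel=2,
            )
            continue
        labels = cut_dendrogram(Z, k)
        curves = np.vstack([X[labels == c].mean(axis=0) for c in range(1, k + 1)])
        levels[k] = ClusterLevel(
            k=k,
            assignment={m: int(c) for m, c in zip(panel.measurement_ids, labels)},
            characteristic_curves=curves,
        )
    return ShapeTaxonomy(
        sensor_id=panel.sensor_id,
        distance=distance,
        linkage=linkage,
        merge_tree=Z,
        levels=levels,
        band=band,
    )


def assign_membership(
    curve: Sequence[float], level: ClusterLevel, distance: str, band: int | None = None
) -> int:
    """Index (1-based) of the nearest characteristic curve; ties go low."""
    curve = np.asarray(curve, dtype=float)
    if curve.size != level.characteristic_curves.shape[1]:
        raise ValueError("curve length does not match characteristic curves")
    if distance == "euclidean":
        d = np.sqrt(np.sum((level.characteristic_curves - curve) ** 2, axis=1))
    elif distance == "dtwarp":
        d = np.array(
            [dtw_distance(curve, c, band=band) for c in level.characteristic_curves]
        )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return int(np.argmin(d)) + 1


def check_nesting(taxonomy: ShapeTaxonomy) -> bool:
    """The k-cut must merge exactly two clusters of the (k+1)-cut."""
    ks = sorted(taxonomy.levels)
    for k, k1 in zip(ks, ks[1:]):
        if k1 != k + 1:
            continue
        coarse = taxonomy.levels[k].assignment
        fine = taxonomy.levels[k1].assignment
        mapping: dict[int, set[int]] = {}
        for m, c in coarse.items():
            mapping.setdefault(c, set()).add(fine[m])
        sizes = sorted(len(v) for v in mapping.values())
        if sizes != [1] * (k - 1) + [2]:
            return False
    return True


def membership_feature_table(
    taxonomies: Mapping[str, ShapeTaxonomy],
    panels: Mapping[str, CurvePanel],
    labels: Mapping[str, str],
):
    """One nominal column per (sensor, k): 26 sensors × k=2..10 → 234 columns.

    Rows present in a taxonomy's training assignment keep their stored
    cluster index; other rows (test measurements) are assigned to the nearest
    characteristic curve under the taxonomy's own distance.
    """
    import pandas as pd

    from .common_features import FeatureTable, check_row_alignment

    ids = check_row_alignment(panels)
    missing = [m for m in ids if m not in labels]
    if missing:
        raise ValueError(f"label missing for measurement {missing[0]!r}")
    columns: dict[str, np.ndarray] = {}
    for sid in sorted(panels):
        if sid not in taxonomies:
            raise ValueError(f"missing taxonomy for sensor {sid!r}")
        tax = taxonomies[sid]
        panel = panels[sid]
        for k in sorted(tax.levels):
            level = tax.levels[k]
            values = np.empty(len(ids), dtype=int)
            for i, m in enumerate(ids):
                if m in level.assignment:
                    values[i] = level.assignment[m]
                else:
                    values[i] = assign_membership(
                        panel.curve_matrix[i], level, tax.distance, band=tax.band
                    )
            columns[f"{sid}_k{k}"] = values
    df = pd.DataFrame(columns, index=pd.Index(ids, name="measurement_id"))
    label_series = pd.Series({m: labels[m] for m in ids}, name="label").loc[ids]
    return FeatureTable(df=df, labels=label_series, kind="nominal")
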