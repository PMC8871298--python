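"""Scalar summary features of response curves — the comparison baseline.

Five descriptors per sensor curve: minimum, maximum, average, trapezoidal
area under the curve, and the mean of the end (stable) part of the
measurement.  These are the features conventionally used for chemiresistive
sensor arrays; the shape-taxonomy features exist to capture what they throw
away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import CurvePanel

COMMON_FEATURES = ("min", "max", "mean", "auc", "end_mean")


@dataclass
class FeatureTable:
    """Measurements × features with class labels.

    ``kind`` distinguishes numeric summary columns from nominal cluster
    membership columns, which downstream selectors and classifiers treat
    differently.
    """

    df: pd.DataFrame              # index: measurement_id
    labels: pd.Series             # aligned to df.index
    kind: str                     # "numeric" | "nominal"

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "nominal"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.df.index.equals(self.labels.index):
            raise ValueError("labels index does not match feature rows")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.columns)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.df.loc[list(ids)], self.labels.loc[list(ids)], self.kind)

    def subset_columns(self, columns: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.df[list(columns)], self.labels, self.kind)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="measurement_id")


def extract_common(
    curve: Sequence[float], end_window: int = 10
) -> tuple[float, float, float, float, float]:
    """(min, max, mean, auc, end_mean) of one curve.

    AUC is the trapezoidal integral at unit spacing; end_mean averages the
    last ``end_window`` points (the stable part of the response).
    """
    curve = np.asarray(curve, dtype=float)
    T = curve.size
    if not 1 <= end_window <= T:
        raise ValueError(f"end_window={end_window} out of range for T={T}")
    return (
        float(curve.min()),
        float(curve.max()),
        float(curve.mean()),
        float(np.trapezoid(curve)),
        float(curve[-end_window:].mean()),
    )


def check_row_alignment(panels: Mapping[str, CurvePanel]) -> list[str]:
    """All panels must list identical measurement_ids in identical order."""
    if not panels:
        raise ValueError("no panels")
    sensor_ids = sorted(panels)
    reference = panels[sensor_ids[0]].measurement_ids
    for sid in sensor_ids[1:]:
        if panels[sid].measurement_ids != reference:
            raise ValueError(f"panel {sid!r} rows are not aligned with {sensor_ids[0]!r}")
    return list(reference)


def common_feature_table(
    panels: Mapping[str, CurvePanel],
    labels: Mapping[str, str],
    end_window: int = 10,
) -> FeatureTable:
    """One numeric column per (sensor, feature): e.g. 26 sensors → 130 columns."""
    ids = check_row_alignment(panels)
    missing = [m for m in ids if m not in labels]
    if missing:
        raise ValueError(f"label missing for measurement {missing[0]!r}")
    columns: dict[str, np.ndarray] = {}
    for sid in sorted(panels):
        panel = panels[sid]
        values = np.array(
            [extract_common(row, end_window=end_window) for row in panel.curve_matrix]
        )
        for j, feat in enumerate(COMMON_FEATURES):
            columns[f"{sid}_{feat}"] = values[:, j]
    df = pd.DataFrame(columns, index=pd.Index(ids, name="measurement_id"))
    label_series = pd.Series({m: labels[m] for m in ids}, name="label").loc[ids]
    return FeatureTable(df=df, labels=label_series, kind="numeric")
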