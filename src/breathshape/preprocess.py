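"""Preprocessing of raw sensor traces into analysis-ready curve panels.

The pipeline order is fixed: equalize lengths → normalize against the
stabilized baseline tail → median-filter, then flag whole measurements as
outliers from the concatenation of all per-sensor panels.

Normalization divides the breath series by the mean of the last ``b_tail``
room-air baseline points (the stabilized sensor response to ambient air), the
standard R/R0 treatment for chemiresistive sensors; a difference mode
(breath − reference) is available as a config switch.

Outlier detection projects measurements onto principal components and flags
by two complementary statistics: the *score distance* (Mahalanobis distance
inside the retained component subspace) and the *orthogonal distance* (norm
of the residual outside it).  Cutoffs come from scaled chi-squared fits with
moment-matched degrees of freedom to each distance sample.  Because roughly
alpha·n clean measurements would exceed a plain 1−alpha quantile by chance,
the outlier cutoff is multiplicity-corrected — the per-measurement quantile
is (1−alpha)^(1/n), so alpha bounds the probability that *any* clean
measurement is flagged.  Distances several times the sample median are
excluded from the moment fit so that gross outliers do not inflate their
own cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .measurement_io import Cohort

STAGE_ORDER = ("equalize", "normalize", "median_filter")


@dataclass
class PreprocessConfig:
    trim: str = "head"                 # head | symmetric
    normalize: str = "ratio"           # ratio | difference
    b_tail: int = 10                   # baseline tail points for the reference
    median_window: int = 3             # odd; 1 disables
    min_length: int = 10               # shortest acceptable breath series
    outlier_alpha: float = 0.01        # tail probability per distance statistic
    var_explained: float = 0.95        # retained PCA variance fraction
    epsilon: float = 1e-9              # degenerate-baseline guard
    stages: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        if self.trim not in ("head", "symmetric"):
            raise ValueError(f"unknown trim mode {self.trim!r}")
        if self.normalize not in ("ratio", "difference"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if tuple(self.stages) != STAGE_ORDER:
            raise ValueError("invalid stage order")
        if not 0 < self.outlier_alpha < 0.5:
            raise ValueError("outlier_alpha must be in (0, 0.5)")
        if not 0 < self.var_explained <= 1:
            raise ValueError("var_explained must be in (0, 1]")


@dataclass
class CurvePanel:
    """Equal-length normalized curves of one sensor across measurements."""

    sensor_id: str
    curve_matrix: np.ndarray           # measurements x T
    measurement_ids: list[str]

    def __post_init__(self) -> None:
        self.curve_matrix = np.asarray(self.curve_matrix, dtype=float)
        if self.curve_matrix.ndim != 2:
            raise ValueError("curve_matrix must be 2-D")
        if self.curve_matrix.shape[0] != len(self.measurement_ids):
            raise ValueError("row count does not match measurement_ids")
        if not np.all(np.isfinite(self.curve_matrix)):
            raise ValueError("curve_matrix contains non-finite values")

    @property
    def T(self) -> int:
        return self.curve_matrix.shape[1]

    def subset(self, ids: Sequence[str]) -> "CurvePanel":
        index = {m: i for i, m in enumerate(self.measurement_ids)}
        rows = [index[m] for m in ids]
        return CurvePanel(self.sensor_id, self.curve_matrix[rows], list(ids))


@dataclass
class OutlierReport:
    measurement_id: str
    score_distance: float
    orthogonal_distance: float
    sd_cutoff: float
    od_cutoff: float
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.flagged = (
            self.score_distance > self.sd_cutoff
            or self.orthogonal_distance > self.od_cutoff
        )


def equalize_lengths(
    traces: Sequence[Sequence[float]],
    trim: str = "head",
    min_length: int = 10,
) -> list[np.ndarray]:
    """Trim all series to the common minimum length T.

    The stabilized end of the response curve carries the signal used
    downstream, so extra points are removed from the *start* by default
    (``trim="head"``); ``trim="symmetric"`` splits the excess between both
    ends.
    """
    arrays = [np.asarray(t, dtype=float) for t in traces]
    if not arrays:
        raise ValueError("no traces to equalize")
    lengths = [a.size for a in arrays]
    if min(lengths) < min_length:
        raise ValueError(
            f"series of length {min(lengths)} is shorter than minimum {min_length}"
        )
    T = min(lengths)
    out = []
    for a in arrays:
        extra = a.size - T
        if extra == 0:
            out.append(a)
        elif trim == "head":
            out.append(a[extra:])
        else:
            front = extra // 2
            out.append(a[front : front + T])
    return out


def normalize_to_baseline(
    breath: Sequence[float],
    baseline: Sequence[float],
    b_tail: int = 10,
    mode: str = "ratio",
    epsilon: float = 1e-9,
) -> np.ndarray:
    """Normalize a breath series against the stabilized baseline tail.

    The reference r is the mean of the last ``b_tail`` room-air values; the
    output is ``breath / r`` (ratio mode) or ``breath − r`` (difference mode).
    """
    breath = np.asarray(breath, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size < b_tail:
        raise ValueError(
            f"baseline has {baseline.size} points, fewer than b_tail={b_tail}"
        )
    r = float(np.mean(baseline[-b_tail:]))
    if mode == "ratio":
        if abs(r) <= epsilon:
            raise ValueError("degenerate baseline")
        return breath / r
    if mode == "difference":
        return breath - r
    raise ValueError(f"unknown normalize mode {mode!r}")


def median_filter(x: Sequence[float], window: int) -> np.ndarray:
    """Running median with replicate (edge-value) padding; window=1 is identity."""
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > x.size:
        raise ValueError("window exceeds series length")
    if window == 1:
        return x.copy()
    return ndimage.median_filter(x, size=window, mode="nearest")


def _chi2_cutoff(sample: np.ndarray, alpha: float) -> float:
    """1−alpha quantile of a scaled chi-squared moment-matched to the sample."""
    m = float(np.mean(sample))
    v = float(np.var(sample, ddof=1)) if sample.size > 1 else 0.0
    if v <= 0 or m <= 0:
        # degenerate sample: nothing exceeds its own constant value
        return m
    dof = 2.0 * m * m / v
    scale = v / (2.0 * m)
    return scale * float(stats.chi2.ppf(1.0 - alpha, dof))


def detect_outliers(
    rows: np.ndarray,
    alpha: float = 0.01,
    var_explained: float = 0.95,
    measurement_ids: Sequence[str] | None = None,
) -> list[OutlierReport]:
    """Flag outlying measurements by PCA score and orthogonal distances.

    Columns are mean-centered, principal components retaining at least
    ``var_explained`` of the variance (capped at rows−1) define the score
    space.  For each row, SD is the Mahalanobis distance of its scores and OD
    the Euclidean norm of its residual.  Each distance sample gets a scaled
    chi-squared cutoff with moment-matched degrees of freedom at the
    multiplicity-corrected quantile (1−alpha)^(1/n); distances beyond several
    times the sample median are excluded from the moment fit so that gross
    outliers do not mask themselves.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a 2-D matrix with at least 10 rows")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    n = X.shape[0]
    ids = list(measurement_ids) if measurement_ids is not None else [
        str(i) for i in range(n)
    ]
    if len(ids) != n:
        raise ValueError("measurement_ids length mismatch")

    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = float(eigvals.sum())
    if total <= 0:
        raise ValueError("no variation")
    cum = np.cumsum(eigvals) / total
    q = int(np.searchsorted(cum, var_explained) + 1)
    q = min(q, n - 1, int(np.sum(eigvals > 1e-12 * eigvals[0])))
    q = max(q, 1)

    scores = Xc @ Vt[:q].T                       # n x q
    sd = np.sqrt(np.sum(scores**2 / eigvals[:q], axis=1))
    residual = Xc - scores @ Vt[:q]
    od = np.linalg.norm(residual, axis=1)
    od = np.where(od < 1e-12 * max(1.0, float(s[0])), 0.0, od)

    # Gross-error prescreen for the moment fit only: distances several times
    # the sample median cannot come from the bulk and would inflate (mask)
    # their own cutoffs, while genuine cohort structure stays within a small
    # multiple of the median and is retained in the estimation sample.
    gross_factor = 5.0
    sd_keep = sd <= gross_factor * max(float(np.median(sd)), 1e-300)
    od_keep = od <= gross_factor * max(float(np.median(od)), 1e-300)
    if sd_keep.sum() < 3:
        sd_keep = np.ones(n, dtype=bool)
    if od_keep.sum() < 3:
        od_keep = np.ones(n, dtype=bool)
    # Cutoffs at the multiplicity-corrected quantile, so alpha bounds the
    # probability that *any* clean measurement is flagged ("extremes" beyond
    # the plain 1-alpha quantile are expected in clean data at a rate of
    # alpha*n and are not outliers by themselves).
    alpha_point = 1.0 - (1.0 - alpha) ** (1.0 / n)
    sd_cut = _chi2_cutoff(sd[sd_keep], alpha_point)
    od_cut = _chi2_cutoff(od[od_keep], alpha_point) if np.any(od[od_keep] > 0) else float(
        np.max(od[od_keep])
    )

    return [
        OutlierReport(
            measurement_id=ids[i],
            score_distance=float(sd[i]),
            orthogonal_distance=float(od[i]),
            sd_cutoff=float(sd_cut),
            od_cutoff=float(od_cut),
        )
        for i in range(n)
    ]


def preprocess_cohort(
    cohort: Cohort,
    config: PreprocessConfig | None = None,
) -> tuple[dict[str, CurvePanel], list[OutlierReport]]:
    """Run the full preprocessing chain on a screened cohort.

    Per sensor: equalize breath lengths across measurements, normalize each
    series against its own baseline tail, median-filter.  Outlier detection
    runs once on the horizontal concatenation of all sensor panels, and
    flagged measurements are removed from every panel so the panels stay
    row-aligned.
    """
    config = config or PreprocessConfig()
    kept = cohort.kept()
    if not kept:
        raise ValueError("cohort has no kept measurements")
    sensor_ids = sorted(kept[0].sensors)
    for m in kept:
        if sorted(m.sensors) != sensor_ids:
            raise ValueError(
                f"measurement {m.measurement_id!r} has a different sensor set; "
                "screen the cohort first"
            )
    ids = [m.measurement_id for m in kept]

    panels: dict[str, CurvePanel] = {}
    for sid in sensor_ids:
        breaths = [m.sensors[sid].breath_values for m in kept]
        equalized = equalize_lengths(breaths, trim=config.trim, min_length=config.min_length)
        curves = []
        for m, series in zip(kept, equalized):
            normalized = normalize_to_baseline(
                series,
                m.sensors[sid].baseline_values,
                b_tail=config.b_tail,
                mode=config.normalize,
                epsilon=config.epsilon,
            )
            curves.append(median_filter(normalized, config.median_window))
        panels[sid] = CurvePanel(sid, np.vstack(curves), list(ids))

    concatenated = np.hstack([panels[sid].curve_matrix for sid in sensor_ids])
    reports = detect_outliers(
        concatenated,
        alpha=config.outlier_alpha,
        var_explained=config.var_explained,
        measurement_ids=ids,
    )
    flagged = {r.measurement_id for r in reports if r.flagged}
    if flagged:
        warnings.warn(
            f"removed {len(flagged)} outlier measurement(s): {sorted(flagged)}",
            stacklevel=2,
        )
        keep_ids = [m for m in ids if m not in flagged]
        panels = {sid: p.subset(keep_ids) for sid, p in panels.items()}
    return panels, reports


def outlier_report_frame(reports: Sequence[OutlierReport]):
    """OutlierReports as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "measurement_id": r.measurement_id,
                "score_distance": r.score_distance,
                "orthogonal_distance": r.orthogonal_distance,
                "sd_cutoff": r.sd_cutoff,
                "od_cutoff": r.od_cutoff,
                "flagged": r.flagged,
            }
            for r in reports
        ]
    )
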