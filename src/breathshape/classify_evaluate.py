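"""Classifier training, repeated-holdout evaluation, and configuration comparison.

Each evaluation run draws one stratified random 70/30 train/test split and is
leakage-safe by construction: taxonomies, discretization bins, feature scores,
the selected column set and the classifier itself are all fitted on the
training portion only.  Metrics per run are overall accuracy, sensitivity
(correctly identified cancer), specificity (correctly identified controls) —
all as percentages with cancer as the positive class — plus AUROC from the
positive-class score with midrank tie handling.  Runs aggregate to means with
Student-t 95% confidence intervals, and configurations are compared by
one-way ANOVA with Bonferroni-adjusted pairwise t-tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.preprocessing import OneHotEncoder
from sklearn.svm import SVC

from .common_features import FeatureTable, common_feature_table
from .feature_selection import score_features, select_features
from .preprocess import CurvePanel
from .shape_taxonomy import (
    build_taxonomy,
    membership_feature_table,
    pairwise_distances,
)

POSITIVE_CLASS = "cancer"
CLASSIFIERS = ("nb", "svm", "rf")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One point of the experiment factorial.

    ``feature_kind`` chooses between scalar curve summaries ("common") and
    cluster-membership attributes ("taxonomy"); distance/linkage only apply
    to the latter.  ``transductive`` clusters all rows once instead of
    refitting taxonomies on each training split (provided because either
    reading of the original protocol is defensible; the leakage-safe
    train-only mode is the default).
    """

    feature_kind: str = "taxonomy"        # taxonomy | common
    distance: str = "euclidean"           # euclidean | dtwarp
    linkage: str = "ward"                 # ward | complete
    selector: str = "infogain"            # infogain | symm_unc | relieff | none
    classifier: str = "nb"                # nb | svm | rf
    select_m: int = 26
    k_range: tuple[int, ...] = tuple(range(2, 11))
    end_window: int = 10
    test_fraction: float = 0.3
    transductive: bool = False

    @property
    def config_id(self) -> str:
        if self.feature_kind == "common":
            return f"common|{self.selector}|{self.classifier}"
        return (
            f"taxonomy|{self.distance}|{self.linkage}|"
            f"{self.selector}|{self.classifier}"
        )


@dataclass
class RunResult:
    run_id: int
    seed: int
    tp: int
    fn: int
    tn: int
    fp: int
    auroc: float

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


METRICS = ("accuracy", "sensitivity", "specificity", "auroc")


@dataclass
class AggregateResult:
    config_id: str
    n_runs: int
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class _FittedModel:
    """A trained classifier remembering its input schema."""

    def __init__(self, estimator, columns, kind, categories=None, encoder=None):
        self.estimator = estimator
        self.columns = list(columns)
        self.kind = kind
        self.categories = categories
        self.encoder = encoder

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        if table.feature_ids != self.columns:
            raise ValueError("feature columns do not match the training schema")
        X = table.df.to_numpy()
        if self.categories is not None:
            encoded = np.empty_like(X, dtype=int)
            for j, cats in enumerate(self.categories):
                idx = np.searchsorted(cats, X[:, j])
                idx = np.clip(idx, 0, len(cats) - 1)
                if not np.array_equal(cats[idx], X[:, j]):
                    raise ValueError("unseen nominal category at prediction time")
                encoded[:, j] = idx
            X = encoded
        if self.encoder is not None:
            X = self.encoder.transform(X)
        return X

    def predict(self, table: FeatureTable) -> np.ndarray:
        return self.estimator.predict(self._matrix(table))

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        """P(cancer) for each row."""
        proba = self.estimator.predict_proba(self._matrix(table))
        pos = list(self.estimator.classes_).index(POSITIVE_CLASS)
        return proba[:, pos]


def train_classifier(table: FeatureTable, algorithm: str, seed: int) -> _FittedModel:
    """Fit NB / linear SVM / RF on a feature table.

    NB uses categorical likelihoods with Laplace add-1 smoothing on nominal
    membership columns and per-class Gaussians on numeric columns.  SVM is a
    linear kernel at C=1 with one-hot encoded nominal columns and Platt-style
    probability calibration on the decision values.  RF grows 100 trees with
    sqrt-feature subsampling.
    """
    if algorithm not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {algorithm!r}")
    y = table.labels.to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    X = table.df.to_numpy()
    nominal = table.kind == "nominal"

    categories = None
    encoder = None
    if nominal:
        categories = [np.unique(X[:, j]) for j in range(X.shape[1])]
        Xenc = np.empty_like(X, dtype=int)
        for j, cats in enumerate(categories):
            Xenc[:, j] = np.searchsorted(cats, X[:, j])
        X = Xenc

    if algorithm == "nb":
        if nominal:
            est = CategoricalNB(alpha=1.0)
        else:
            est = GaussianNB()
    elif algorithm == "svm":
        if nominal:
            encoder = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
            X = encoder.fit_transform(X)
        est = SVC(kernel="linear", C=1.0, probability=True, random_state=seed)
    else:
        est = RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        )
    est.fit(X, y)
    return _FittedModel(est, table.feature_ids, table.kind, categories, encoder)


# ---------------------------------------------------------------------------
# single evaluation run
# ---------------------------------------------------------------------------

def stratified_split(
    labels: pd.Series, test_fraction: float, seed: int, max_attempts: int = 10
) -> tuple[list[str], list[str]]:
    """Class-stratified random holdout split; redraws if a fold lacks a class."""
    ids = np.asarray(labels.index)
    y = labels.to_numpy()
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        train, test = [], []
        for c in np.unique(y):
            members = ids[y == c]
            perm = rng.permutation(len(members))
            n_test = int(round(test_fraction * len(members)))
            test.extend(members[perm[:n_test]])
            train.extend(members[perm[n_test:]])
        train_classes = set(labels.loc[train])
        test_classes = set(labels.loc[test])
        if len(train_classes) >= 2 and len(test_classes) >= 2:
            return sorted(train), sorted(test)
    raise ValueError("could not draw a split containing both classes")


def auroc_score(y_true: Sequence[str], scores: Sequence[float]) -> float:
    """Rank-statistic AUROC for the positive (cancer) class with midrank ties."""
    y = np.asarray(y_true) == POSITIVE_CLASS
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _feature_tables(
    panels: Mapping[str, CurvePanel],
    labels: Mapping[str, str],
    config: PipelineConfig,
    train_ids: Sequence[str],
    distance_cache: Mapping[str, np.ndarray] | None,
) -> FeatureTable:
    if config.feature_kind == "common":
        return common_feature_table(panels, labels, end_window=config.end_window)
    if config.feature_kind != "taxonomy":
        raise ValueError(f"unknown feature kind {config.feature_kind!r}")
    fit_ids = (
        list(panels[sorted(panels)[0]].measurement_ids)
        if config.transductive
        else list(train_ids)
    )
    taxonomies = {}
    for sid in sorted(panels):
        sub = panels[sid].subset(fit_ids)
        condensed = None
        if distance_cache is not None and sid in distance_cache:
            condensed = _subset_condensed(
                distance_cache[sid], panels[sid].measurement_ids, fit_ids
            )
        taxonomies[sid] = build_taxonomy(
            sub,
            distance=config.distance,
            linkage=config.linkage,
            k_range=config.k_range,
            condensed=condensed,
        )
    return membership_feature_table(taxonomies, panels, labels)


def _subset_condensed(
    square: np.ndarray, all_ids: Sequence[str], ids: Sequence[str]
) -> np.ndarray:
    from scipy.spatial.distance import squareform

    index = {m: i for i, m in enumerate(all_ids)}
    rows = [index[m] for m in ids]
    return squareform(square[np.ix_(rows, rows)], checks=False)


def precompute_distances(
    panels: Mapping[str, CurvePanel], distance: str, band: int | None = None
) -> dict[str, np.ndarray]:
    """Square per-sensor distance matrices over all rows.

    Pairwise dissimilarities depend on the two curves only, so train-subset
    matrices sliced from this cache are identical to recomputing them on the
    training rows; the cache just removes repeated work across runs.
    """
    from scipy.spatial.distance import squareform

    return {
        sid: squareform(pairwise_distances(p.curve_matrix, distance, band=band))
        for sid, p in panels.items()
    }


def evaluate_run(
    panels: Mapping[str, CurvePanel],
    labels: Mapping[str, str],
    config: PipelineConfig,
    seed: int,
    run_id: int = 0,
    distance_cache: Mapping[str, np.ndarray] | None = None,
) -> RunResult:
    """One feature-selection → training → testing cycle on a fresh split."""
    label_series = pd.Series(labels).loc[
        panels[sorted(panels)[0]].measurement_ids
    ]
    train_ids, test_ids = stratified_split(label_series, config.test_fraction, seed)
    table = _feature_tables(panels, labels, config, train_ids, distance_cache)
    train_table = table.subset_rows(train_ids)
    test_table = table.subset_rows(test_ids)

    if config.selector != "none":
        scores = score_features(train_table, config.selector)
        selected = select_features(scores, policy="top_m", m=config.select_m)
        train_table = train_table.subset_columns(selected)
        test_table = test_table.subset_columns(selected)

    model = train_classifier(train_table, config.classifier, seed)
    predictions = model.predict(test_table)
    scores_pos = model.predict_scores(test_table)
    y_true = test_table.labels.to_numpy()

    tp = int(np.sum((y_true == POSITIVE_CLASS) & (predictions == POSITIVE_CLASS)))
    fn = int(np.sum((y_true == POSITIVE_CLASS) & (predictions != POSITIVE_CLASS)))
    tn = int(np.sum((y_true != POSITIVE_CLASS) & (predictions != POSITIVE_CLASS)))
    fp = int(np.sum((y_true != POSITIVE_CLASS) & (predictions == POSITIVE_CLASS)))
    return RunResult(
        run_id=run_id,
        seed=seed,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        auroc=auroc_score(y_true, scores_pos),
    )


# ---------------------------------------------------------------------------
# aggregation and comparison
# ---------------------------------------------------------------------------

def aggregate(results: Sequence[RunResult], config_id: str = "") -> AggregateResult:
    """Mean and Student-t 95% CI of each metric across runs."""
    if len(results) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    means, lo, hi = {}, {}, {}
    n = len(results)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    for metric in METRICS:
        values = np.array([getattr(r, metric) for r in results], dtype=float)
        m = float(values.mean())
        half = tcrit * float(values.std(ddof=1)) / np.sqrt(n)
        means[metric], lo[metric], hi[metric] = m, m - half, m + half
    return AggregateResult(config_id=config_id, n_runs=n, means=means, ci_low=lo, ci_high=hi)


def compare_configurations(
    metric_by_config: Mapping[str, Sequence[float]],
) -> dict:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Returns {"anova_p": float, "pairwise": DataFrame[config_a, config_b,
    p_raw, p_adjusted]} with adjusted p = min(1, p · n_pairs).
    """
    configs = sorted(metric_by_config)
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to compare")
    groups = [np.asarray(metric_by_config[c], dtype=float) for c in configs]
    for c, g in zip(configs, groups):
        if g.size == 0:
            raise ValueError(f"configuration {c!r} has no runs")
    anova_p = float(stats.f_oneway(*groups).pvalue)
    pairs = list(itertools.combinations(range(len(configs)), 2))
    rows = []
    for i, j in pairs:
        p = float(stats.ttest_ind(groups[i], groups[j]).pvalue)
        rows.append(
            {
                "config_a": configs[i],
                "config_b": configs[j],
                "p_raw": p,
                "p_adjusted": min(1.0, p * len(pairs)),
            }
        )
    return {"anova_p": anova_p, "pairwise": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# experiment matrix
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    combinations: list[PipelineConfig]
    n_runs: int = 1000
    master_seed: int = 0


@dataclass
class ExperimentResults:
    aggregates: dict[str, AggregateResult]
    runs: dict[str, list[RunResult]]
    errors: dict[str, str] = field(default_factory=dict)

    def metric_vectors(self, metric: str) -> dict[str, list[float]]:
        return {
            cid: [getattr(r, metric) for r in rr] for cid, rr in self.runs.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, agg in self.aggregates.items():
            row = {"configuration": cid, "n_runs": agg.n_runs}
            for metric in METRICS:
                row[f"{metric}_mean"] = agg.means[metric]
                row[f"{metric}_ci_low"] = agg.ci_low[metric]
                row[f"{metric}_ci_high"] = agg.ci_high[metric]
            rows.append(row)
        return pd.DataFrame(rows)


def run_experiment_matrix(
    panels: Mapping[str, CurvePanel],
    labels: Mapping[str, str],
    spec: ExperimentSpec,
) -> ExperimentResults:
    """Full factorial: every combination × n_runs, reseeded deterministically.

    A master seed spawns one child seed per (combination, run); repeating the
    call with the same master seed reproduces every split, selection and
    model exactly.
    """
    aggregates: dict[str, AggregateResult] = {}
    runs: dict[str, list[RunResult]] = {}
    errors: dict[str, str] = {}
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(len(spec.combinations))
    for config, child in zip(spec.combinations, children):
        cid = config.config_id
        cache = None
        if config.feature_kind == "taxonomy":
            cache = precompute_distances(panels, config.distance)
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(spec.n_runs)]
        results = [
            evaluate_run(panels, labels, config, seed, run_id=i, distance_cache=cache)
            for i, seed in enumerate(run_seeds)
        ]
        runs[cid] = results
        try:
            aggregates[cid] = aggregate(results, config_id=cid)
        except ValueError as exc:
            errors[cid] = str(exc)
    return ExperimentResults(aggregates=aggregates, runs=runs, errors=errors)
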