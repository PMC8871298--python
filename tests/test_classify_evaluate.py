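"""Classifier contracts, run metrics, aggregation and configuration comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import breathshape as bs
from breathshape.classify_evaluate import METRICS
from breathshape.common_features import FeatureTable


def _nominal_table(values, labels, ids=None):
    ids = ids or [f"m{i}" for i in range(len(labels))]
    df = pd.DataFrame({"f0": values}, index=pd.Index(ids, name="measurement_id"))
    return FeatureTable(df, pd.Series(labels, index=df.index, name="label"), "nominal")


class TestTrainClassifier:
    def test_nb_separable_nominal_perfect_on_train(self):
        values = [1] * 10 + [2] * 10
        labels = ["cancer"] * 10 + ["control"] * 10
        table = _nominal_table(values, labels)
        model = bs.train_classifier(table, "nb", seed=0)
        assert list(model.predict(table)) == labels

    def test_rf_deterministic_given_seed(self, rng):
        n = 40
        df = pd.DataFrame(
            rng.normal(size=(n, 5)),
            index=pd.Index([f"m{i}" for i in range(n)], name="measurement_id"),
            columns=[f"f{j}" for j in range(5)],
        )
        labels = pd.Series(["cancer", "control"] * 20, index=df.index, name="label")
        table = FeatureTable(df, labels, "numeric")
        m1 = bs.train_classifier(table, "rf", seed=7)
        m2 = bs.train_classifier(table, "rf", seed=7)
        assert np.array_equal(m1.predict_scores(table), m2.predict_scores(table))

    def test_single_class_rejected(self):
        table = _nominal_table([1, 2, 1], ["cancer"] * 3)
        for algo in ("nb", "svm", "rf"):
            with pytest.raises(ValueError):
                bs.train_classifier(table, algo, seed=0)

    def test_svm_single_row_rejected(self):
        table = _nominal_table([1], ["cancer"])
        with pytest.raises(ValueError):
            bs.train_classifier(table, "svm", seed=0)

    def test_schema_mismatch_rejected(self):
        labels = ["cancer", "control"] * 5
        table = _nominal_table([1, 2] * 5, labels)
        model = bs.train_classifier(table, "nb", seed=0)
        other = table.df.rename(columns={"f0": "g0"})
        wrong = FeatureTable(other, table.labels, "nominal")
        with pytest.raises(ValueError, match="schema"):
            model.predict(wrong)


class TestRunMetrics:
    def test_confusion_arithmetic(self):
        r = bs.RunResult(run_id=0, seed=0, tp=2, fn=1, tn=3, fp=1, auroc=0.8)
        assert r.sensitivity == pytest.approx(66.6667, abs=1e-3)
        assert r.specificity == pytest.approx(75.0)
        assert r.accuracy == pytest.approx(71.4286, abs=1e-3)

    def test_perfect_scores_auroc_one(self):
        y = ["cancer"] * 3 + ["control"] * 4
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1, 0.05]
        assert bs.auroc_score(y, scores) == 1.0

    def test_tied_scores_auroc_half(self):
        y = ["cancer", "control"] * 5
        assert bs.auroc_score(y, [0.5] * 10) == 0.5

    def test_auroc_monotone_transform_invariance(self, rng):
        for _ in range(20):
            y = np.where(rng.random(30) < 0.4, "cancer", "control")
            if len(set(y)) < 2:
                continue
            s = rng.normal(size=30)
            base = bs.auroc_score(y, s)
            assert bs.auroc_score(y, np.exp(s)) == pytest.approx(base)
            assert bs.auroc_score(y, 3 * s + 7) == pytest.approx(base)


class TestEvaluateRun:
    def test_metric_identities_recompute(self, small_sim):
        run = bs.evaluate_run(
            small_sim["panels"], small_sim["labels"], bs.PipelineConfig(), seed=11
        )
        total = run.tp + run.tn + run.fp + run.fn
        assert run.accuracy == pytest.approx(100 * (run.tp + run.tn) / total)
        assert run.sensitivity == pytest.approx(100 * run.tp / (run.tp + run.fn))
        assert run.specificity == pytest.approx(100 * run.tn / (run.tn + run.fp))

    def test_split_is_stratified_and_disjoint(self, small_sim):
        labels = pd.Series(small_sim["labels"])
        train, test = bs.stratified_split(labels, 0.3, seed=5)
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(labels.index)
        assert len(set(labels.loc[train])) == 2
        assert len(set(labels.loc[test])) == 2

    def test_leakage_guard_test_labels_do_not_touch_model(self, small_sim):
        """Permuting labels outside the training split leaves the model unchanged."""
        panels, labels = small_sim["panels"], dict(small_sim["labels"])
        config = bs.PipelineConfig(feature_kind="common")
        label_series = pd.Series(labels).loc[panels["GNP01"].measurement_ids]
        train_ids, test_ids = bs.stratified_split(label_series, 0.3, seed=3)
        table = bs.common_feature_table(panels, labels)
        from breathshape.feature_selection import score_features, select_features

        def fit(perturbed_labels):
            t = FeatureTable(table.df, pd.Series(perturbed_labels).loc[table.df.index], "numeric")
            train = t.subset_rows(train_ids)
            sel = select_features(score_features(train, "infogain"), m=10)
            model = bs.train_classifier(train.subset_columns(sel), "nb", seed=1)
            return sel, model.estimator.theta_.copy()

        flipped = dict(labels)
        for mid in test_ids:
            flipped[mid] = "control" if flipped[mid] == "cancer" else "cancer"
        sel_a, theta_a = fit(labels)
        sel_b, theta_b = fit(flipped)
        assert sel_a == sel_b
        assert np.array_equal(theta_a, theta_b)


class TestAggregate:
    def _runs(self, accuracies):
        out = []
        for i, a in enumerate(accuracies):
            tp = int(round(a))
            out.append(bs.RunResult(run_id=i, seed=i, tp=tp, fn=100 - tp, tn=tp,
                                    fp=100 - tp, auroc=a / 100))
        return out

    def test_identical_values_zero_width_ci(self):
        runs = [bs.RunResult(run_id=i, seed=i, tp=3, fn=1, tn=4, fp=2, auroc=0.75)
                for i in range(10)]
        agg = bs.aggregate(runs)
        for metric in METRICS:
            assert agg.ci_low[metric] == pytest.approx(agg.means[metric])
            assert agg.ci_high[metric] == pytest.approx(agg.means[metric])

    def test_two_values_symmetric(self):
        agg = bs.aggregate(self._runs([60, 80]))
        assert agg.means["accuracy"] == pytest.approx(70.0)
        assert agg.ci_high["accuracy"] - 70 == pytest.approx(70 - agg.ci_low["accuracy"])

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            bs.aggregate(self._runs([50]))

    def test_t_interval_nominal_coverage(self, rng):
        """95% t-intervals over repeated gaussian samples cover the true mean."""
        mu, n_rep, n = 70.0, 400, 25
        covered = 0
        tcrit = stats.t.ppf(0.975, n - 1)
        for _ in range(n_rep):
            x = rng.normal(mu, 5, size=n)
            half = tcrit * x.std(ddof=1) / np.sqrt(n)
            covered += abs(x.mean() - mu) <= half
        assert 0.92 <= covered / n_rep <= 0.98


class TestCompareConfigurations:
    def test_null_distributions_not_significant(self, rng):
        groups = {f"c{i}": rng.normal(70, 5, size=100) for i in range(3)}
        result = bs.compare_configurations(groups)
        assert result["anova_p"] > 0.05
        assert (result["pairwise"]["p_adjusted"] > 0.05).all()

    def test_shifted_group_detected(self, rng):
        groups = {
            "low": rng.normal(50, 1, size=100),
            "high": rng.normal(60, 1, size=100),
        }
        result = bs.compare_configurations(groups)
        assert result["pairwise"]["p_adjusted"].iloc[0] < 1e-6

    def test_single_configuration_rejected(self, rng):
        with pytest.raises(ValueError):
            bs.compare_configurations({"only": rng.normal(size=10)})

    def test_adjustment_multiplies_and_caps(self, rng):
        groups = {f"c{i}": rng.normal(size=30) for i in range(4)}
        result = bs.compare_configurations(groups)
        n_pairs = 6
        for _, row in result["pairwise"].iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * n_pairs))


class TestExperimentMatrix:
    def test_bookkeeping_and_determinism(self, small_sim):
        spec = bs.ExperimentSpec(
            combinations=[
                bs.PipelineConfig(feature_kind="common", classifier="nb"),
                bs.PipelineConfig(feature_kind="taxonomy", classifier="nb"),
            ],
            n_runs=4,
            master_seed=99,
        )
        r1 = bs.run_experiment_matrix(small_sim["panels"], small_sim["labels"], spec)
        r2 = bs.run_experiment_matrix(small_sim["panels"], small_sim["labels"], spec)
        assert len(r1.aggregates) == 2
        for agg in r1.aggregates.values():
            assert agg.n_runs == 4
        pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())

    def test_single_run_error_surfaced_per_combination(self, small_sim):
        spec = bs.ExperimentSpec(
            combinations=[bs.PipelineConfig(feature_kind="common")],
            n_runs=1,
            master_seed=1,
        )
        results = bs.run_experiment_matrix(small_sim["panels"], small_sim["labels"], spec)
        assert results.errors
        assert "common|infogain|nb" in results.errors
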