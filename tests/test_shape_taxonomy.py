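"""Distances, agglomerative linkage, dendrogram cuts and membership encoding."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import breathshape as bs
from breathshape.preprocess import CurvePanel
from breathshape.shape_taxonomy import cut_dendrogram

from oracles import dtw_brute, merge_sets_from_Z, naive_agglomeration


class TestEuclideanDistance:
    def test_pythagorean(self):
        assert bs.euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_zero_on_identical(self, rng):
        x = rng.normal(size=10)
        assert bs.euclidean_distance(x, x) == 0.0

    def test_pointwise_arithmetic(self):
        assert bs.euclidean_distance([1, 2, 3], [2, 2, 4]) == pytest.approx(np.sqrt(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bs.euclidean_distance([1, 2], [1, 2, 3])


class TestDTWDistance:
    def test_zero_on_identical(self, rng):
        x = rng.normal(size=15)
        assert bs.dtw_distance(x, x) == 0.0

    def test_warping_absorbs_duplicate(self):
        assert bs.dtw_distance([1, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert bs.dtw_distance([0, 0, 0], [1, 1, 1]) == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bs.dtw_distance([], [1, 2])

    def test_band_narrower_than_length_gap(self):
        with pytest.raises(ValueError):
            bs.dtw_distance([1, 2, 3, 4, 5, 6], [1, 2], band=1)

    def test_symmetry_and_diagonal_bound(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(size=rng.integers(3, 15))
            assert bs.dtw_distance(a, b) == pytest.approx(bs.dtw_distance(b, a))
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            assert bs.dtw_distance(a, b) <= np.sum(np.abs(a - b)) + 1e-12

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(1, 13))
            b = rng.normal(size=rng.integers(1, 13))
            assert bs.dtw_distance(a, b) == pytest.approx(dtw_brute(a, b), abs=1e-10)

    def test_band_only_tightens(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        free = bs.dtw_distance(a, b)
        banded = bs.dtw_distance(a, b, band=2)
        assert banded >= free - 1e-12


class TestLinkage:
    def test_nearest_pair_merges_first(self):
        D = np.array([[0, 1, 9], [1, 0, 9.5], [9, 9.5, 0]], dtype=float)
        for method in ("complete", "ward"):
            Z = bs.linkage_cluster(D, method)
            assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_count(self, rng):
        X = rng.normal(size=(9, 4))
        Z = bs.linkage_cluster(pdist(X), "complete")
        assert Z.shape == (8, 4)

    @pytest.mark.parametrize("method", ["complete", "ward"])
    def test_matches_naive_oracle(self, method, rng):
        for _ in range(30):
            X = rng.normal(size=(8, 5))
            S = squareform(pdist(X))
            Z = bs.linkage_cluster(S, method)
            heights, merged = naive_agglomeration(S, method)
            assert np.allclose(Z[:, 2], heights, atol=1e-9)
            assert merge_sets_from_Z(Z) == merged

    @pytest.mark.parametrize("method,scipy_method", [("complete", "complete"), ("ward", "ward")])
    def test_matches_scipy_on_tie_free_input(self, method, scipy_method, rng):
        X = rng.normal(size=(12, 6))
        condensed = pdist(X)
        Z_ours = bs.linkage_cluster(condensed, method)
        Z_scipy = sch.linkage(condensed, method=scipy_method)
        assert np.allclose(np.sort(Z_ours[:, 2]), np.sort(Z_scipy[:, 2]), atol=1e-8)
        for k in (2, 3, 5):
            ours = cut_dendrogram(Z_ours, k)
            theirs = sch.cut_tree(Z_scipy, n_clusters=k).ravel()
            assert adjusted_rand_score(ours, theirs) == pytest.approx(1.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            bs.linkage_cluster(D, "complete")

    def test_negative_rejected(self):
        D = np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            bs.linkage_cluster(D, "complete")


class TestBuildTaxonomy:
    def test_two_separated_groups_recovered(self, rng):
        flat = np.ones(40)
        bump = np.ones(40)
        bump[10:30] += 1.0
        curves = np.vstack(
            [flat + 0.05 * rng.normal(size=40) for _ in range(10)]
            + [bump + 0.05 * rng.normal(size=40) for _ in range(10)]
        )
        panel = CurvePanel("S", curves, [f"m{i}" for i in range(20)])
        tax = bs.build_taxonomy(panel, "euclidean", "ward", k_range=[2])
        labels = [tax.levels[2].assignment[f"m{i}"] for i in range(20)]
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_singleton_cut_returns_curves(self, rng):
        curves = rng.normal(size=(5, 12))
        panel = CurvePanel("S", curves, [f"m{i}" for i in range(5)])
        tax = bs.build_taxonomy(panel, "euclidean", "complete", k_range=[5])
        level = tax.levels[5]
        for i, mid in enumerate(panel.measurement_ids):
            c = level.assignment[mid]
            assert np.allclose(level.characteristic_curves[c - 1], curves[i])

    def test_characteristic_curves_are_member_means(self, tiny_panels):
        panel = tiny_panels["GNP01"]
        tax = bs.build_taxonomy(panel, "euclidean", "ward", k_range=[3])
        level = tax.levels[3]
        for c in range(1, 4):
            members = [m for m, a in level.assignment.items() if a == c]
            rows = [panel.measurement_ids.index(m) for m in members]
            assert np.allclose(
                level.characteristic_curves[c - 1],
                panel.curve_matrix[rows].mean(axis=0),
            )

    def test_identical_curves_warn_with_zero_heights(self):
        curves = np.tile(np.linspace(1, 2, 15), (6, 1))
        panel = CurvePanel("S", curves, [f"m{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="identical"):
            tax = bs.build_taxonomy(panel, "euclidean", "complete", k_range=[2])
        assert np.allclose(tax.merge_tree[:, 2], 0.0)

    def test_oversized_k_omitted_with_warning(self, rng):
        curves = rng.normal(size=(4, 10))
        panel = CurvePanel("S", curves, [f"m{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="omitting"):
            tax = bs.build_taxonomy(panel, "euclidean", "ward", k_range=[2, 6])
        assert sorted(tax.levels) == [2]

    def test_nesting_property(self, tiny_panels):
        for sid, panel in tiny_panels.items():
            for distance in ("euclidean",):
                for linkage in ("complete", "ward"):
                    tax = bs.build_taxonomy(panel, distance, linkage)
                    assert bs.check_nesting(tax), (sid, distance, linkage)

    def test_serialization_round_trip(self, tiny_panels, tmp_path):
        tax = bs.build_taxonomy(tiny_panels["GNP01"], "euclidean", "ward")
        path = tmp_path / "tax.json"
        tax.save(path)
        again = bs.ShapeTaxonomy.load(path)
        assert again.levels.keys() == tax.levels.keys()
        for k in tax.levels:
            assert again.levels[k].assignment == tax.levels[k].assignment
            assert np.allclose(
                again.levels[k].characteristic_curves,
                tax.levels[k].characteristic_curves,
            )


class TestAssignMembership:
    def test_exact_characteristic_curve_maps_to_itself(self, tiny_panels):
        tax = bs.build_taxonomy(tiny_panels["GNP01"], "euclidean", "ward", k_range=[4])
        level = tax.levels[4]
        for j in range(4):
            assert bs.assign_membership(
                level.characteristic_curves[j], level, "euclidean"
            ) == j + 1

    def test_training_curves_return_home_when_separated(self, rng):
        centers = np.vstack([np.zeros(20), np.full(20, 5.0), np.full(20, -5.0)])
        curves = np.vstack([c + 0.01 * rng.normal(size=20) for c in centers for _ in range(4)])
        panel = CurvePanel("S", curves, [f"m{i}" for i in range(12)])
        tax = bs.build_taxonomy(panel, "euclidean", "ward", k_range=[3])
        level = tax.levels[3]
        for i, mid in enumerate(panel.measurement_ids):
            assert bs.assign_membership(curves[i], level, "euclidean") == level.assignment[mid]

    def test_tie_breaks_low(self):
        level = bs.ClusterLevel(
            k=2,
            assignment={"a": 1, "b": 2},
            characteristic_curves=np.array([[1.0, 0.0], [-1.0, 0.0]]),
        )
        assert bs.assign_membership([0.0, 0.0], level, "euclidean") == 1

    def test_length_mismatch(self):
        level = bs.ClusterLevel(
            k=1, assignment={"a": 1}, characteristic_curves=np.ones((1, 4))
        )
        with pytest.raises(ValueError):
            bs.assign_membership([1.0, 2.0], level, "euclidean")


class TestMembershipTable:
    def test_full_array_column_count(self, small_sim):
        panels = small_sim["panels"]
        taxonomies = {sid: bs.build_taxonomy(p) for sid, p in panels.items()}
        table = bs.membership_feature_table(taxonomies, panels, small_sim["labels"])
        assert len(table.feature_ids) == 26 * 9 == 234
        assert table.kind == "nominal"

    def test_single_level_values(self, tiny_panels, small_sim):
        panels = {"GNP01": tiny_panels["GNP01"]}
        taxonomies = {"GNP01": bs.build_taxonomy(panels["GNP01"], k_range=[2])}
        table = bs.membership_feature_table(taxonomies, panels, small_sim["labels"])
        assert table.feature_ids == ["GNP01_k2"]
        assert set(table.df["GNP01_k2"]) <= {1, 2}

    def test_missing_taxonomy_rejected(self, tiny_panels, small_sim):
        taxonomies = {"GNP01": bs.build_taxonomy(tiny_panels["GNP01"])}
        with pytest.raises(ValueError, match="missing taxonomy"):
            bs.membership_feature_table(taxonomies, tiny_panels, small_sim["labels"])

    def test_test_row_equal_to_training_row_gets_same_vector(self, rng):
        centers = np.vstack([np.zeros(15), np.full(15, 4.0)])
        curves = np.vstack([c + 0.01 * rng.normal(size=15) for c in centers for _ in range(5)])
        ids = [f"m{i}" for i in range(10)]
        panel = CurvePanel("S", curves, ids)
        train = panel.subset(ids[:8])
        tax = bs.build_taxonomy(train, "euclidean", "ward", k_range=[2])
        labels = {m: ("cancer" if i % 2 else "control") for i, m in enumerate(ids)}
        # duplicate a training curve as a "test" row
        dup = CurvePanel("S", np.vstack([curves[:8], curves[[0]]]), ids[:8] + ["copy"])
        labels["copy"] = "control"
        table = bs.membership_feature_table({"S": tax}, {"S": dup}, labels)
        assert table.df.loc["copy", "S_k2"] == table.df.loc["m0", "S_k2"]
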