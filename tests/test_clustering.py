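import itertools

import numpy as np
import pytest

from planktraits import (
    DissimilarityMatrix,
    TraitAssignment,
    ValidationError,
    cut_tree,
    elbow_select,
    encode_traits,
    export_dendrogram,
    gower,
    import_dendrogram,
    ward_cluster,
)
from planktraits.clustering import argmax_curvature


def ward_cost_oracle(dm: DissimilarityMatrix):
    """Exhaustive-search agglomeration recomputing the Ward merge cost from
    scratch at every step.

    Within-cluster dispersion SS(C) = (1/|C|) sum_{i<j in C} d^2; the merge
    cost of (A, B) is SS(A|B) - SS(A) - SS(B) and the reported height is
    sqrt(2 * cost), matching the Lance-Williams Ward.D2 convention.
    """
    d2 = dm.values**2
    n = dm.n

    def ss(c):
        idx = sorted(c)
        return sum(d2[a, b] for a, b in itertools.combinations(idx, 2)) / len(c)

    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            cost = ss(clusters[i] | clusters[j]) - ss(clusters[i]) - ss(clusters[j])
            if best is None or cost < best[0] - 1e-12:
                best = (cost, i, j)
        cost, i, j = best
        new = n + step
        clusters[new] = clusters.pop(i) | clusters.pop(j)
        merges.append((i, j, float(np.sqrt(max(2 * cost, 0.0))), len(clusters[new])))
    return merges


def random_dissimilarity(rng, n):
    A = rng.random((n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    D /= D.max()
    return DissimilarityMatrix(labels=[f"s{i}" for i in range(n)], values=D)


def partition_sets(assignment):
    return {frozenset(assignment.members(g)) for g in range(1, assignment.k + 1)}


def profile(name, body, feed, troph, rep):
    return TraitAssignment(name, body, feed, troph, rep)


class TestGower:
    def test_identical_profiles_distance_zero(self):
        m = encode_traits(
            [
                profile("a", "small", "current", "carnivore", "free_spawner"),
                profile("b", "small", "current", "carnivore", "free_spawner"),
            ]
        )
        for mode in ("categorical_traits", "binary_columns"):
            assert gower(m, mode).values[0, 1] == 0.0

    def test_all_traits_differ(self):
        m = encode_traits(
            [
                profile("a", "small", "current", "carnivore", "free_spawner"),
                profile("b", "giant", "mixed", "omnivore", "egg_brooding"),
            ]
        )
        assert gower(m, "categorical_traits").values[0, 1] == pytest.approx(1.0)
        assert gower(m, "binary_columns").values[0, 1] == pytest.approx(8 / 17)

    def test_single_trait_differs(self):
        m = encode_traits(
            [
                profile("a", "small", "current", "carnivore", "free_spawner"),
                profile("b", "small", "mixed", "carnivore", "free_spawner"),
            ]
        )
        assert gower(m, "categorical_traits").values[0, 1] == pytest.approx(0.25)
        assert gower(m, "binary_columns").values[0, 1] == pytest.approx(2 / 17)

    def test_modes_proportional_on_fixture(self, fixture_matrix):
        matrix, _ = fixture_matrix
        d_cat = gower(matrix, "categorical_traits").values
        d_bin = gower(matrix, "binary_columns").values
        assert np.allclose(d_bin, (8 / 17) * d_cat)
        assert np.allclose(d_cat, d_cat.T)
        assert (np.diag(d_cat) == 0).all()
        assert d_cat.min() >= 0 and d_cat.max() <= 1

    def test_unknown_mode_rejected(self, fixture_matrix):
        with pytest.raises(ValueError):
            gower(fixture_matrix[0], "euclidean")


class TestWardCluster:
    def test_two_items_single_merge(self):
        dm = DissimilarityMatrix(labels=["A", "B"], values=np.array([[0, 0.6], [0.6, 0]]))
        dend = ward_cluster(dm)
        assert len(dend.merges) == 1
        left, right, height, size = dend.merges[0]
        assert (left, right, size) == (0, 1, 2)
        assert height == pytest.approx(0.6)

    def test_zero_distance_pairs_merge_first(self):
        D = np.full((4, 4), 0.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        dend = ward_cluster(DissimilarityMatrix(labels=list("abcd"), values=D))
        assert {tuple(m[:2]) for m in dend.merges[:2]} == {(0, 1), (2, 3)}
        assert dend.merges[0][2] == 0.0 and dend.merges[1][2] == 0.0

    def test_singleton_input_rejected(self):
        with pytest.raises(ValidationError):
            ward_cluster(DissimilarityMatrix(labels=["A"], values=np.zeros((1, 1))))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dm = random_dissimilarity(rng, int(rng.integers(4, 11)))
        impl = ward_cluster(dm).merges
        oracle = ward_cost_oracle(dm)
        for (a, b, h, s), (a2, b2, h2, s2) in zip(impl, oracle):
            assert (a, b, s) == (a2, b2, s2)
            assert h == pytest.approx(h2, abs=1e-8)

    def test_matches_scipy_on_metric_data(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        pts = rng.random((9, 3))
        D = squareform(pdist(pts))
        D /= D.max() * 1.01
        dm = DissimilarityMatrix(labels=[f"s{i}" for i in range(9)], values=D)
        Z = linkage(squareform(D), method="ward")
        for row, (a, b, h, _s) in zip(Z, ward_cluster(dm).merges):
            assert {int(row[0]), int(row[1])} == {a, b}
            assert row[2] == pytest.approx(h, abs=1e-8)

    def test_heights_monotone(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        heights = [m[2] for m in dend.merges]
        assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(heights, heights[1:]))

    def test_topology_invariant_under_gower_mode(self, fixture_matrix):
        matrix, _ = fixture_matrix
        merges_cat = [m[:2] for m in ward_cluster(gower(matrix, "categorical_traits")).merges]
        merges_bin = [m[:2] for m in ward_cluster(gower(matrix, "binary_columns")).merges]
        assert merges_cat == merges_bin


class TestCutTree:
    def test_extreme_cuts(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        assert cut_tree(dend, 1).k == 1
        singles = cut_tree(dend, dend.n)
        assert singles.k == dend.n
        assert sorted(singles.sizes().values()) == [1] * dend.n

    def test_out_of_range_k(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        with pytest.raises(ValidationError):
            cut_tree(dend, 0)
        with pytest.raises(ValidationError):
            cut_tree(dend, dend.n + 1)

    def test_nested_across_k(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        for k in range(2, 12):
            coarse = partition_sets(cut_tree(dend, k))
            fine = partition_sets(cut_tree(dend, k + 1))
            for group in coarse:
                assert any(part <= group for part in fine)
                assert group == frozenset().union(*(p for p in fine if p <= group))

    def test_recovers_eight_distinct_profiles(self, eight_profile_matrix):
        from sklearn.metrics import adjusted_rand_score

        matrix, planted = eight_profile_matrix
        dend = ward_cluster(gower(matrix))
        cut = cut_tree(dend, 8)
        assert adjusted_rand_score(planted, cut.group_ids) == 1.0

    def test_groups_numbered_by_decreasing_size(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        cut = cut_tree(dend, 6)
        sizes = [cut.sizes()[g] for g in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)


class TestElbow:
    def test_zero_dispersion_floor(self):
        # four equidistant planted profiles (all four traits differ between
        # any two groups), four identical species each: wss hits 0 at k=4
        # and the curvature maximum sits on the floor
        profiles = [
            ("small", "current", "omnivore_herbivore", "free_spawner"),
            ("medium", "active_ambush", "carnivore", "egg_brooding"),
            ("large", "passive_ambush", "omnivore_detritivore", "parthenogenesis"),
            ("giant", "mixed", "omnivore", "alternation_of_generations"),
        ]
        assignments = [
            profile(f"Q{g}_{i}", *p)
            for g, p in enumerate(profiles, start=1)
            for i in range(4)
        ]
        d = gower(encode_traits(assignments))
        curve = elbow_select(d, ward_cluster(d), k_max=8)
        wss = dict(zip(curve.k_values, curve.wss))
        assert wss[4] == pytest.approx(0.0, abs=1e-12)
        assert curve.selected_k == 4

    def test_wss_non_increasing(self, fixture_dendrogram):
        d, dend = fixture_dendrogram
        curve = elbow_select(d, dend, k_max=15)
        assert all(b <= a + 1e-12 for a, b in zip(curve.wss, curve.wss[1:]))

    def test_hand_built_kink_selected(self):
        # piecewise-linear decreasing curve with one sharp kink at k=5
        ks = list(range(2, 11))
        wss = [100 - 12 * (k - 2) if k <= 5 else 64 - 1.0 * (k - 5) for k in ks]
        assert argmax_curvature(ks, wss) == 5

    def test_k_max_validation(self, fixture_dendrogram):
        d, dend = fixture_dendrogram
        with pytest.raises(ValidationError):
            elbow_select(d, dend, k_max=d.n)
        with pytest.raises(ValidationError):
            elbow_select(d, dend, k_max=3)


class TestDendrogramSerialization:
    def test_two_leaf_newick_shape(self):
        dm = DissimilarityMatrix(labels=["A", "B"], values=np.array([[0, 0.5], [0.5, 0]]))
        nwk = export_dendrogram(ward_cluster(dm), "newick")
        assert nwk == "(A:0.5,B:0.5)n0;"

    def test_merge_json_round_trip_identity(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        back = import_dendrogram(export_dendrogram(dend, "merge_json"), "merge_json")
        assert back.leaf_labels == dend.leaf_labels
        assert back.merges == dend.merges

    def test_newick_round_trip_preserves_all_cuts(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        back = import_dendrogram(export_dendrogram(dend, "newick"), "newick")
        assert sorted(back.leaf_labels) == sorted(dend.leaf_labels)
        for k in range(1, dend.n + 1):
            assert partition_sets(cut_tree(back, k)) == partition_sets(cut_tree(dend, k))

    def test_unknown_format_rejected(self, fixture_dendrogram):
        _, dend = fixture_dendrogram
        with pytest.raises(ValueError):
            export_dendrogram(dend, "nexus")
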