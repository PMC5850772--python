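"""Complete-linkage clustering: oracles, ultrametricity, clade selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from cladecall import ConfigurationError, HierarchicalClades
from cladecall.cluster import Dendrogram, complete_linkage
from cladecall.errors import DegenerateDataError


def brute_force_complete_linkage(x, labels):
    """Independent enumeration oracle: at each step scan all cluster pairs,
    recomputing the complete-linkage distance from raw points."""
    clusters = [[i] for i in range(len(labels))]
    nodes = list(range(len(labels)))
    merges, heights = [], []
    next_node = len(labels)
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            d = max(np.linalg.norm(x[p] - x[q]) for p in a for q in b)
            key = (d, tuple(sorted((min(labels[p] for p in a),
                                    min(labels[q] for q in b)))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (d, _), i, j = best
        merges.append((nodes[i], nodes[j]))
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        nodes[i] = next_node
        next_node += 1
        del clusters[j], nodes[j]
    return merges, heights


class TestLinkage:
    def test_identical_profiles_merge_first_at_zero_height(self):
        x = np.array([[0.0, 0.0], [5.0, 1.0], [0.0, 0.0], [9.0, 3.0]])
        dend = complete_linkage(x, ["a", "b", "c", "d"])
        assert dend.merges[0] == (0, 2)
        assert dend.heights[0] == 0.0

    def test_four_point_hand_computed_merges(self):
        # points on a line: 0, 1, 3, 7.  (0,1) fuse at 1; point 3 joins at
        # max(3-0, 3-1) = 3; point 7 joins last at max distance 7.
        x = np.array([[0.0], [1.0], [3.0], [7.0]])
        dend = complete_linkage(x, ["p0", "p1", "p2", "p3"])
        assert dend.merges == ((0, 1), (4, 2), (5, 3))
        assert dend.heights == (1.0, 3.0, 7.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(0, 1, (n, 3))
        labels = [f"c{i}" for i in range(n)]
        dend = complete_linkage(x, labels)
        merges, heights = brute_force_complete_linkage(x, labels)
        assert list(dend.merges) == merges
        np.testing.assert_allclose(dend.heights, heights, atol=1e-12)

    def test_cophenetic_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (20, 5))
        labels = [f"c{i:02d}" for i in range(20)]
        dend = complete_linkage(x, labels)
        ours = squareform(dend.cophenetic().to_numpy(), checks=False)
        theirs = cophenet(linkage(x, method="complete"))
        np.testing.assert_allclose(np.sort(ours), np.sort(theirs), atol=1e-10)
        # heights themselves agree
        np.testing.assert_allclose(
            dend.heights, linkage(x, method="complete")[:, 2], atol=1e-10
        )

    def test_cophenetic_matrix_is_ultrametric(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (12, 4))
        coph = complete_linkage(x, [f"c{i}" for i in range(12)]).cophenetic()
        c = coph.to_numpy()
        for i, j, k in itertools.combinations(range(12), 3):
            d = sorted([c[i, j], c[i, k], c[j, k]])
            assert d[1] == pytest.approx(d[2], abs=1e-12)  # two largest equal

    def test_merge_heights_are_monotone(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, (30, 5))
        dend = complete_linkage(x, [f"c{i:02d}" for i in range(30)])
        assert all(
            dend.heights[i] <= dend.heights[i + 1] for i in range(len(dend.heights) - 1)
        )

    def test_partition_invariant_under_input_permutation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (15, 3))
        labels = [f"c{i:02d}" for i in range(15)]
        base = complete_linkage(x, labels).cut(4)
        perm = rng.permutation(15)
        cut = complete_linkage(x[perm], [labels[i] for i in perm]).cut(4)
        for k in (base, cut):
            assert set(k.index) == set(labels)
        groups_a = {frozenset(base.index[base == g]) for g in base.unique()}
        groups_b = {frozenset(cut.index[cut == g]) for g in cut.unique()}
        assert groups_a == groups_b

    def test_equal_distance_tie_broken_lexicographically(self):
        # three collinear equidistant points: ties between (a,b) and (b,c)
        x = np.array([[0.0], [1.0], [2.0]])
        dend = complete_linkage(x, ["b", "a", "c"])
        # pair distances: b-a = 1, a-c = 1 -> tie; keys ('a','b') < ('a','c')
        assert dend.merges[0] == (0, 1)  # leaves 'b' and 'a'

    def test_single_clone_degenerate_and_nan_rejected(self):
        dend = complete_linkage(np.array([[1.0, 2.0]]), ["only"])
        assert dend.merges == () and dend.n_leaves == 1
        with pytest.raises(ConfigurationError, match="NaN"):
            complete_linkage(np.array([[1.0], [np.nan]]), ["a", "b"])


class TestCladeSelection:
    def test_exact_clusters_recover_true_count_with_zero_wgss(self):
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        x = np.repeat(centers, 5, axis=0)
        frame = pd.DataFrame(x, index=[f"c{i:02d}" for i in range(15)])
        res = HierarchicalClades(frame).fit(k_max=8)
        assert res.k == 3
        assert res.trace.loc[res.trace["k"] == 3, "wgss"].iloc[0] == pytest.approx(0.0)

    def test_wgss_is_non_increasing_and_zero_at_n(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.normal(0, 1, (12, 4)), index=[f"c{i:02d}" for i in range(12)]
        )
        res = HierarchicalClades(frame).fit(k=3, k_max=12)
        w = res.trace["wgss"].to_numpy()
        assert np.all(np.diff(w) <= 1e-9)
        assert w[-1] == pytest.approx(0.0, abs=1e-18)

    def test_elbow_statistic_matches_arithmetic_recomputation(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            rng.normal(0, 1, (12, 3)), index=[f"c{i:02d}" for i in range(12)]
        )
        res = HierarchicalClades(frame).fit(k=2, k_max=10)
        w = res.trace["wgss"].to_numpy()
        stat = res.trace["elbow_stat"].to_numpy()
        for i in range(1, len(w) - 1):
            assert stat[i] == pytest.approx(w[i - 1] - 2 * w[i] + w[i + 1], rel=1e-12)
        curv = res.trace["log_curvature"].to_numpy()
        lw = np.log(w)
        for i in range(1, len(w) - 1):
            assert curv[i] == pytest.approx(
                lw[i - 1] - 2 * lw[i] + lw[i + 1], rel=1e-9
            )

    def test_automatic_selection_requires_room(self):
        frame = pd.DataFrame([[0.0], [1.0]], index=["a", "b"])
        with pytest.raises(DegenerateDataError, match="k_max"):
            HierarchicalClades(frame).fit()
        assert HierarchicalClades(frame).fit(k=2).k == 2

    def test_forced_k_overrides_selection(self, cohort_matrix):
        res = HierarchicalClades(cohort_matrix).fit(k=3)
        assert res.k == 3 and not res.selected_automatically
        assert res.assignment.nunique() == 3

    def test_correlation_metric_supported(self, cohort_matrix):
        res = HierarchicalClades(cohort_matrix, metric="correlation").fit(k=5)
        assert res.assignment.nunique() == 5


class TestNewick:
    def test_single_leaf(self):
        dend = Dendrogram(("c1",), (), ())
        assert dend.to_newick() == "c1;"

    def test_two_leaves_share_the_merge_height(self):
        dend = Dendrogram(("a", "b"), ((0, 1),), (3.5,))
        assert dend.to_newick() == "(a:3.5,b:3.5);"

    def test_round_trip_preserves_topology_and_heights(self):
        import skbio

        rng = np.random.default_rng(9)
        x = rng.normal(0, 2, (10, 4))
        labels = [f"c{i}" for i in range(10)]
        dend = complete_linkage(x, labels)
        tree = skbio.TreeNode.read([dend.to_newick()])
        coph = dend.cophenetic()
        for a, b in itertools.combinations(labels, 2):
            # tip-to-tip path length in an ultrametric tree = 2 * merge height
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                2 * coph.loc[a, b], abs=1e-9
            )


def test_zero_noise_clades_match_generative_classes(zero_noise_cohort):
    """Without noise the five-clade cut equals the class partition (classes
    sharing a clade co-cluster)."""
    from cladecall import build_matrix

    ct, truth, _ = zero_noise_cohort
    matrix = build_matrix(ct, "ancestor")
    res = HierarchicalClades(matrix).fit()
    classes = truth.set_index("clone")["class"].reindex(res.assignment.index)
    # without noise, every class collapses to a point: the automatic cut
    # resolves all eight classes and matches the class partition exactly
    assert res.k == classes.nunique()
    tab8 = pd.crosstab(classes, res.assignment)
    assert (tab8.gt(0).sum(axis=1) == 1).all()
    assert (tab8.gt(0).sum(axis=0) == 1).all()
    # the five-clade cut groups co-clading classes as documented
    tab = pd.crosstab(classes, res.dendrogram.cut(5))
    assert (tab.gt(0).sum(axis=1) == 1).all()
    expected_clades = {
        frozenset({"SNF3_high"}),
        frozenset({"SNF3_moderate", "MTH1"}),
        frozenset({"SNF3_low"}),
        frozenset({"RGT2", "IPT1"}),
        frozenset({"HXT67_amp", "MOT3"}),
    }
    observed = {
        frozenset(tab.index[tab[c] > 0]) for c in tab.columns
    }
    assert observed == expected_clades
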