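"""K-means/silhouette selection and the indegree-outdegree hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdsocial import (
    ahc_build,
    cluster_affinity,
    cluster_degrees,
    dendrogram_to_newick,
    kmeans_cluster,
    silhouette_select_k,
)


def brute_affinity(W, ca, cb, mode="mean"):
    """Independent double-loop evaluation of the directed affinities."""

    def directed(src, dst):
        total = 0.0
        for j in src:
            indeg = sum(W[m, j] for m in dst) / len(dst)
            outdeg = sum(W[j, m] for m in dst) / len(dst)
            total += indeg * outdeg
        return total

    s = directed(cb, ca) + directed(ca, cb)
    return s / 2 if mode == "mean" else s


def random_W(rng, n):
    """Random rank-style asymmetric matrix with zero diagonal."""
    m = rng.uniform(1, n - 1, size=(n, n))
    np.fill_diagonal(m, 0)
    return m


class TestKMeans:
    def test_two_separated_pairs(self):
        pts = np.array([[0, 0], [0.1, 0], [50, 50], [50.1, 50]])
        res = kmeans_cluster(pts, 2, seed=0)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        assert res.labels[0] == 0  # canonical first-occurrence labels

    def test_k_equal_n_rejected(self):
        with pytest.raises(ValueError, match="k must satisfy"):
            kmeans_cluster(np.zeros((4, 2)), 4)

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0, 1, (10, 2)), rng.normal(8, 1, (10, 2))]
        )
        res = kmeans_cluster(pts, 2, seed=0)

        def inertia(labels):
            tot = 0.0
            for c in set(labels):
                grp = pts[np.asarray(labels) == c]
                tot += ((grp - grp.mean(axis=0)) ** 2).sum()
            return tot

        best_random = min(
            inertia(rng.integers(0, 2, size=20)) for _ in range(200)
        )
        assert res.inertia <= best_random + 1e-9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, size=(12, 2))
        a = kmeans_cluster(pts, 3, seed=5)
        b = kmeans_cluster(pts, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestSilhouetteSelection:
    def test_three_planted_triplets(self):
        rng = np.random.default_rng(2)
        centres = np.array([[0, 0], [20, 0], [0, 20]])
        pts = np.vstack([c + rng.normal(0, 0.3, (3, 2)) for c in centres])
        k, labels, scores = silhouette_select_k(pts, seed=0)
        assert k == 3
        assert labels.k == 3
        assert all(-1 <= s <= 1 for s in scores.values())

    def test_planted_four_clusters_modal_k(self):
        """Over 20 noise seeds, the modal selected k matches the 4
        planted clusters."""
        centres = np.array([[0, 0], [30, 0], [0, 30], [30, 30]])
        selected = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.vstack([c + rng.normal(0, 1.0, (5, 2)) for c in centres])
            k, _, _ = silhouette_select_k(pts, seed=0)
            selected.append(k)
        values, counts = np.unique(selected, return_counts=True)
        assert values[np.argmax(counts)] == 4

    def test_k_within_range(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, size=(9, 2))
        k, _, scores = silhouette_select_k(pts, seed=0)
        assert set(scores) == set(range(2, 8))  # [2, min(8, N-2)]
        assert 2 <= k <= 7

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="N >= 4"):
            silhouette_select_k(np.zeros((3, 2)))


class TestClusterDegrees:
    def test_singleton_cluster(self, cattle_W):
        # animal 8 (index 7) vs cluster {10} (index 9)
        indeg, outdeg = cluster_degrees(cattle_W, 7, [9])
        assert indeg == pytest.approx(2.99)   # attention 8 attracts from 10
        assert outdeg == pytest.approx(3.06)  # attention 8 pays to 10

    def test_matches_explicit_sums(self):
        rng = np.random.default_rng(4)
        W = random_W(rng, 8)
        cluster = [1, 4, 6]
        indeg, outdeg = cluster_degrees(W, 0, cluster)
        assert indeg == pytest.approx(np.mean([W[j, 0] for j in cluster]))
        assert outdeg == pytest.approx(np.mean([W[0, j] for j in cluster]))

    def test_focal_in_cluster_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            cluster_degrees(np.zeros((3, 3)), 0, [0, 1])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            cluster_degrees(np.zeros((3, 3)), 0, [])


class TestClusterAffinity:
    def test_singleton_pair_product_identity(self, cattle_W):
        aff = cluster_affinity(cattle_W, [7], [9])  # animals 8 and 10
        assert aff == pytest.approx(3.06 * 2.99)
        assert cluster_affinity(cattle_W, [7], [9], mode="sum") == pytest.approx(
            2 * 3.06 * 2.99
        )

    @given(st.integers(0, 2**16))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        W = random_W(rng, 7)
        ca, cb = [0, 2], [1, 3, 5]
        assert cluster_affinity(W, ca, cb) == pytest.approx(
            cluster_affinity(W, cb, ca)
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        W = random_W(rng, 9)
        ca, cb = [0, 3], [1, 4, 7]
        for mode in ("mean", "sum"):
            assert cluster_affinity(W, ca, cb, mode=mode) == pytest.approx(
                brute_affinity(W, ca, cb, mode=mode), abs=1e-12
            )

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            cluster_affinity(np.zeros((4, 4)), [0, 1], [1, 2])


class TestAhc:
    def test_two_leaves_single_merge(self):
        W = np.array([[0, 2.0], [3.0, 0]])
        dend = ahc_build(W)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(6.0)  # W12 * W21

    def test_example_first_merge_is_bonded_pair(self, cattle_W):
        dend = ahc_build(cattle_W)
        left, right = dend.merge_members()[0]
        assert sorted(left + right) == ["10", "8"]
        assert dend.merges[0, 2] == pytest.approx(9.1494)

    def test_merge_count_and_leaf_preservation(self):
        rng = np.random.default_rng(6)
        W = random_W(rng, 8)
        dend = ahc_build(W)
        assert dend.merges.shape == (7, 4)
        final_left, final_right = dend.merge_members()[-1]
        assert sorted(final_left + final_right) == sorted(dend.leaves)
        assert dend.merges[-1, 3] == 8

    def test_sizes_sum_correctly(self):
        rng = np.random.default_rng(7)
        dend = ahc_build(random_W(rng, 6))
        n = 6
        sizes = {i: 1 for i in range(n)}
        for r, (l, rr, _, size) in enumerate(dend.merges):
            expected = sizes[int(l)] + sizes[int(rr)]
            assert size == expected
            sizes[n + r] = expected

    def test_planted_blocks_split_last(self):
        """Two planted groups (small within-products, large between)
        must be the two sides of the final merge."""
        n = 6
        W = np.full((n, n), 5.0)
        groups = [{0, 1, 2}, {3, 4, 5}]
        for g in groups:
            for i in g:
                for j in g:
                    if i != j:
                        W[i, j] = 1.0
        np.fill_diagonal(W, 0)
        dend = ahc_build(W)
        left, right = dend.merge_members()[-1]
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"0", "1", "2"}),
            frozenset({"3", "4", "5"}),
        }

    def test_max_polarity_reverses_first_merge(self, cattle_W):
        dend = ahc_build(cattle_W, polarity="max")
        left, right = dend.merge_members()[0]
        # largest pairwise product involves the most mutually distant pair
        D = cattle_W.to_numpy() * cattle_W.to_numpy().T
        iu = np.triu_indices(10, 1)
        i, j = iu[0][np.argmax(D[iu])], iu[1][np.argmax(D[iu])]
        assert sorted(left + right) == sorted(
            [cattle_W.index[i], cattle_W.index[j]]
        )


class TestNewick:
    def test_two_leaf_shape(self):
        W = np.array([[0, 2.0], [3.0, 0]])
        dend = ahc_build(W)
        s = dendrogram_to_newick(dend)
        assert s == "(0:3,1:3);"  # height 6 -> level 3 each side

    def test_example_leaves_once_each(self, cattle_W, tmp_path):
        dend = ahc_build(cattle_W)
        path = tmp_path / "t.nwk"
        dendrogram_to_newick(dend, path)
        import dendropy

        tree = dendropy.Tree.get(path=str(path), schema="newick")
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert leaves == sorted(cattle_W.index)

    def test_roundtrip_topology(self):
        rng = np.random.default_rng(8)
        W = random_W(rng, 7)
        dend = ahc_build(W)
        import dendropy

        tree = dendropy.Tree.get(
            data=dendrogram_to_newick(dend), schema="newick"
        )
        # every recorded merge corresponds to a clade in the parsed tree
        clades = {
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in tree.preorder_node_iter()
        }
        for left, right in dend.merge_members():
            assert frozenset(left + right) in clades
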