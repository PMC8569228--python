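"""Identity distances, neighbour joining, bootstrap, midpoint rooting."""

import math

import dendropy
import numpy as np
import pytest

from evasinclass.align import MSA
from evasinclass.tree import (DistanceMatrix, bootstrap_support,
                              identity_distance, midpoint_root,
                              neighbor_joining, read_newick,
                              tree_bipartitions, write_newick)

from conftest import leaf_distances, random_binary_tree


def nj_path_distances(tree):
    return leaf_distances(tree)


class TestIdentityDistance:
    def test_identical_rows_zero(self):
        d = identity_distance(MSA(["a", "b"], ["ACDE", "ACDE"]))
        assert d.values[0, 1] == 0.0

    def test_single_mismatch(self):
        d = identity_distance(MSA(["a", "b"], ["ACDE", "ACDF"]))
        assert d.values[0, 1] == pytest.approx(math.sqrt(1 - 3 / 4))

    def test_pairwise_deletion_skips_gap_columns(self):
        d = identity_distance(MSA(["a", "b"], ["AC-E", "ACDE"]))
        assert d.values[0, 1] == 0.0  # 3 compared, 3 matched

    def test_complete_deletion_option(self):
        msa = MSA(["a", "b", "c"], ["AC-E", "ACDE", "GCDE"])
        d = identity_distance(msa, deletion="complete")
        # only columns 1,2,4 survive; a vs c differ at column 1 of 3
        assert d.values[0, 2] == pytest.approx(math.sqrt(1 - 2 / 3))

    def test_disjoint_rows_warn_distance_one(self):
        msa = MSA(["a", "b"], ["AC--", "--DE"])
        with pytest.warns(UserWarning, match="no comparable"):
            d = identity_distance(msa)
        assert d.values[0, 1] == 1.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            identity_distance(MSA(["a"], ["ACDE"]))

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["t1", "t2", "t3"],
                           np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float))
        tree = neighbor_joining(D)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == {"t1": 2.0, "t2": 3.0, "t3": 7.0}

    def test_additive_four_taxon_matrix(self):
        ids = ["A", "B", "C", "D"]
        V = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                      [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids, V))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}  # AB|CD
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0}
        paths = nj_path_distances(tree)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert paths[(a, b)] == pytest.approx(V[ids.index(a), ids.index(b)])

    def test_star_matrix_zero_internal_edge(self):
        n = 5
        V = np.ones((n, n)) - np.eye(n)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], V))
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node is not tree.seed_node:
                assert node.edge.length == pytest.approx(0.0)

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"],
                                               np.array([[0, 6], [6, 0]], float)))
        paths = nj_path_distances(tree)
        assert paths[("a", "b")] == pytest.approx(6.0)

    def test_recovers_random_additive_trees(self, rng):
        """Path lengths and topology reproduce random additive inputs."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            true_tree = random_binary_tree(rng, n)
            dist = leaf_distances(true_tree)
            ids = sorted({a for a, _ in dist} | {b for _, b in dist})
            V = np.zeros((n, n))
            for (a, b), d in dist.items():
                i, j = ids.index(a), ids.index(b)
                V[i, j] = V[j, i] = d
            est = neighbor_joining(DistanceMatrix(ids, V))
            assert tree_bipartitions(est) == tree_bipartitions(true_tree)
            est_paths = nj_path_distances(est)
            residual = max(abs(est_paths[k] - dist[k]) for k in dist)
            assert residual < 1e-9

    def test_agrees_with_skbio_on_additive_input(self, rng):
        """Cross-check topology against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            n = int(rng.integers(5, 10))
            true_tree = random_binary_tree(rng, n)
            dist = leaf_distances(true_tree)
            ids = sorted({a for a, _ in dist} | {b for _, b in dist})
            V = np.zeros((n, n))
            for (a, b), d in dist.items():
                i, j = ids.index(a), ids.index(b)
                V[i, j] = V[j, i] = d
            ours = neighbor_joining(DistanceMatrix(ids, V))
            theirs = skbio_nj(SkbioDM(V, ids))
            their_bips = set()
            all_leaves = frozenset(ids)
            anchor = min(all_leaves)
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    side = all_leaves - side if anchor in side else side
                    their_bips.add(side)
            assert tree_bipartitions(ours) == their_bips


class TestBootstrap:
    def _signal_msa(self):
        # every column separates {a,b} from {c,d,e}
        return MSA(["a", "b", "c", "d", "e"],
                   ["AAAA", "AAAA", "TTTT", "TTTT", "TTTT"])

    def test_perfect_signal_full_support(self):
        tree, support = bootstrap_support(self._signal_msa(), n_reps=50, seed=4)
        assert support  # non-empty
        assert all(v == 1.0 for v in support.values())

    def test_no_replicates_no_supports(self):
        tree, support = bootstrap_support(self._signal_msa(), n_reps=0, seed=4)
        assert support == {}
        for node in tree.preorder_node_iter():
            assert node.is_leaf() or node.label is None

    def test_same_seed_reproducible(self, rng):
        rows = ["".join(rng.choice(list("ACDEFG"), 30)) for _ in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        _, s1 = bootstrap_support(msa, n_reps=30, seed=99)
        _, s2 = bootstrap_support(msa, n_reps=30, seed=99)
        assert s1 == s2
        _, s3 = bootstrap_support(msa, n_reps=30, seed=100)
        assert s1.keys() == s3.keys()

    def test_supports_are_fractions(self, rng):
        rows = ["".join(rng.choice(list("AC"), 20)) for _ in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        _, support = bootstrap_support(msa, n_reps=40, seed=1)
        assert all(0.0 <= v <= 1.0 for v in support.values())


class TestMidpointRoot:
    def test_two_leaf_edge_split_in_half(self):
        tree = neighbor_joining(DistanceMatrix(["A", "B"],
                                               np.array([[0, 6], [6, 0]], float)))
        rooted = midpoint_root(tree)
        depths = {lf.taxon.label: lf.distance_from_root()
                  for lf in rooted.leaf_node_iter()}
        assert depths == {"A": 3.0, "B": 3.0}

    def test_chain_root_position(self):
        tr = dendropy.Tree.get(data="(A:1,B:5,C:1);", schema="newick")
        tr.is_rooted = False
        rooted = midpoint_root(tr)
        depths = {lf.taxon.label: lf.distance_from_root()
                  for lf in rooted.leaf_node_iter()}
        assert depths["A"] == pytest.approx(3.0)
        assert depths["B"] == pytest.approx(3.0)
        assert depths["C"] == pytest.approx(3.0)

    def test_all_zero_lengths_rejected(self):
        tr = dendropy.Tree.get(data="(A:0,B:0,C:0);", schema="newick")
        tr.is_rooted = False
        with pytest.raises(ValueError, match="midpoint undefined"):
            midpoint_root(tr)

    def test_minimizes_max_depth_on_random_trees(self, rng):
        """Max root-to-leaf depth equals half the tree diameter exactly."""
        for _ in range(100):
            n = int(rng.integers(4, 15))
            tree = random_binary_tree(rng, n)
            diameter = max(leaf_distances(tree).values())
            rooted = midpoint_root(tree)
            assert len(rooted.seed_node.child_nodes()) == 2
            max_depth = max(lf.distance_from_root()
                            for lf in rooted.leaf_node_iter())
            assert max_depth == pytest.approx(diameter / 2, abs=1e-9)

    def test_leaf_set_preserved(self, rng):
        tree = random_binary_tree(rng, 8)
        before = {lf.taxon.label for lf in tree.leaf_node_iter()}
        rooted = midpoint_root(tree)
        assert {lf.taxon.label for lf in rooted.leaf_node_iter()} == before


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, rng):
        rows = ["".join(rng.choice(list("ACDEFGHIK"), 40)) for _ in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        tree, support = bootstrap_support(msa, n_reps=20, seed=7)
        rooted = midpoint_root(tree, support)
        text = write_newick(rooted)
        back = read_newick(text)
        back.is_rooted = True
        assert tree_bipartitions(back) == tree_bipartitions(rooted)
        orig_lengths = sorted((e.length or 0.0) for e in rooted.edges()
                              if e.length is not None)
        back_lengths = sorted((e.length or 0.0) for e in back.edges()
                              if e.length is not None)
        assert np.allclose(orig_lengths, back_lengths)
        orig_labels = sorted(n.label for n in rooted.preorder_node_iter()
                             if n.label is not None)
        back_labels = sorted(n.label for n in back.preorder_node_iter()
                             if n.label is not None)
        assert orig_labels == back_labels
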