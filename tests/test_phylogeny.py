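"""Tree construction: distances, NJ recovery, bootstrap, Newick round-trip."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from epitoscan.epitopes import EpitopeCountRow
from epitoscan.phylogeny import (
    PhylogenyError,
    annotate_leaves,
    bipartitions,
    bootstrap_support,
    midpoint_root,
    msa_to_distances,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    write_newick,
)

from conftest import random_sequence


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths (skbio TreeNode)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 2.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.extend([nodes[j], nodes[i]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def evolve_panel(rng, topology_depths, length=60):
    """Two clear clades diverged from one ancestor, for bootstrap tests."""
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    ancestor = rng.choice(residues, size=length)

    def mutate(seq, k):
        out = seq.copy()
        for pos in rng.choice(length, size=k, replace=False):
            out[pos] = residues[int(rng.integers(0, 20))]
        return out

    clade_a = mutate(ancestor, 15)
    clade_b = mutate(ancestor, 15)
    panel = []
    for i in range(3):
        panel.append((f"a{i}", "".join(mutate(clade_a, 3))))
    for i in range(3):
        panel.append((f"b{i}", "".join(mutate(clade_b, 3))))
    return panel


class TestDistances:
    def test_identical_rows_are_zero(self):
        dm = msa_to_distances([("x", "ACDEF"), ("y", "ACDEF")], "p_distance")
        assert dm["x", "y"] == 0.0

    def test_p_distance_direct_count(self):
        dm = msa_to_distances([("x", "AAAAAAAAAA"), ("y", "AAAAAAAAAC")], "p_distance")
        assert dm["x", "y"] == pytest.approx(0.1)

    def test_poisson_correction(self):
        aligned = [("x", "AAAAAAAAAA"), ("y", "AACCAAAAAA")]
        dm = msa_to_distances(aligned, "poisson_corrected")
        assert dm["x", "y"] == pytest.approx(-math.log(1 - 0.2))
        dm0 = msa_to_distances([("x", "AAAA"), ("y", "AAAA")], "poisson_corrected")
        assert dm0["x", "y"] == 0.0

    def test_pairwise_gap_deletion(self):
        # column 2 gapped in y: compared columns are 1,3,4 -> 1 mismatch of 3
        dm = msa_to_distances([("x", "ACDE"), ("y", "A-DQ")], "p_distance")
        assert dm["x", "y"] == pytest.approx(1 / 3)

    def test_all_gap_pair_errors(self):
        with pytest.raises(PhylogenyError, match="comparable"):
            msa_to_distances([("x", "AC--"), ("y", "--DE")], "p_distance")

    def test_saturated_pair_errors_under_poisson(self):
        with pytest.raises(PhylogenyError, match="[Ss]aturated"):
            msa_to_distances([("x", "AAAA"), ("y", "CCCC")], "poisson_corrected")


class TestNeighborJoining:
    def test_recovers_known_quartet_with_exact_lengths(self):
        # ((A:2,B:3):4 joined to C:5, D:6) - an additive matrix
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 5, 11, 12],
                [5, 0, 12, 13],
                [11, 12, 0, 11],
                [12, 13, 11, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(d, ids))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 5.0, "D": 6.0}
        assert bipartitions(tree) == {
            frozenset((frozenset({"A", "B"}), frozenset({"C", "D"})))
        }

    def test_three_taxa_unique_topology(self):
        dm = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float), ["A", "B", "C"])
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        assert bipartitions(tree) == set()

    def test_too_few_taxa_error(self):
        with pytest.raises(PhylogenyError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["A", "B"]))

    def test_star_ties_are_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(d, list("ABCDE"))
        trees = [neighbor_joining(dm) for _ in range(5)]
        first = str(trees[0])
        assert all(str(t) == first for t in trees[1:])

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_recovers_random_additive_trees(self, rng, n_taxa):
        """RF distance 0 to the generating topology on additive matrices."""
        for _ in range(5):
            true_tree = random_additive_tree(rng, n_taxa)
            dm = true_tree.tip_tip_distances()
            recovered = neighbor_joining(DistanceMatrix(dm.data, list(dm.ids)))
            assert robinson_foulds(true_tree, recovered) == 0

    def test_agrees_with_skbio_nj(self, rng):
        from skbio.tree import nj as skbio_nj

        true_tree = random_additive_tree(rng, 7)
        dm = true_tree.tip_tip_distances()
        dm = DistanceMatrix(dm.data, list(dm.ids))
        assert robinson_foulds(neighbor_joining(dm), skbio_nj(dm)) == 0

    def test_branch_lengths_nonnegative_even_on_noisy_input(self, rng):
        d = np.abs(rng.normal(1.0, 0.5, size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(d, list("ABCDEF")))
        assert all(
            (n.length or 0) >= 0 for n in tree.traverse() if n is not tree
        )


class TestBootstrap:
    def test_clean_clades_get_full_support(self, rng):
        panel = evolve_panel(rng, None)
        tree = bootstrap_support(panel, 50, seed=3, model="p_distance")
        split = frozenset(
            (frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"}))
        )
        supports = {
            frozenset((frozenset(t.name for t in n.tips()),
                       frozenset(x.name for x in tree.tips()) - frozenset(t.name for t in n.tips()))): n.support
            for n in tree.non_tips(include_self=False)
            if hasattr(n, "support")
        }
        assert supports[split] == 100.0

    def test_same_seed_identical_supports(self, rng):
        panel = evolve_panel(rng, None)
        t1 = bootstrap_support(panel, 30, seed=9, model="p_distance")
        t2 = bootstrap_support(panel, 30, seed=9, model="p_distance")
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
        assert s1 == s2

    def test_supports_within_sampling_error_across_seeds(self, rng):
        panel = evolve_panel(rng, None)

        def supports(seed):
            tree = bootstrap_support(panel, 500, seed=seed, model="p_distance")
            out = {}
            tips = frozenset(t.name for t in tree.tips())
            for n in tree.non_tips(include_self=False):
                if hasattr(n, "support"):
                    side = frozenset(t.name for t in n.tips())
                    out[frozenset((side, tips - side))] = n.support
            return out

        s_a, s_b = supports(1), supports(2)
        assert s_a.keys() == s_b.keys()
        for split in s_a:
            assert abs(s_a[split] - s_b[split]) <= 10.0  # ~4 sd at n=500

    def test_supports_bounded_and_replicates_validated(self, rng):
        panel = evolve_panel(rng, None)
        tree = bootstrap_support(panel, 20, seed=5, model="p_distance")
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert 0.0 <= n.support <= 100.0
        with pytest.raises(PhylogenyError):
            bootstrap_support(panel, 0, seed=5)
        with pytest.raises(PhylogenyError):
            bootstrap_support([("a", "A"), ("b", "C"), ("c", "A")], 10, seed=5)


class TestNewickRoundTrip:
    def test_lossless_for_topology_lengths_supports(self, rng, tmp_path):
        panel = evolve_panel(rng, None)
        tree = bootstrap_support(panel, 25, seed=7, model="p_distance")
        p1, p2 = tmp_path / "t1.nwk", tmp_path / "t2.nwk"
        write_newick(tree, p1)
        back = read_newick(p1)
        write_newick(back, p2)
        assert p1.read_text() == p2.read_text()
        assert robinson_foulds(tree, back) == 0
        for a, b in zip(tree.postorder(), back.postorder()):
            if a.length is not None:
                assert b.length == pytest.approx(a.length, abs=1e-6)
            assert getattr(a, "support", None) == pytest.approx(
                getattr(b, "support", None) or 0
            ) or getattr(a, "support", None) is None


class TestAnnotation:
    def _rows(self, ids):
        return [
            EpitopeCountRow(sid, i, i + 1, 0, 0, passthrough_linear80=90.0 + i,
                            passthrough_3depi=80.0 + i)
            for i, sid in enumerate(ids)
        ]

    def test_rows_follow_tree_traversal_order(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        table = annotate_leaves(tree, self._rows(["D", "B", "C", "A"]))
        assert list(table.index) == [t.name for t in tree.tips()]
        assert list(table.columns) == [
            "passthrough_linear80", "passthrough_3depi",
            "n_positive", "n_positive_2m", "n_negative", "n_negative_2m",
        ]

    def test_shuffled_input_same_output(self, rng):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
        rows = self._rows(["A", "B", "C"])
        t1 = annotate_leaves(tree, rows)
        order = list(rng.permutation(3))
        t2 = annotate_leaves(tree, [rows[i] for i in order])
        assert t1.equals(t2)

    def test_missing_leaf_errors_with_name(self):
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))
        with pytest.raises(PhylogenyError, match="'C'"):
            annotate_leaves(tree, self._rows(["A", "B"]))

    def test_midpoint_rooting_preserves_tips(self, rng):
        true_tree = random_additive_tree(rng, 6)
        dm = true_tree.tip_tip_distances()
        tree = neighbor_joining(DistanceMatrix(dm.data, list(dm.ids)))
        rooted = midpoint_root(tree)
        assert {t.name for t in rooted.tips()} == {t.name for t in tree.tips()}
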