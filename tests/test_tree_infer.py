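"""Distances, neighbor joining, bootstrap, rooting.

NJ consistency on additive metrics is the main oracle: distances generated
by summing path lengths on a random binary tree must return that exact tree.
scikit-bio's NJ serves as an independent implementation cross-check.
"""

import math

import numpy as np
import pytest

from lgtscreen.core import Bipartition, DataError, Msa
from lgtscreen.tree_infer import (
    DistanceMatrix,
    bootstrap_support,
    correct_distances,
    neighbor_joining,
    nj_tree,
    p_distance,
    poisson_correct,
    root_tree,
)
from lgtscreen.trees import read_newick, tip_distances


class TestPDistance:
    def test_identical_rows(self):
        d = p_distance(Msa([("a", "MKV"), ("b", "MKV")]))
        assert d.d[0, 1] == 0.0

    def test_hand_count(self):
        d = p_distance(Msa([("a", "MKV"), ("b", "MIV")]))
        assert d.d[0, 1] == pytest.approx(1 / 3)

    def test_pairwise_deletion(self):
        d = p_distance(Msa([("a", "M-V"), ("b", "MKV")]))
        assert d.d[0, 1] == 0.0  # 2 comparable columns, both equal

    def test_no_overlap_error_names_pair(self):
        with pytest.raises(DataError, match="'a'.*'b'"):
            p_distance(Msa([("a", "M--"), ("b", "--V")]))


class TestPoissonCorrection:
    def test_zero(self):
        assert poisson_correct(0.0) == 0.0

    def test_closed_form_at_half(self):
        expected = -(19 / 20) * math.log(1 - 10 / 19)
        assert poisson_correct(0.5) == pytest.approx(expected)
        assert poisson_correct(0.5) == pytest.approx(0.70985, abs=5e-5)

    def test_saturation(self):
        assert math.isinf(poisson_correct(0.95))

    def test_matrix_marks_saturated_pairs(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.96], [0.96, 0]]))
        corrected = correct_distances(dm)
        assert corrected.saturated[0, 1]
        with pytest.raises(DataError, match="saturated"):
            neighbor_joining(
                DistanceMatrix(
                    ["a", "b", "c"],
                    np.array([[0, 0.96, 0.1], [0.96, 0, 0.1], [0.1, 0.1, 0]]),
                    np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool),
                )
            )


def _random_additive(rng, n_taxa):
    """A random binary tree and the additive tip-distance matrix it induces."""
    from lgtscreen.trees import Node, PhyloTree

    nodes = [Node(f"t{i:02d}", length=float(rng.uniform(0.1, 1.0))) for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = Node(length=float(rng.uniform(0.1, 1.0)))
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = Node()
    for x in nodes:
        root.add(x)
    tree = PhyloTree(root)
    labels = sorted(tree.tip_labels())
    dist = tip_distances(tree)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = dist[(a, b)]
    return tree, DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # tree ((a:1,b:2):1,c:3,d:4) with c,d joined through the root
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = 7
        d[2, 3] = 7
        tree = neighbor_joining(DistanceMatrix(labels, d))
        dist = tip_distances(tree)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert dist[(a, b)] == pytest.approx(d[labels.index(a), labels.index(b)], abs=1e-9)
        bips = tree.bipartitions()
        assert Bipartition.of({"a", "b"}, labels) in bips

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.label: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_taxa(self):
        with pytest.raises(DataError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]])))

    def test_consistency_on_random_additive_metrics(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 13))
            true_tree, dm = _random_additive(rng, n)
            est = neighbor_joining(dm)
            assert set(est.bipartitions()) == set(true_tree.bipartitions())
            d_est = tip_distances(est)
            d_true = tip_distances(true_tree)
            for pair, d in d_true.items():
                assert d_est[pair] == pytest.approx(d, abs=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        _, dm = _random_additive(rng, 8)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.d, ids=dm.labels))
        all_tips = frozenset(dm.labels)
        their_bips = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                their_bips.add(Bipartition.of(side, all_tips))
        assert set(ours.bipartitions()) == their_bips

    def test_equidistant_ties_deterministic_star(self):
        # equidistant 4 taxa: every join ties; the internal edge estimates to
        # exactly 0 and collapses, leaving a star with tip lengths 1/2 —
        # byte-identical regardless of input label order
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(["d", "c", "b", "a"], d))
        t2 = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], d))
        for t in (t1, t2):
            assert len(t.bipartitions()) == 0  # star
            assert {tip.length for tip in t.tips()} == {0.5}


class TestBootstrap:
    def _msa(self, rng, length=300):
        from lgtscreen.simulate import ScenarioConfig, make_gene_tree, simulate_alignment

        cfg = ScenarioConfig(scenario="transfer", seed=11)
        tree, _ = make_gene_tree(cfg)
        return simulate_alignment(tree, length, seed=11)

    def test_identical_sequences_star(self):
        msa = Msa([(f"s{i}", "MKVLWAAG") for i in range(4)])
        tree = bootstrap_support(msa, replicates=5, seed=0)
        for bip, node in tree.bipartitions().items():
            assert node.support == 0.0 or node.support is None

    def test_single_replicate_supports_binary(self, rng):
        msa = self._msa(rng, length=120)
        tree = bootstrap_support(msa, replicates=1, seed=3)
        sups = {n.support for n in tree.bipartitions().values()}
        assert sups <= {0.0, 100.0}

    def test_determinism(self, rng):
        msa = self._msa(rng, length=120)
        t1 = bootstrap_support(msa, replicates=20, seed=42)
        t2 = bootstrap_support(msa, replicates=20, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_bounded_and_on_base_edges_only(self, rng):
        msa = self._msa(rng, length=120)
        tree = bootstrap_support(msa, replicates=20, seed=7)
        for node in tree.bipartitions().values():
            assert node.support is not None and 0 <= node.support <= 100

    def test_long_internal_branch_high_support(self):
        # two tight 3-tip clusters separated by a long internal edge
        nwk = "((a:0.05,(b:0.05,c:0.05):0.05):1.0,(d:0.05,(e:0.05,f:0.05):0.05):1.0);"
        from lgtscreen.simulate import simulate_alignment

        tree = read_newick(nwk)
        msa = simulate_alignment(tree, 500, seed=9)
        bt = bootstrap_support(msa, replicates=100, seed=9)
        bip = Bipartition.of({"a", "b", "c"}, list("abcdef"))
        assert bt.bipartitions()[bip].support >= 90


class TestRooting:
    def test_outgroup_rooting(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rooted = root_tree(t, {"c", "d"})
        clades = rooted.clades()
        assert frozenset({"c", "d"}) in clades
        assert frozenset({"a", "b"}) in clades

    def test_nonmonophyletic_outgroup_error(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(DataError, match="not monophyletic"):
            root_tree(t, {"a", "c"})

    def test_midpoint_on_chain(self):
        # diameter path a—c has length 5; midpoint sits 2.5 from each
        t = read_newick("(a:1,b:1,c:4);")
        rooted = root_tree(t, "midpoint")
        d = tip_distances(rooted)
        assert d[("a", "c")] == pytest.approx(5.0)
        depths = {}
        for tip in rooted.tips():
            depth, n = 0.0, tip
            while n.parent is not None:
                depth += n.length
                n = n.parent
            depths[tip.label] = depth
        assert depths["c"] == pytest.approx(2.5)
        assert depths["a"] == pytest.approx(2.5)

    def test_midpoint_matches_outgroup_on_balanced_tree(self):
        t = read_newick("((a:1,b:1):2,(c:1,d:1):2);")
        r = root_tree(t, "midpoint")
        assert frozenset({"a", "b"}) in r.clades()
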