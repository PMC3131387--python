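"""Donor-lineage screen: monophyly, sister groups, ranking, classification.

The monophyly/sister/support extraction is validated against an independent
oracle that re-derives every bipartition with dendropy.
"""

import dendropy
import numpy as np
import pytest

from lgtscreen.core import Bipartition, DataError, Domain, TaxonRecord
from lgtscreen.screen import (
    Category,
    ScreenConfig,
    assign_groups,
    clade_support,
    classify_origin,
    donor_rank,
    eukaryote_monophyly,
    results_to_tsv,
    screen_batch,
    screen_tree,
    sister_group,
)
from lgtscreen.tree_infer import root_tree
from lgtscreen.trees import read_newick


def _taxa(**kwargs) -> dict[str, TaxonRecord]:
    """Build tip-label -> TaxonRecord from label: (domain, group) pairs."""
    out = {}
    for label, (domain, group) in kwargs.items():
        out[label] = TaxonRecord(label, label, domain, group)
    return out


E, B, A = Domain.EUKARYOTA, Domain.BACTERIA, Domain.ARCHAEA


@pytest.fixture
def five_group_tips():
    return _taxa(
        e1=(E, "Eukaryota"), e2=(E, "Eukaryota"),
        m1=(B, "Myxococcales"), m2=(B, "Myxococcales"),
        p1=(B, "Alphaproteobacteria"), p2=(B, "Alphaproteobacteria"),
        a1=(A, "Archaea"), a2=(A, "Archaea"),
    )


class TestAssignGroups:
    def test_prefix_convention(self, toy_taxonomy):
        t = read_newick("((MYX01|1,HSAP|2),(ARC01|3,ARC02|4));")
        toy_taxonomy["HSAP"] = TaxonRecord("HSAP", "HSAP", E, "Metazoa")
        mapping = assign_groups(t, toy_taxonomy)
        assert mapping["MYX01|1"].group == "Myxococcales"
        assert mapping["HSAP|2"].group == "Metazoa"

    def test_unmapped_tip_listed(self, toy_taxonomy):
        t = read_newick("((MYX01|1,NOPE|2),(ARC01|3,ARC02|4));")
        with pytest.raises(DataError, match="NOPE"):
            assign_groups(t, toy_taxonomy)


class TestMonophyly:
    def test_monophyletic_unrooted(self, five_group_tips):
        t = read_newick("((e1,e2),(m1,m2),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        mono, clades = eukaryote_monophyly(t, tips)
        assert mono and clades == [frozenset({"e1", "e2"})]

    def test_scattered_eukaryotes(self, five_group_tips):
        t = read_newick("((e1,m1),(e2,m2),a1);")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        mono, clades = eukaryote_monophyly(t, tips)
        assert not mono
        assert set(clades) == {frozenset({"e1"}), frozenset({"e2"})}

    def test_no_eukaryotes_error(self, five_group_tips):
        t = read_newick("((m1,m2),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        with pytest.raises(DataError):
            eukaryote_monophyly(t, tips)

    def test_agrees_with_dendropy_oracle_on_random_trees(self, rng):
        for rep in range(200):
            n = int(rng.integers(6, 13))
            tips, newick = _random_labeled_tree(rng, n)
            tree = read_newick(newick)
            mono, _ = eukaryote_monophyly(tree, tips)
            assert mono == _oracle_monophyly(newick, tips)


def _random_labeled_tree(rng, n):
    """Random binary newick over n tips with random domain/group labels."""
    groups = [
        (E, "Eukaryota"), (B, "Myxococcales"), (B, "Alphaproteobacteria"),
        (B, "OtherBacteria"), (A, "Archaea"),
    ]
    labels = [f"t{i:02d}" for i in range(n)]
    # at least one eukaryote and two prokaryotes
    assignment = {}
    assignment[labels[0]] = groups[0]
    assignment[labels[1]] = groups[1]
    assignment[labels[2]] = groups[2]
    for lbl in labels[3:]:
        assignment[lbl] = groups[int(rng.integers(0, len(groups)))]
    tips = {l: TaxonRecord(l, l, d, g) for l, (d, g) in assignment.items()}
    nodes = [f"{l}:{rng.uniform(0.1, 1):.3f}" for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1):.3f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return tips, f"({','.join(nodes)});"


def _oracle_monophyly(newick, tips) -> bool:
    """Independent check via dendropy's bipartition machinery."""
    t = dendropy.Tree.get(data=newick, schema="newick")
    euk = {l for l, r in tips.items() if r.domain is Domain.EUKARYOTA}
    all_tips = {l.taxon.label for l in t.leaf_node_iter()}
    if euk == all_tips:
        raise AssertionError("degenerate: all tips eukaryotic")
    if len(euk) == 1:
        return True
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if side == euk or (all_tips - side) == euk:
            return True
    return False


class TestSisterAndRank:
    def test_pure_sister(self, five_group_tips):
        t = read_newick("(((e1,e2),(m1,m2)),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        sister, comp = sister_group(t, frozenset({"e1", "e2"}), tips)
        assert sister == frozenset({"m1", "m2"})
        assert comp == {"Myxococcales": 2}

    def test_mixed_sister_purity(self, five_group_tips):
        t = read_newick("(((e1,e2),(m1,p1)),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        _, comp = sister_group(t, frozenset({"e1", "e2"}), tips)
        assert comp == {"Myxococcales": 1, "Alphaproteobacteria": 1}

    def test_whole_tree_clade_error(self, five_group_tips):
        t = read_newick("((e1,e2),(m1,m2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        with pytest.raises(DataError):
            sister_group(t, frozenset(t.tip_labels()), tips)

    def test_rank_order_of_first_appearance(self, five_group_tips):
        t = read_newick("((((e1,e2),(m1,m2)),(p1,p2)),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        rank = donor_rank(t, frozenset({"e1", "e2"}), tips)
        assert rank[:2] == ["Myxococcales", "Alphaproteobacteria"]
        assert rank[2] == "Archaea"

    def test_within_step_tip_count_tie_rule(self):
        tips = _taxa(
            e1=(E, "Eukaryota"),
            m1=(B, "Myxococcales"), m2=(B, "Myxococcales"), f1=(B, "Firmicutes"),
            a1=(A, "Archaea"), a2=(A, "Archaea"),
        )
        t = read_newick("((e1,(m1,(m2,f1))),(a1,a2));")
        rank = donor_rank(t, frozenset({"e1"}), tips)
        # sibling subtree holds 2 myxococcal vs 1 firmicute tips
        assert rank[:2] == ["Myxococcales", "Firmicutes"]

    def test_max_depth_truncates(self, five_group_tips):
        t = read_newick("((((e1,e2),(m1,m2)),(p1,p2)),(a1,a2));")
        tips = {k: v for k, v in five_group_tips.items() if k in t.tip_labels()}
        rank = donor_rank(t, frozenset({"e1", "e2"}), tips, max_depth=1)
        assert rank == ["Myxococcales"]


class TestCladeSupport:
    def test_labeled_edge_value(self):
        t = read_newick("(((e1,e2)90,(m1,m2)85)72,(a1,a2)60);")
        assert clade_support(t, frozenset({"e1", "e2", "m1", "m2"})) == 72.0

    def test_absent_edge(self):
        t = read_newick("(((e1,e2),(m1,m2))72,(a1,a2));")
        assert clade_support(t, frozenset({"e1", "m1"})) is None

    def test_single_tip_absent(self):
        t = read_newick("(((e1,e2),(m1,m2))72,(a1,a2));")
        assert clade_support(t, frozenset({"e1"})) is None


class TestClassify:
    def test_pure_supported(self):
        r = classify_origin(
            "f", True, {"Myxococcales": 2}, ["Myxococcales"], 72.0, ScreenConfig()
        )
        assert r.category is Category.SUPPORTED_DONOR and not r.strong

    def test_pure_but_weak_support(self):
        r = classify_origin(
            "f", True, {"Myxococcales": 2}, ["Myxococcales"], 45.0, ScreenConfig()
        )
        assert r.category is Category.WEAK_DONOR

    def test_patchy_donor_first_in_rank(self):
        comp = {"Myxococcales": 2, "Firmicutes": 3}
        r = classify_origin(
            "f", True, comp, ["Myxococcales", "Firmicutes"], 80.0, ScreenConfig()
        )
        assert r.category is Category.PATCHY_DONOR

    def test_other_origin(self):
        r = classify_origin(
            "f", True, {"Alphaproteobacteria": 3}, ["Alphaproteobacteria"], 90.0,
            ScreenConfig(),
        )
        assert r.category is Category.OTHER_ORIGIN

    def test_strong_flag(self):
        r = classify_origin(
            "f", True, {"Myxococcales": 3}, ["Myxococcales"], 97.0, ScreenConfig()
        )
        assert r.strong

    def test_monotonicity_in_min_support(self):
        for sup in (30.0, 50.0, 70.0, 95.0):
            lo = classify_origin(
                "f", True, {"Myxococcales": 2}, ["Myxococcales"], sup,
                ScreenConfig(min_support=40),
            )
            hi = classify_origin(
                "f", True, {"Myxococcales": 2}, ["Myxococcales"], sup,
                ScreenConfig(min_support=80),
            )
            if hi.category is Category.SUPPORTED_DONOR:
                assert lo.category is Category.SUPPORTED_DONOR


class TestScreenTree:
    def test_transfer_topology_supported(self, five_group_tips):
        nwk = "(((e1:1,e2:1)95:1,(m1:1,m2:1)90:1)85:1,(p1:1,p2:1)80:1,(a1:1,a2:1)75:1);"
        t = read_newick(nwk)
        r = screen_tree("fam", t, five_group_tips)
        assert r.category is Category.SUPPORTED_DONOR
        assert r.donor_purity == 1.0
        assert r.donor_rank[0] == "Myxococcales"

    def test_label_permutation_invariance(self, five_group_tips):
        nwk = "(((e1:1,e2:1)95:1,(m1:1,m2:1)90:1)85:1,(p1:1,p2:1)80:1,(a1:1,a2:1)75:1);"
        perm = {"e1": "zz9", "e2": "qq1", "m1": "mm7", "m2": "bb2",
                "p1": "pp1", "p2": "pp2", "a1": "aa1", "a2": "aa2"}
        renamed = nwk
        for old, new in perm.items():
            renamed = renamed.replace(old, new)
        taxa2 = {
            perm[k]: TaxonRecord(perm[k], perm[k], v.domain, v.group)
            for k, v in five_group_tips.items()
        }
        r1 = screen_tree("fam", read_newick(nwk), five_group_tips)
        r2 = screen_tree("fam", read_newick(renamed), taxa2)
        assert r1.category is r2.category
        assert r1.clade_support == r2.clade_support
        assert r1.donor_purity == r2.donor_purity

    def test_root_robustness_outgroup_vs_midpoint(self, five_group_tips):
        nwk = (
            "(((e1:0.1,e2:0.1)95:0.3,(m1:0.1,m2:0.1)90:0.3)85:0.5,"
            "(p1:0.1,p2:0.1)80:0.5,(a1:0.1,a2:0.1)75:2.0);"
        )
        t = read_newick(nwk)
        r_og = screen_tree("f", t, five_group_tips)
        no_archaea = ScreenConfig(outgroup_domain=Domain.ARCHAEA)
        mid = root_tree(t, "midpoint")
        assert frozenset({"e1", "e2"}) in mid.clades()
        r_og2 = screen_tree("f", t, five_group_tips, no_archaea)
        assert r_og.category is r_og2.category is Category.SUPPORTED_DONOR


class TestBatch:
    def test_counts_match_per_tree(self, five_group_tips):
        good = "(((e1,e2)95,(m1,m2)90)85,(p1,p2)80,(a1,a2)75);"
        vertical = "(((e1,e2)95,(p1,p2)90)85,(m1,m2)80,(a1,a2)75);"
        trees = {
            "t1": read_newick(good),
            "t2": read_newick(good),
            "t3": read_newick(vertical),
        }
        results, summary = screen_batch(trees, five_group_tips)
        cats = {r.family_id: r.category for r in results}
        assert cats["t1"] is Category.SUPPORTED_DONOR
        assert cats["t3"] is Category.OTHER_ORIGIN
        assert summary.category_counts["supported_donor"] == 2
        assert summary.donor_counts["Myxococcales"] == 2

    def test_empty_batch_error(self, five_group_tips):
        with pytest.raises(DataError):
            screen_batch({}, five_group_tips)

    def test_per_tree_errors_recorded_not_raised(self, five_group_tips):
        trees = {
            "ok": read_newick("(((e1,e2)95,(m1,m2)90)85,(p1,p2)80,(a1,a2)75);"),
            "bad": read_newick("((x1,x2),(m1,m2),(a1,a2));"),  # unmapped tips
        }
        results, _ = screen_batch(trees, five_group_tips)
        by_id = {r.family_id: r for r in results}
        assert by_id["bad"].error is not None
        assert by_id["ok"].category is Category.SUPPORTED_DONOR

    def test_tsv_round_shape(self, five_group_tips):
        trees = {"t": read_newick("(((e1,e2)95,(m1,m2)90)85,(p1,p2)80,(a1,a2)75);")}
        results, _ = screen_batch(trees, five_group_tips)
        tsv = results_to_tsv(results)
        assert tsv.splitlines()[0].startswith("family_id\t")
        assert "supported_donor" in tsv
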