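"""Construction-side oracles shared by unit and acceptance tests.

These build random trees *with known structure* (clade sets, sister pairs,
supports, additive distances recorded at construction time) so screen and
inference outputs can be compared against ground truth that never passes
through the code paths under test.
"""

from __future__ import annotations

import numpy as np

from lgtscreen.core import Domain, TaxonRecord
from lgtscreen.tree_infer import DistanceMatrix
from lgtscreen.trees import Node, PhyloTree, tip_distances

GROUPS = [
    (Domain.EUKARYOTA, "Eukaryota"),
    (Domain.BACTERIA, "Myxococcales"),
    (Domain.BACTERIA, "Alphaproteobacteria"),
    (Domain.BACTERIA, "OtherBacteria"),
    (Domain.ARCHAEA, "Archaea"),
]


def random_additive(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths and the additive
    distance matrix its paths induce."""
    nodes = [
        Node(f"t{i:02d}", length=float(rng.uniform(0.1, 1.0))) for i in range(n_taxa)
    ]
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


def random_screen_case(rng: np.random.Generator, n_tips: int):
    """Random rooted binary tree with supports, plus construction-side truth.

    Returns (newick, taxa, clade_supports, sister_map, all_tips) where
    clade_supports maps each non-root clade's tip set to the support written
    on its edge (None for leaves) and sister_map maps each non-root clade to
    its sibling's tip set.
    """
    labels = [f"t{i:02d}" for i in range(n_tips)]
    taxa = {}
    # guarantee ≥1 eukaryote and ≥2 prokaryotes
    for idx, grp in ((0, GROUPS[0]), (1, GROUPS[1]), (2, GROUPS[4])):
        taxa[labels[idx]] = TaxonRecord(labels[idx], labels[idx], grp[0], grp[1])
    for lbl in labels[3:]:
        d, g = GROUPS[int(rng.integers(0, len(GROUPS)))]
        taxa[lbl] = TaxonRecord(lbl, lbl, d, g)

    clade_supports: dict[frozenset, float | None] = {}
    sister_map: dict[frozenset, frozenset] = {}

    def build(members: list[str], is_root: bool) -> tuple[str, frozenset]:
        if len(members) == 1:
            clade_supports[frozenset(members)] = None
            return f"{members[0]}:{rng.uniform(0.1, 1.0):.4f}", frozenset(members)
        k = int(rng.integers(1, len(members)))
        shuffled = list(members)
        rng.shuffle(shuffled)
        left, right = shuffled[:k], shuffled[k:]
        nl, sl = build(left, False)
        nr, sr = build(right, False)
        sister_map[sl] = sr
        sister_map[sr] = sl
        me = frozenset(members)
        if is_root:
            return f"({nl},{nr});", me
        support = int(rng.integers(2, 101))
        clade_supports[me] = float(support)
        return f"({nl},{nr}){support}:{rng.uniform(0.1, 1.0):.4f}", me

    newick, _ = build(labels, True)
    return newick, taxa, clade_supports, sister_map, frozenset(labels)
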