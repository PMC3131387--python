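"""Distance-based tree inference with bootstrap supports.

Pairwise-deletion p-distances, a 20-state Poisson correction, Saitou–Nei
neighbor joining with deterministic tie-breaking, nonparametric bootstrap
supports, and outgroup/midpoint rooting.  This is the in-repo tree engine the
screen consumes; externally built trees (Newick with support labels) are
accepted interchangeably.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import DataError, Msa
from .trees import Node, PhyloTree, reroot_on_edge, unroot

logger = logging.getLogger(__name__)

#: p-distances at or beyond this value cannot be Poisson-corrected (20 states)
SATURATION_P = 19.0 / 20.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)


def _encode(msa: Msa) -> np.ndarray:
    """Rows as uint8 character codes; fast vectorized comparisons."""
    return np.frombuffer(
        "".join(s for _, s in msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(msa.n_rows, msa.length)


def p_distance(msa: Msa) -> DistanceMatrix:
    """Proportion of differing sites over pairwise non-gap columns."""
    X = _encode(msa)
    gap = ord("-")
    ok = X != gap
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        comparable = both.sum(axis=1)
        diffs = ((X[i] != X[i + 1 :]) & both).sum(axis=1)
        zero = comparable == 0
        if np.any(zero):
            j = i + 1 + int(np.nonzero(zero)[0][0])
            raise DataError(
                f"no overlapping non-gap columns between "
                f"{msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        d[i, i + 1 :] = diffs / comparable
    d = d + d.T
    return DistanceMatrix(list(msa.ids), d)


def poisson_correct(p: float) -> float:
    """Multiple-hit correction for amino acids: d = -(19/20)·ln(1 - 20p/19).

    Returns ``inf`` (a saturation mark) at p ≥ 19/20.
    """
    if p < 0:
        raise DataError(f"negative p-distance {p}")
    if p >= SATURATION_P:
        return math.inf
    return -(19.0 / 20.0) * math.log(1.0 - p * 20.0 / 19.0)


def correct_distances(dm: DistanceMatrix) -> DistanceMatrix:
    """Apply the Poisson correction elementwise, marking saturated pairs."""
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - dm.d * 20.0 / 19.0
        corrected = np.where(arg > 0, -(19.0 / 20.0) * np.log(np.maximum(arg, 1e-300)), np.inf)
    np.fill_diagonal(corrected, 0.0)
    saturated = dm.d >= SATURATION_P
    np.fill_diagonal(saturated, False)
    return DistanceMatrix(list(dm.labels), corrected, saturated)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ.  Ties in the Q criterion break by the lexicographically
    smallest (representative-label, representative-label) pair, where a
    cluster is represented by its smallest tip label; negative branch lengths
    clamp to 0.  Returns an unrooted tree (trifurcating root)."""
    n = dm.n
    if n < 3:
        raise DataError(f"neighbor joining needs ≥3 taxa, got {n}")
    if np.any(dm.saturated):
        pairs = np.argwhere(dm.saturated)
        i, j = pairs[0]
        raise DataError(
            f"saturated distance between {dm.labels[i]!r} and {dm.labels[j]!r}; "
            "cannot build a tree"
        )

    D = dm.d.copy()
    nodes = [Node(lbl) for lbl in dm.labels]
    reps = list(dm.labels)  # representative (min) tip label per cluster
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]

        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])

        # distances from the new cluster to every other active cluster
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    # join the last two clusters through an unrooted basal node
    i, j = active
    if reps[j] < reps[i]:
        i, j = j, i
    a, b = nodes[i], nodes[j]
    dij = D[i, j]
    if a.is_leaf and b.is_leaf:
        raise DataError("degenerate 2-cluster state")  # unreachable for n ≥ 3
    if b.is_leaf or (not a.is_leaf and len(a.children) >= len(b.children)):
        root, other = a, b
    else:
        root, other = b, a
    other.length = max(dij, 0.0)
    root.add(other)
    root.length = 0.0
    tree = PhyloTree(root)
    _collapse_zero_edges(tree)
    return tree


def _collapse_zero_edges(tree: PhyloTree, tol: float = 1e-12) -> None:
    """Merge zero-length internal edges into polytomies: an edge whose
    estimated length is 0 carries no grouping signal (identical sequences
    give a star, not an arbitrary resolution)."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if (
                node is not tree.root
                and not node.is_leaf
                and node.length <= tol
            ):
                parent = node.parent
                assert parent is not None
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for k, c in enumerate(node.children):
                    parent.children.insert(idx + k, c)
                    c.parent = parent
                changed = True
                break


def nj_tree(msa: Msa, correction: str = "poisson") -> PhyloTree:
    """Distances from an alignment (p-distance, optionally Poisson-corrected)
    followed by neighbor joining."""
    dm = p_distance(msa)
    if correction == "poisson":
        dm = correct_distances(dm)
    elif correction != "none":
        raise DataError(f"unknown distance correction {correction!r}")
    return neighbor_joining(dm)


def bootstrap_support(
    msa: Msa,
    replicates: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> PhyloTree:
    """NJ tree on the full alignment with supports from column-resampled
    replicates: support = % of usable replicates containing each internal
    bipartition of the base tree.  Degenerate replicates (a pair with no
    comparable columns, or saturation) are skipped and the denominator
    adjusted."""
    if replicates < 1:
        raise DataError("replicates must be ≥ 1")
    base = nj_tree(msa, correction)
    base_bips = base.bipartitions()
    counts = {bip: 0 for bip in base_bips}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, msa.length, size=msa.length)
        rep_msa = msa.select_columns(cols.tolist())
        try:
            rep_tree = nj_tree(rep_msa, correction)
        except DataError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        used += 1
        rep_bips = rep_tree.bipartitions()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in base_bips.items():
        node.support = 100.0 * counts[bip] / used if used else 0.0
    return base


def root_tree(tree: PhyloTree, outgroup: set[str] | str) -> PhyloTree:
    """Root on an outgroup tip set, or at the midpoint of the longest
    tip-to-tip path when ``outgroup == "midpoint"``.  Operates on a copy."""
    tree = tree.copy()
    if len(tree.root.children) == 2:
        unroot(tree)
    if outgroup == "midpoint":
        return _midpoint_root(tree)
    og = frozenset(outgroup)
    all_tips = frozenset(tree.tip_labels())
    missing = og - all_tips
    if missing:
        raise DataError(f"outgroup tips absent from tree: {sorted(missing)}")
    if og == all_tips:
        raise DataError("outgroup cannot be the whole tree")
    below = tree.leaf_sets()
    target = None
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        if side == og or (all_tips - side) == og:
            target = node
            break
    if target is None:
        # the outgroup is not monophyletic: name the clashing split
        best = max(
            (below[id(n)] for n in tree.postorder() if n is not tree.root),
            key=lambda s: len(s & og) - len(s - og),
        )
        raise DataError(
            f"outgroup {sorted(og)} is not monophyletic; closest bipartition "
            f"side is {sorted(best)}"
        )
    return reroot_on_edge(tree, target)


def _midpoint_root(tree: PhyloTree) -> PhyloTree:
    tips = tree.tips()
    if len(tips) < 2:
        raise DataError("midpoint rooting needs ≥2 tips")

    # distances from every node to its farthest descendant tip, then find the
    # global diameter path by combining across each node's children
    far_down: dict[int, tuple[float, Node]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            far_down[id(node)] = (0.0, node)
        else:
            far_down[id(node)] = max(
                ((far_down[id(c)][0] + c.length, far_down[id(c)][1])
                 for c in node.children),
                key=lambda t: t[0],
            )
    best = (-1.0, None, None)  # (diameter, tip_a, tip_b)
    for node in tree.postorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        tops = sorted(
            ((far_down[id(c)][0] + c.length, far_down[id(c)][1]) for c in node.children),
            key=lambda t: -t[0],
        )
        diam = tops[0][0] + tops[1][0]
        if diam > best[0]:
            best = (diam, tops[0][1], tops[1][1])
    diameter, tip_a, tip_b = best
    if diameter <= 0:
        # star-like zero-length tree: root arbitrarily but deterministically
        target = min(tree.root.children, key=lambda c: c.label or "")
        return reroot_on_edge(tree, target, length_from_child=0.0)

    # walk from tip_a toward tip_b accumulating half the diameter
    path = _path_between(tip_a, tip_b)
    half = diameter / 2.0
    acc = 0.0
    for child, up in path:
        edge = child.length
        if acc + edge >= half - 1e-12:
            return reroot_on_edge(
                tree, child, length_from_child=(half - acc) if up else edge - (half - acc)
            )
        acc += edge
    raise AssertionError("midpoint walk overran the path")  # pragma: no cover


def _path_between(a: Node, b: Node) -> list[tuple[Node, bool]]:
    """Edges on the a→b path as (child_end_node, walking_upward) pairs."""
    anc_a: list[Node] = []
    n: Node | None = a
    while n is not None:
        anc_a.append(n)
        n = n.parent
    ids = {id(x): k for k, x in enumerate(anc_a)}
    chain_b: list[Node] = []
    m: Node | None = b
    while id(m) not in ids:  # type: ignore[arg-type]
        chain_b.append(m)  # type: ignore[arg-type]
        m = m.parent  # type: ignore[union-attr]
    meet = ids[id(m)]
    up = [(node, True) for node in anc_a[:meet]]
    down = [(node, False) for node in reversed(chain_b)]
    return up + down
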