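"""Phylogenetic tree structure, Newick I/O, bipartitions, rerooting.

Trees are mutable rooted node structures; "unrooted" trees are carried as a
basal multifurcation and interpreted through their bipartition set.  Internal
node labels on input Newick are read as bootstrap-style supports: numeric
values in [0, 1] are taken as fractions and rescaled to the percent scale,
values in (1, 100] are used as-is.
"""

from __future__ import annotations

from typing import Iterator

from .core import Bipartition, DataError, LgtscreenError


class NewickError(LgtscreenError):
    """Newick syntax error; message carries the character position."""


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        length: float = 0.0,
        support: float | None = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label or ''} {kind}>"


class PhyloTree:
    """A tree rooted at ``root``; degree-3+ root means an unrooted tree."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        labels = [n.label for n in self.tips()]
        if any(l is None for l in labels):
            raise DataError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            raise DataError("tree tip labels are not unique")
        return labels  # type: ignore[return-value]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length, n.support)
            for c in n.children:
                m.add(clone(c))
            return m

        return PhyloTree(clone(self.root))

    # -- bipartitions ------------------------------------------------------

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Tip-label set below each node, keyed by id(node)."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])  # type: ignore[list-item]
            else:
                s: frozenset[str] = frozenset()
                for c in node.children:
                    s |= below[id(c)]
                below[id(node)] = s
        return below

    def bipartitions(self, include_trivial: bool = False) -> dict[Bipartition, Node]:
        """Canonical bipartition -> defining edge's child node.

        Internal edges only unless ``include_trivial``; with a degree-2 root
        the two root edges collapse to one split (the copy carrying a support
        wins the mapping).
        """
        all_tips = frozenset(self.tip_labels())
        below = self.leaf_sets()
        out: dict[Bipartition, Node] = {}
        for node in self.postorder():
            if node is self.root:
                continue
            side = below[id(node)]
            if len(side) == len(all_tips):
                continue
            if node.is_leaf and not include_trivial:
                continue
            bip = Bipartition.of(side, all_tips)
            if bip in out and out[bip].support is not None and node.support is None:
                continue
            out[bip] = node
        return out

    def clades(self) -> dict[frozenset[str], Node]:
        """Tip set below each non-root node (rooted-tree clade view)."""
        below = self.leaf_sets()
        return {below[id(n)]: n for n in self.postorder() if n is not self.root}

    # -- output ------------------------------------------------------------

    def to_newick(self, with_supports: bool = True, with_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if with_supports and node.support is not None:
                    s += _fmt_num(node.support)
                elif node.label:
                    s += node.label
            if with_lengths and node.parent is not None:
                s += ":" + _fmt_num(node.length)
            return s

        return fmt(self.root) + ";"


def _fmt_num(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return format(x, ".10g")


# ---------------------------------------------------------------------------
# Newick parsing


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string; numeric internal labels become supports
    (fractions in [0, 1] rescaled to percent)."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError(f"missing ';' terminator at position {len(s)}")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}") from None
        return 0.0

    def parse_subtree() -> Node:
        nonlocal pos
        if pos >= len(s):
            raise error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            node = Node()
            node.add(parse_subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("unbalanced parentheses: expected ')'")
            pos += 1
            label = parse_label()
            if label:
                support = _parse_support(label)
                if support is not None:
                    node.support = support
                else:
                    node.label = label
            node.length = parse_length()
            return node
        label = parse_label()
        if not label:
            raise error("expected a tip label")
        node = Node(label)
        node.length = parse_length()
        return node

    tree = PhyloTree(parse_subtree())
    if pos != len(s):
        raise NewickError(f"unbalanced parentheses: trailing text at position {pos}")
    tree.root.support = None  # a root label is not an edge support
    tree.root.length = 0.0
    return tree


def _parse_support(label: str) -> float | None:
    try:
        v = float(label)
    except ValueError:
        return None
    if 0.0 <= v <= 1.0:
        return v * 100.0
    if 1.0 < v <= 100.0:
        return v
    raise DataError(f"support value {v} outside [0, 100]")


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Rerooting


def _suppress_unary(node: Node) -> None:
    """Splice out a degree-2 internal node left behind by rerooting."""
    (child,) = node.children
    parent = node.parent
    assert parent is not None
    child.length += node.length
    child.parent = parent
    parent.children[parent.children.index(node)] = child


def reroot_on_edge(
    tree: PhyloTree, child: Node, length_from_child: float | None = None
) -> PhyloTree:
    """Reroot on the edge above ``child``; the edge's support is preserved on
    both resulting root-child edges (same bipartition).  Modifies in place."""
    old_parent = child.parent
    if old_parent is None:
        raise DataError("cannot reroot on the root node")
    edge_len = child.length
    edge_sup = child.support
    if length_from_child is None:
        length_from_child = edge_len / 2.0
    length_from_child = min(max(length_from_child, 0.0), edge_len)

    # chain from old_parent up to the old root
    chain: list[Node] = []
    n: Node | None = old_parent
    while n is not None:
        chain.append(n)
        n = n.parent
    # edge attributes of each chain node before the flip
    attrs = [(n.length, n.support) for n in chain]

    old_parent.children.remove(child)
    new_root = Node()
    new_root.add(child)
    child.length = length_from_child
    child.support = edge_sup
    new_root.add(old_parent)
    old_parent.length = edge_len - length_from_child
    old_parent.support = edge_sup

    # flip the chain: each node becomes a child of its former child
    for i in range(len(chain) - 1):
        upper, lower = chain[i + 1], chain[i]
        upper.children.remove(lower)
        lower.add(upper)
        upper.length, upper.support = attrs[i]

    old_root = chain[-1]
    if len(old_root.children) == 1:
        _suppress_unary(old_root)

    new_root.length = 0.0
    new_root.support = None
    tree.root = new_root
    return tree


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a degree-2 root into a basal multifurcation (in place)."""
    root = tree.root
    if len(root.children) != 2:
        return tree
    a, b = root.children
    keep, fold = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise DataError("cannot unroot a 2-tip tree")
    root.children.remove(keep)
    for c in keep.children:
        root.add(c)
    fold.length += keep.length
    if fold.support is None:
        fold.support = keep.support
    root.children.remove(fold)
    root.children.append(fold)  # keep a stable, deterministic order
    fold.parent = root
    return tree


def tip_distances(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Path-length distance between every tip pair (small trees only)."""
    tips = tree.tips()
    dist: dict[tuple[str, str], float] = {}
    for t in tips:
        # distance from t to every node by walking up then down
        d_up: dict[int, float] = {}
        n: Node | None = t
        acc = 0.0
        while n is not None:
            d_up[id(n)] = acc
            acc += n.length
            n = n.parent
        for u in tips:
            if u.label <= t.label:  # type: ignore[operator]
                continue
            m: Node | None = u
            acc2 = 0.0
            while m is not None and id(m) not in d_up:
                acc2 += m.length
                m = m.parent
            assert m is not None
            d = acc2 + d_up[id(m)]
            dist[(t.label, u.label)] = d  # type: ignore[index]
            dist[(u.label, t.label)] = d  # type: ignore[index]
    return dist
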