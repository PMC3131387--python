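"""Donor-lineage screening of gene trees.

Given a gene tree with bootstrap-style supports and a taxonomy, decide
whether the eukaryotic sequences form a clade, which prokaryotic group is
its sister, how well-supported the combined group is, and classify the
family's inferred origin.  This formalizes the visual tree-inspection step
of sister-clade LGT screens into explicit, threshold-driven rules:

* ``supported_donor``  — eukaryotes monophyletic, sister dominated by the
  candidate donor group (purity ≥ min_sister_purity), combined clade support
  ≥ min_support;
* ``weak_donor``       — same topology but support below threshold or absent;
* ``patchy_donor``     — sister mixed, yet the donor is the first prokaryotic
  group encountered walking rootward from the eukaryote clade;
* ``other_origin``     — some other group passes the supported rule;
* ``unresolved``       — none of the above;
* ``euk_nonmonophyletic`` — eukaryotes scattered and no sub-clade rescues a
  donor call.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .core import DataError, Domain, TaxonRecord, resolve_taxon
from .trees import Node, PhyloTree
from .tree_infer import root_tree


class Category(enum.Enum):
    SUPPORTED_DONOR = "supported_donor"
    WEAK_DONOR = "weak_donor"
    PATCHY_DONOR = "patchy_donor"
    OTHER_ORIGIN = "other_origin"
    UNRESOLVED = "unresolved"
    EUK_NONMONOPHYLETIC = "euk_nonmonophyletic"


#: preference order when several eukaryote sub-clades yield different calls
_CATEGORY_PRIORITY = [
    Category.SUPPORTED_DONOR,
    Category.WEAK_DONOR,
    Category.PATCHY_DONOR,
    Category.OTHER_ORIGIN,
    Category.UNRESOLVED,
    Category.EUK_NONMONOPHYLETIC,
]


@dataclass(frozen=True)
class ScreenConfig:
    donor_group: str = "Myxococcales"
    min_support: float = 50.0
    strong_support: float = 95.0
    min_sister_purity: float = 0.8
    outgroup_domain: Domain = Domain.ARCHAEA
    max_rank_depth: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.min_support <= 100 and 0 <= self.strong_support <= 100):
            raise DataError("support thresholds must be in [0, 100]")
        if not (0 <= self.min_sister_purity <= 1):
            raise DataError("min_sister_purity must be in [0, 1]")


@dataclass
class ScreenResult:
    family_id: str
    euk_monophyletic: bool
    sister_groups: dict[str, int]
    donor_rank: list[str]
    clade_support: float | None
    category: Category
    donor_purity: float = 0.0
    strong: bool = False
    error: str | None = None


# ---------------------------------------------------------------------------


def assign_groups(
    tree: PhyloTree, taxonomy: Mapping[str, TaxonRecord]
) -> dict[str, TaxonRecord]:
    """Resolve every tip to its TaxonRecord; unmapped tips are an error."""
    mapping: dict[str, TaxonRecord] = {}
    unmapped = []
    for label in tree.tip_labels():
        try:
            mapping[label] = resolve_taxon(label, taxonomy)
        except DataError:
            unmapped.append(label)
    if unmapped:
        raise DataError(f"tips with no taxonomy entry: {sorted(unmapped)}")
    return mapping


def eukaryote_monophyly(
    tree: PhyloTree, tip_taxa: Mapping[str, TaxonRecord]
) -> tuple[bool, list[frozenset[str]]]:
    """Is the full eukaryote tip set one side of some bipartition?

    If not, return the inclusion-maximal eukaryote-only bipartition sides,
    each of which is screened separately downstream.
    """
    all_tips = frozenset(tree.tip_labels())
    euk = frozenset(t for t in all_tips if tip_taxa[t].domain is Domain.EUKARYOTA)
    prok = all_tips - euk
    if not euk:
        raise DataError("tree has no eukaryotic tips")
    if len(prok) < 2:
        raise DataError("tree needs at least 2 prokaryotic tips")
    if len(euk) == len(all_tips):
        raise DataError("tree has no prokaryotic tips")

    sides = set()
    below = tree.leaf_sets()
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        if 0 < len(side) < len(all_tips):
            sides.add(side)
            sides.add(all_tips - side)

    if euk in sides or len(euk) == 1:
        return True, [euk]
    euk_only = [s for s in sides if s <= euk]
    maximal = [
        s for s in euk_only if not any(s < t for t in euk_only)
    ]
    return False, sorted(maximal, key=lambda s: (-len(s), tuple(sorted(s))))


def sister_group(
    tree: PhyloTree, clade: frozenset[str], tip_taxa: Mapping[str, TaxonRecord]
) -> tuple[frozenset[str], dict[str, int]]:
    """Sister tip set of a clade in a rooted tree, with its per-group
    composition.  The clade must not be a direct child of the root's parent
    edge (a root child's sister is the other root child)."""
    node = _find_clade(tree, clade)
    parent = node.parent
    if parent is None:
        raise DataError("clade is the whole tree; no sister exists")
    below = tree.leaf_sets()
    sister: frozenset[str] = frozenset()
    for sib in parent.children:
        if sib is not node:
            sister |= below[id(sib)]
    if not sister:
        raise DataError("clade has no sister (unary parent)")
    comp = Counter(tip_taxa[t].group for t in sister)
    return sister, dict(comp)


def _find_clade(tree: PhyloTree, clade: frozenset[str]) -> Node:
    clades = tree.clades()
    if clade in clades:
        return clades[clade]
    all_tips = frozenset(tree.tip_labels())
    if clade == all_tips:
        raise DataError("clade is the whole tree; no sister exists")
    raise DataError(f"tip set {sorted(clade)} is not a clade of the rooted tree")


def donor_rank(
    tree: PhyloTree,
    clade: frozenset[str],
    tip_taxa: Mapping[str, TaxonRecord],
    max_depth: int = 5,
) -> list[str]:
    """Prokaryotic groups in order of first appearance walking rootward from
    the clade; within one step, groups order by descending tip count then
    lexicographically.  Eukaryotic tips never enter the ranking."""
    node = _find_clade(tree, clade)
    below = tree.leaf_sets()
    seen: list[str] = []
    steps = 0
    current = node
    while current.parent is not None and steps < max_depth:
        parent = current.parent
        new_tips: frozenset[str] = frozenset()
        for sib in parent.children:
            if sib is not current:
                new_tips |= below[id(sib)]
        counts = Counter(
            tip_taxa[t].group
            for t in new_tips
            if tip_taxa[t].domain is not Domain.EUKARYOTA
        )
        for group, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if group not in seen:
                seen.append(group)
        current = parent
        steps += 1
    return seen


def clade_support(tree: PhyloTree, tipset: frozenset[str]) -> float | None:
    """Support of the internal edge splitting ``tipset`` from the rest, or
    None when no such edge exists."""
    if not tipset:
        raise DataError("empty tip set")
    all_tips = frozenset(tree.tip_labels())
    if tipset == all_tips:
        raise DataError("tip set equals the whole tree")
    if len(tipset) == 1 or len(all_tips - tipset) == 1:
        return None  # pendant edge, not an internal bipartition
    below = tree.leaf_sets()
    # prefer the edge whose child side equals the tipset itself (a degree-2
    # root can carry distinct labels on its two edges of the same split)
    complement_hit = None
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = below[id(node)]
        if side == tipset:
            return node.support
        if side == all_tips - tipset:
            complement_hit = node
    return None if complement_hit is None else complement_hit.support


def classify_origin(
    family_id: str,
    monophyletic: bool,
    sister_comp: dict[str, int],
    rank: list[str],
    support: float | None,
    cfg: ScreenConfig,
) -> ScreenResult:
    total = sum(sister_comp.values())
    purity = {g: c / total for g, c in sister_comp.items()} if total else {}
    donor_purity = purity.get(cfg.donor_group, 0.0)

    if donor_purity >= cfg.min_sister_purity:
        if support is not None and support >= cfg.min_support:
            cat = Category.SUPPORTED_DONOR
        else:
            cat = Category.WEAK_DONOR
    elif any(
        g != cfg.donor_group
        and p >= cfg.min_sister_purity
        and support is not None
        and support >= cfg.min_support
        for g, p in purity.items()
    ):
        cat = Category.OTHER_ORIGIN
    elif rank and rank[0] == cfg.donor_group:
        cat = Category.PATCHY_DONOR
    else:
        cat = Category.UNRESOLVED

    return ScreenResult(
        family_id=family_id,
        euk_monophyletic=monophyletic,
        sister_groups=dict(sister_comp),
        donor_rank=list(rank),
        clade_support=support,
        category=cat,
        donor_purity=donor_purity,
        strong=support is not None and support >= cfg.strong_support,
    )


def screen_tree(
    family_id: str,
    tree: PhyloTree,
    taxonomy: Mapping[str, TaxonRecord],
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Run the full per-family screen: taxon assignment, rooting (outgroup
    domain if present and monophyletic, else midpoint), monophyly test,
    sister composition, donor ranking, support extraction, classification."""
    cfg = cfg or ScreenConfig()
    tip_taxa = assign_groups(tree, taxonomy)
    monophyletic, euk_clades = eukaryote_monophyly(tree, tip_taxa)

    outgroup = frozenset(
        t for t, rec in tip_taxa.items() if rec.domain is cfg.outgroup_domain
    )
    rooted = None
    if outgroup and len(outgroup) < len(tip_taxa):
        try:
            rooted = root_tree(tree, set(outgroup))
        except DataError:
            rooted = None
    if rooted is None:
        rooted = root_tree(tree, "midpoint")

    results = []
    for clade in euk_clades:
        try:
            results.append(
                _screen_clade(family_id, rooted, clade, tip_taxa, monophyletic, cfg)
            )
        except DataError:
            continue
    if not results:
        return ScreenResult(
            family_id, monophyletic, {}, [], None,
            Category.EUK_NONMONOPHYLETIC if not monophyletic else Category.UNRESOLVED,
        )
    results.sort(key=lambda r: _CATEGORY_PRIORITY.index(r.category))
    best = results[0]
    if not monophyletic and best.category is Category.UNRESOLVED:
        best.category = Category.EUK_NONMONOPHYLETIC
    return best


def _screen_clade(
    family_id: str,
    rooted: PhyloTree,
    clade: frozenset[str],
    tip_taxa: Mapping[str, TaxonRecord],
    monophyletic: bool,
    cfg: ScreenConfig,
) -> ScreenResult:
    clades = rooted.clades()
    if clade not in clades:
        # rooting may have placed the root inside the clade; skip such cases
        raise DataError(f"eukaryote tip set not a clade after rooting: {sorted(clade)}")
    sister, comp = sister_group(rooted, clade, tip_taxa)
    rank = donor_rank(rooted, clade, tip_taxa, cfg.max_rank_depth)
    # support of the combined eukaryote + dominant-donor-sister group
    support = clade_support(rooted, clade | sister)
    return classify_origin(family_id, monophyletic, comp, rank, support, cfg)


@dataclass
class ScreenSummary:
    n_trees: int
    category_counts: dict[str, int] = field(default_factory=dict)
    donor_counts: dict[str, int] = field(default_factory=dict)


def screen_batch(
    trees: Mapping[str, PhyloTree],
    taxonomy: Mapping[str, TaxonRecord],
    cfg: ScreenConfig | None = None,
) -> tuple[list[ScreenResult], ScreenSummary]:
    """Screen a batch of gene trees; per-tree errors are recorded on the
    result rather than aborting the batch.  The summary tallies categories
    and, for donor-positive families, the first-ranked group."""
    if not trees:
        raise DataError("empty tree batch")
    cfg = cfg or ScreenConfig()
    results = []
    for fam_id in sorted(trees):
        try:
            results.append(screen_tree(fam_id, trees[fam_id], taxonomy, cfg))
        except DataError as exc:
            results.append(
                ScreenResult(
                    fam_id, False, {}, [], None, Category.UNRESOLVED, error=str(exc)
                )
            )
    cat_counts = Counter(r.category.value for r in results)
    donor_counts = Counter(r.donor_rank[0] for r in results if r.donor_rank)
    summary = ScreenSummary(
        n_trees=len(results),
        category_counts=dict(cat_counts),
        donor_counts=dict(donor_counts),
    )
    return results, summary


def results_to_tsv(results: list[ScreenResult]) -> str:
    header = (
        "family_id\tcategory\teuk_monophyletic\tdonor_purity\tclade_support"
        "\tstrong\tsister_groups\tdonor_rank\terror"
    )
    lines = [header]
    for r in results:
        comp = ",".join(f"{g}:{c}" for g, c in sorted(r.sister_groups.items()))
        sup = "" if r.clade_support is None else f"{r.clade_support:.1f}"
        lines.append(
            f"{r.family_id}\t{r.category.value}\t{int(r.euk_monophyletic)}"
            f"\t{r.donor_purity:.4f}\t{sup}\t{int(r.strong)}"
            f"\t{comp}\t{','.join(r.donor_rank)}\t{r.error or ''}"
        )
    return "\n".join(lines) + "\n"
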