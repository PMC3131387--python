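"""Synthetic benchmark data with known gene-history truth.

Generates labeled multi-group datasets at toy scale: a prokaryote backbone
(archaea as outgroup, then other bacteria, α-proteobacteria and the
candidate donor order as monophyletic groups), a eukaryote clade attached
either vertically (sister to the α-proteobacteria — the endosymbiotic
expectation) or by transfer (grafted inside the donor clade), protein
alignments evolved along the tree under the WAG model, and CDS whose codon
composition mixes donor and host profiles to a stated amelioration degree.

Every random draw flows through one seeded numpy Generator per family, with
categorical sampling via inverse-CDF on the uniform stream, so outputs are
reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .composition import CodonProfile, profile_from_gc
from .core import (
    DataError,
    Domain,
    Msa,
    SeqKind,
    SequenceRecord,
    TaxonRecord,
    write_alignment_fasta,
    write_fasta,
    write_taxonomy,
)
from .trees import Node, PhyloTree

WAG_SHA256 = "4508113886bed81726006df035dda68c20e971ca3f209ca6cc669f214ef66a24"

_GROUP_PREFIX = {
    "Archaea": "ARC",
    "Alphaproteobacteria": "ALP",
    "Myxococcales": "MYX",
    "OtherBacteria": "OTH",
    "Eukaryota": "EUK",
}

_GROUP_DOMAIN = {
    "Archaea": Domain.ARCHAEA,
    "Alphaproteobacteria": Domain.BACTERIA,
    "Myxococcales": Domain.BACTERIA,
    "OtherBacteria": Domain.BACTERIA,
    "Eukaryota": Domain.EUKARYOTA,
}


@dataclass
class ScenarioConfig:
    """One simulated gene family's generating conditions."""

    groups: dict[str, int] = field(
        default_factory=lambda: {
            "Archaea": 4,
            "Alphaproteobacteria": 6,
            "Myxococcales": 6,
            "OtherBacteria": 8,
            "Eukaryota": 8,
        }
    )
    scenario: str = "transfer"  # or "vertical"
    donor_group: str = "Myxococcales"
    length: int = 300  # amino acids
    branch_scale: float = 1.0
    gamma_shape: float | None = None
    #: when set, the edge subtending the grafted eukaryote+donor-subtree
    #: clade gets this length (pre-scale) instead of inheriting half of the
    #: split donor edge — the "long graft edge" condition for support tests
    graft_edge_length: float | None = None
    seed: int = 0
    # CDS composition: donor/host genome G+C and amelioration degree
    donor_gc: float = 0.72
    host_gc: float = 0.45
    cds_alpha: float = 1.0
    cds_length_codons: int = 500

    def __post_init__(self) -> None:
        if len(self.groups) < 3:
            raise DataError("need ≥3 groups")
        if any(c < 1 for c in self.groups.values()):
            raise DataError("all group tip counts must be ≥1")
        if self.length < 50:
            raise DataError("sequence length must be ≥50")
        if self.scenario not in ("vertical", "transfer"):
            raise DataError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "transfer" and self.donor_group not in self.groups:
            raise DataError(f"donor group {self.donor_group!r} not configured")
        if not (0.0 <= self.cds_alpha <= 1.0):
            raise DataError("cds_alpha must be in [0, 1]")


@dataclass
class TruthRecord:
    family_id: str
    scenario: str
    origin_group: str  # true sister group of the eukaryote clade
    graft_sister_tips: list[str]
    seed: int
    cds_alpha: float


def taxon_labels(group: str, count: int) -> list[str]:
    prefix = _GROUP_PREFIX.get(group, group[:3].upper())
    return [f"{prefix}{i + 1:02d}" for i in range(count)]


def make_taxonomy(cfg: ScenarioConfig, rng: np.random.Generator) -> list[TaxonRecord]:
    """Taxon table for the configured groups.  Donor-group genomes get a high
    G+C (the 0.69–0.74 band typical of large-genome donors), eukaryote hosts
    the host_gc, the rest an intermediate value."""
    records = []
    for group, count in cfg.groups.items():
        domain = _GROUP_DOMAIN.get(group, Domain.BACTERIA)
        for label in taxon_labels(group, count):
            if group == cfg.donor_group:
                gc = cfg.donor_gc + rng.uniform(-0.015, 0.015)
            elif domain is Domain.EUKARYOTA:
                gc = cfg.host_gc + rng.uniform(-0.01, 0.01)
            else:
                gc = 0.50 + rng.uniform(-0.05, 0.05)
            records.append(TaxonRecord(label, label, domain, group, round(gc, 4)))
    return records


# ---------------------------------------------------------------------------
# Gene-tree generation


def _random_subtree(
    labels: list[str], rng: np.random.Generator, scale: float
) -> Node:
    """Random coalescent-like binary subtree over the labels (joined in a
    seeded random order); tip and internal branch lengths from fixed bands."""
    nodes = []
    for lbl in labels:
        n = Node(lbl)
        n.length = rng.uniform(0.05, 0.15) * scale
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.length = rng.uniform(0.02, 0.10) * scale
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def make_gene_tree(
    cfg: ScenarioConfig, family_id: str | None = None
) -> tuple[PhyloTree, TruthRecord]:
    """Backbone with each group monophyletic; the eukaryote clade is either
    sister to the α-proteobacteria (vertical) or grafted onto an edge inside
    the donor clade (transfer)."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.branch_scale
    fam = family_id or f"fam{cfg.seed:05d}"

    def tips(group: str) -> list[str]:
        return [f"{t}|{fam}" for t in taxon_labels(group, cfg.groups[group])]

    sub = {g: _random_subtree(tips(g), rng, s) for g in cfg.groups}
    for g, node in sub.items():
        node.length = rng.uniform(0.25, 0.40) * s  # group stem

    euk = sub["Eukaryota"]
    euk.length = 0.30 * s  # graft / stem edge of the eukaryote clade

    # groups placed explicitly on the backbone; the rest hang off the
    # bacterial node
    placed = {"Archaea", "Alphaproteobacteria", "Eukaryota"}
    if cfg.scenario == "transfer":
        if cfg.donor_group == "Alphaproteobacteria":
            raise DataError("transfer donor must differ from Alphaproteobacteria")
        placed.add(cfg.donor_group)
    elif "Myxococcales" in cfg.groups:
        placed.add("Myxococcales")

    root = Node()
    root.add(sub["Archaea"])
    bact = Node()
    bact.length = rng.uniform(0.25, 0.40) * s
    root.add(bact)
    for g in cfg.groups:
        if g not in placed:
            bact.add(sub[g])
    inner = Node()
    inner.length = rng.uniform(0.25, 0.40) * s
    bact.add(inner)

    if cfg.scenario == "vertical":
        pair = Node()
        pair.length = rng.uniform(0.05, 0.15) * s
        pair.add(sub["Alphaproteobacteria"])
        pair.add(euk)
        inner.add(pair)
        if "Myxococcales" in cfg.groups:
            inner.add(sub["Myxococcales"])
        origin = "Alphaproteobacteria"
        sister_tips = tips("Alphaproteobacteria")
    else:
        inner.add(sub["Alphaproteobacteria"])
        donor = sub[cfg.donor_group]
        inner.add(donor)
        # graft point: a random edge strictly inside the donor subtree
        candidates = []
        stack = list(donor.children)
        while stack:
            n = stack.pop()
            candidates.append(n)
            stack.extend(n.children)
        idx = int(rng.integers(0, len(candidates)))
        target = candidates[idx]
        graft = Node()
        old_parent = target.parent
        assert old_parent is not None
        half = target.length / 2.0
        graft.length = (
            cfg.graft_edge_length * s if cfg.graft_edge_length is not None else half
        )
        target.length = half
        old_parent.children[old_parent.children.index(target)] = graft
        graft.parent = old_parent
        graft.add(target)
        graft.add(euk)
        origin = cfg.donor_group
        subtree_tips = []
        walk = [target]
        while walk:
            n = walk.pop()
            if n.is_leaf:
                subtree_tips.append(n.label)
            walk.extend(n.children)
        sister_tips = sorted(subtree_tips)

    tree = PhyloTree(root)
    truth = TruthRecord(
        family_id=fam,
        scenario=cfg.scenario,
        origin_group=origin,
        graft_sister_tips=sorted(sister_tips),
        seed=cfg.seed,
        cds_alpha=cfg.cds_alpha,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# Protein sequence simulation (WAG continuous-time Markov model)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model: Q built from exchangeabilities S and
    equilibrium frequencies π, scaled to one expected substitution per site
    per unit branch length."""

    name: str
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,), sums to 1

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        if not np.allclose(S, S.T):
            raise DataError("exchangeability matrix must be symmetric")
        if not np.isclose(pi.sum(), 1.0, atol=1e-9) or np.any(pi <= 0):
            raise DataError("frequencies must be positive and sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        # symmetrized eigendecomposition for fast exp(Q t)
        sqrt_pi = np.sqrt(pi)
        A = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
        self._vals = vals
        self._U = vecs / sqrt_pi[:, None]
        self._W = vecs.T * sqrt_pi[None, :]
        self.exchangeabilities = S
        self.frequencies = pi

    def transition(self, t: float) -> np.ndarray:
        P = (self._U * np.exp(self._vals * t)[None, :]) @ self._W
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("transition matrix rows do not sum to 1")
        return P

    def site_transition_rows(self, states: np.ndarray, t_sites: np.ndarray) -> np.ndarray:
        """Per-site transition probability rows for site-specific times."""
        E = np.exp(np.outer(t_sites, self._vals))  # (L, 20)
        rows = (self._U[states] * E) @ self._W
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        return rows


def load_wag() -> SubstitutionModel:
    """Bundled Whelan–Goldman (WAG) model, checksum-verified."""
    data = resources.files("lgtscreen.data").joinpath("wag.txt").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != WAG_SHA256:
        raise DataError(f"WAG data file corrupted (sha256 {digest})")
    lines = [l for l in data.decode().splitlines() if l and not l.startswith("#")]
    assert lines[0].split()[1] == AMINO_ACIDS
    i_ex = lines.index("exchangeabilities")
    i_fr = lines.index("frequencies")
    ex = [float(x) for x in lines[i_ex + 1 : i_fr]]
    fr = np.array([float(x) for x in lines[i_fr + 1 :]])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = ex[k]
            k += 1
    assert k == 190 and len(fr) == 20
    return SubstitutionModel("WAG", S, fr / fr.sum())


def poisson_model() -> SubstitutionModel:
    """Equal-rates fallback: uniform frequencies, equal exchangeabilities."""
    S = np.ones((20, 20)) - np.eye(20)
    return SubstitutionModel("Poisson", S, np.full(20, 0.05))


def _inverse_cdf_sample(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Categorical draw per row of ``probs`` via inverse-CDF on the uniform
    stream (deterministic given the RNG state)."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])
    return (cum < u[:, None]).sum(axis=1).clip(0, probs.shape[1] - 1)


def simulate_alignment(
    tree: PhyloTree,
    length: int,
    model: SubstitutionModel | None = None,
    gamma_shape: float | None = None,
    seed: int = 0,
) -> Msa:
    """Evolve a root sequence drawn from the model equilibrium down the tree:
    sites are independent, each branch applies exp(Q·t·r) with optional
    per-site gamma rate multipliers r (mean 1).  Returns the true alignment
    (indel-free)."""
    model = model or load_wag()
    rng = np.random.default_rng(seed)
    pi = model.frequencies
    rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
        if gamma_shape
        else np.ones(length)
    )
    root_states = _inverse_cdf_sample(rng, np.tile(pi, (length, 1)))
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        t = max(node.length, 0.0)
        if t == 0.0:
            states[id(node)] = parent_states.copy()
            continue
        rows = model.site_transition_rows(parent_states, t * rates)
        states[id(node)] = _inverse_cdf_sample(rng, rows)
    rows_out = []
    for tip in tree.tips():
        seq = "".join(AMINO_ACIDS[s] for s in states[id(tip)])
        rows_out.append((tip.label, seq))
    return Msa(rows_out)


# ---------------------------------------------------------------------------
# CDS simulation


def simulate_cds(
    length_codons: int,
    donor_profile: CodonProfile,
    host_profile: CodonProfile,
    alpha: float,
    seed: int = 0,
    seq_id: str = "cds",
) -> SequenceRecord:
    """Codons drawn i.i.d. from the mixture α·host + (1−α)·donor over sense
    codons (stop codons carry no mass by construction); a terminal TAA stop
    is appended."""
    if not (0.0 <= alpha <= 1.0):
        raise DataError("alpha must be in [0, 1]")
    from .composition import SENSE_CODONS

    mix = alpha * host_profile.codon_freq + (1.0 - alpha) * donor_profile.codon_freq
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)
    idx = _inverse_cdf_sample(rng, np.tile(mix, (length_codons, 1)))
    seq = "".join(SENSE_CODONS[i] for i in idx) + "TAA"
    return SequenceRecord(seq_id, seq, SeqKind.CDS)


# ---------------------------------------------------------------------------
# Dataset builder


def make_dataset(
    out_dir: str | Path,
    n_families: int = 40,
    fraction_transfer: float = 0.5,
    template: ScenarioConfig | None = None,
    seed: int = 0,
    write_cds: bool = True,
) -> Path:
    """Write a complete benchmark dataset: per family a true gene tree
    (Newick), its simulated alignment (FASTA) and eukaryote CDS set, plus the
    taxonomy TSV, the truth table and a manifest of all seeds."""
    if n_families < 1:
        raise DataError("n_families must be ≥1")
    if not (0.0 <= fraction_transfer <= 1.0):
        raise DataError("fraction_transfer must be in [0, 1]")
    template = template or ScenarioConfig()
    out = Path(out_dir)
    (out / "families").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    fam_seeds = master.integers(0, 2**31 - 1, size=n_families)
    n_transfer = round(n_families * fraction_transfer)

    taxonomy = make_taxonomy(template, np.random.default_rng(seed))
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    donor_profile = profile_from_gc(template.donor_gc)
    host_profile = profile_from_gc(template.host_gc)

    truth_lines = ["family_id\tscenario\torigin_group\tcds_alpha\tseed"]
    manifest = {
        "seed": int(seed),
        "n_families": n_families,
        "fraction_transfer": fraction_transfer,
        "template": {
            k: v for k, v in asdict(template).items() if k != "groups"
        } | {"groups": dict(template.groups)},
        "families": [],
    }
    for i in range(n_families):
        scenario = "transfer" if i < n_transfer else "vertical"
        fam_seed = int(fam_seeds[i])
        cfg = ScenarioConfig(
            groups=dict(template.groups),
            scenario=scenario,
            donor_group=template.donor_group,
            length=template.length,
            branch_scale=template.branch_scale,
            gamma_shape=template.gamma_shape,
            seed=fam_seed,
            donor_gc=template.donor_gc,
            host_gc=template.host_gc,
            cds_alpha=template.cds_alpha,
            cds_length_codons=template.cds_length_codons,
        )
        fam_id = f"fam{i:03d}"
        tree, truth = make_gene_tree(cfg, family_id=fam_id)
        msa = simulate_alignment(
            tree, cfg.length, gamma_shape=cfg.gamma_shape, seed=fam_seed
        )
        tree_path = out / "families" / f"{fam_id}.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        write_alignment_fasta(msa, out / "families" / f"{fam_id}.aln.fasta")
        if write_cds:
            alpha = cfg.cds_alpha if scenario == "transfer" else 1.0
            cds_records = [
                simulate_cds(
                    cfg.cds_length_codons,
                    donor_profile,
                    host_profile,
                    alpha,
                    seed=fam_seed + 7 * k + 1,
                    seq_id=f"{t}|{fam_id}",
                )
                for k, t in enumerate(
                    taxon_labels("Eukaryota", cfg.groups.get("Eukaryota", 0))
                )
            ]
            if cds_records:
                write_fasta(cds_records, out / "families" / f"{fam_id}.cds.fasta")
        truth_lines.append(
            f"{fam_id}\t{scenario}\t{truth.origin_group}\t"
            f"{cfg.cds_alpha if scenario == 'transfer' else 1.0}\t{fam_seed}"
        )
        manifest["families"].append(
            {"family_id": fam_id, "scenario": scenario, "seed": fam_seed}
        )
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
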