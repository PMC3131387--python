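"""Compositional lateral-gene-transfer tests.

Recently transferred genes tend to carry the donor genome's nucleotide and
codon-usage signature until amelioration drags them toward the host.  This
module measures that signal three ways: CDS G+C against the genome average,
Karlin's codon-usage bias B (amino-acid-weighted L1 distance between
synonymous codon frequencies, range [0, 2]), and a grid-search amelioration
degree alpha_hat locating the gene's codon usage on the donor→host mixture
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .core import DataError, SequenceRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: sense codons of the standard code, fixed order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: codons grouped by the amino acid they encode
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    SYNONYMOUS_FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

_GC_COUNT = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS], dtype=float)


def gc_content(seq: str | SequenceRecord) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator."""
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    s = s.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise DataError(f"non-nucleotide characters {sorted(bad)}")
    counted = sum(s.count(b) for b in "ACGT")
    if counted == 0:
        raise DataError("sequence has no countable (non-N) bases")
    return (s.count("G") + s.count("C")) / counted


@dataclass
class CodonProfile:
    """Codon usage: full sense-codon distribution with derived amino-acid
    frequencies and within-family synonymous frequencies.

    Synonymous families with zero observations carry the uniform
    distribution so B stays defined (they contribute nothing anyway when
    weighted by an amino-acid frequency of zero).
    """

    codon_freq: np.ndarray  # (61,) over SENSE_CODONS, sums to 1

    def __post_init__(self) -> None:
        self.codon_freq = np.asarray(self.codon_freq, dtype=float)
        if self.codon_freq.shape != (len(SENSE_CODONS),):
            raise DataError(f"codon_freq must have length {len(SENSE_CODONS)}")
        if np.any(self.codon_freq < 0):
            raise DataError("codon frequencies must be nonnegative")
        total = self.codon_freq.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise DataError(f"codon frequencies sum to {total}, not 1")

    @property
    def aa_freq(self) -> dict[str, float]:
        out = {}
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            out[aa] = float(
                sum(self.codon_freq[SENSE_CODONS.index(c)] for c in codons)
            )
        return out

    def synonymous_freq(self, aa: str) -> dict[str, float]:
        codons = SYNONYMOUS_FAMILIES[aa]
        vals = np.array([self.codon_freq[SENSE_CODONS.index(c)] for c in codons])
        total = vals.sum()
        if total == 0:
            vals = np.full(len(codons), 1.0 / len(codons))
        else:
            vals = vals / total
        return dict(zip(codons, vals))

    def expected_gc(self) -> float:
        """Expected per-base G+C of sequences drawn from this profile."""
        return float((self.codon_freq * _GC_COUNT).sum() / 3.0)


def codon_profile(cds: str | SequenceRecord) -> CodonProfile:
    """Codon usage of one CDS.  Length must be divisible by 3; stop codons
    are allowed only terminally (the terminal stop is excluded)."""
    s = (cds.residues if isinstance(cds, SequenceRecord) else cds).upper()
    if len(s) % 3 != 0:
        raise DataError(f"CDS length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts = np.zeros(len(SENSE_CODONS))
    for k, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise DataError(f"internal stop codon {codon} at codon position {k}")
        try:
            counts[SENSE_CODONS.index(codon)] += 1
        except ValueError:
            raise DataError(f"unrecognized codon {codon!r} at position {k}") from None
    if counts.sum() == 0:
        raise DataError("CDS has no sense codons")
    return CodonProfile(counts / counts.sum())


def karlin_bias(gene: CodonProfile, reference: CodonProfile) -> float:
    """Karlin's codon-usage difference B(gene | reference):

    B = Σ_a p_a(gene) · Σ_{codons of a} | f_gene(codon) − f_ref(codon) |

    summed over amino acids observed in the gene; single-codon families
    (Met, Trp) contribute 0.  Range [0, 2].
    """
    p = gene.aa_freq
    b = 0.0
    for aa, pa in p.items():
        if pa == 0.0:
            continue
        fg = gene.synonymous_freq(aa)
        fr = reference.synonymous_freq(aa)
        b += pa * sum(abs(fg[c] - fr[c]) for c in SYNONYMOUS_FAMILIES[aa])
    return b


@dataclass
class CompositionReport:
    gene_id: str
    gc_gene: float
    gc_reference: float
    gc_delta: float
    karlin_b: float
    flags: set[str] = field(default_factory=set)
    alpha_hat: float | None = None


def flag_alien(
    gene_cds: SequenceRecord,
    reference: CodonProfile,
    genome_gc: float,
    gc_delta_max: float = 0.08,
    b_max: float = 0.40,
) -> CompositionReport:
    """Flag a gene as compositionally alien against its resident genome:
    ``gc_deviant`` when |gc_gene − genome_gc| > gc_delta_max, ``codon_deviant``
    when Karlin B > b_max.  All measured values are carried on the report so
    thresholds can be re-applied afterwards."""
    if not (0.0 <= genome_gc <= 1.0):
        raise DataError("genome_gc must be in [0, 1]")
    gc_gene = gc_content(gene_cds)
    profile = codon_profile(gene_cds)
    b = karlin_bias(profile, reference)
    flags = set()
    if abs(gc_gene - genome_gc) > gc_delta_max:
        flags.add("gc_deviant")
    if b > b_max:
        flags.add("codon_deviant")
    return CompositionReport(
        gene_id=gene_cds.seq_id,
        gc_gene=gc_gene,
        gc_reference=genome_gc,
        gc_delta=gc_gene - genome_gc,
        karlin_b=b,
        flags=flags,
    )


def amelioration_scan(
    gene_cds: SequenceRecord | CodonProfile,
    donor: CodonProfile,
    host: CodonProfile,
    grid_step: float = 0.01,
) -> float:
    """Amelioration degree alpha_hat: grid-argmin over α ∈ [0, 1] of the L1
    distance between the gene's codon distribution and the mixture
    α·host + (1−α)·donor.  α=0 means donor-like, α=1 fully ameliorated.

    Requires donor and host to be distinguishable (total variation > 0.05).
    Ties break toward the smaller α."""
    tv = 0.5 * float(np.abs(donor.codon_freq - host.codon_freq).sum())
    if tv <= 0.05:
        raise DataError(
            f"donor and host codon profiles are indistinguishable (TV={tv:.4f})"
        )
    gene = gene_cds if isinstance(gene_cds, CodonProfile) else codon_profile(gene_cds)
    alphas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    mixtures = (
        alphas[:, None] * host.codon_freq[None, :]
        + (1.0 - alphas[:, None]) * donor.codon_freq[None, :]
    )
    l1 = np.abs(mixtures - gene.codon_freq[None, :]).sum(axis=1)
    return float(alphas[int(np.argmin(l1))])


def profile_from_gc(gc_target: float, tol: float = 1e-6) -> CodonProfile:
    """Synthesize a codon profile with a given expected G+C by exponential
    tilting: P(codon) ∝ exp(β·GC(codon)), β solved by bisection.

    High targets shift both synonymous usage and amino-acid composition
    toward G+C-rich codons (Ala/Gly/Pro/Arg), as in real high-G+C genomes;
    any target strictly inside (0, 1) is attainable.
    """
    if not (0.0 < gc_target < 1.0):
        raise DataError("gc_target must be in (0, 1)")

    def expected(beta: float) -> float:
        w = np.exp(beta * _GC_COUNT)
        w /= w.sum()
        return float((w * _GC_COUNT).sum() / 3.0)

    lo, hi = -60.0, 60.0
    if not (expected(lo) < gc_target < expected(hi)):
        raise DataError(f"gc_target {gc_target} outside attainable range")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if expected(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    w = np.exp((lo + hi) / 2 * _GC_COUNT)
    return CodonProfile(w / w.sum())


def composition_report_tsv(reports: list[CompositionReport]) -> str:
    header = "gene_id\tgc_gene\tgc_reference\tgc_delta\tkarlin_b\tflags\talpha_hat"
    lines = [header]
    for r in reports:
        a = "" if r.alpha_hat is None else f"{r.alpha_hat:.2f}"
        lines.append(
            f"{r.gene_id}\t{r.gc_gene:.4f}\t{r.gc_reference:.4f}"
            f"\t{r.gc_delta:+.4f}\t{r.karlin_b:.4f}"
            f"\t{','.join(sorted(r.flags))}\t{a}"
        )
    return "\n".join(lines) + "\n"
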