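"""Shared domain types and file I/O.

Data model for the screen: taxa with group labels and genome composition,
protein/CDS sequence records keyed by the ``taxonid|protid`` convention,
alignments, and tree bipartitions.  FASTA goes through Biopython; the
taxonomy table is a plain 4-column TSV.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class Domain(enum.Enum):
    ARCHAEA = "Archaea"
    BACTERIA = "Bacteria"
    EUKARYOTA = "Eukaryota"


class LgtscreenError(Exception):
    """Base class for all package errors."""


class DataError(LgtscreenError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class TaxonRecord:
    """A sampled genome: domain, group label, optional genome-average G+C."""

    taxon_id: str
    display_name: str
    domain: Domain
    group: str
    genome_gc: float | None = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise DataError("taxon_id must be nonempty")
        if not self.group:
            raise DataError(f"taxon {self.taxon_id!r}: group must be nonempty")
        if self.genome_gc is not None and not (0.0 <= self.genome_gc <= 1.0):
            raise DataError(
                f"taxon {self.taxon_id!r}: genome_gc {self.genome_gc} outside [0, 1]"
            )


class SeqKind(enum.Enum):
    PROTEIN = "protein"
    CDS = "cds"


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    residues: str
    kind: SeqKind = SeqKind.PROTEIN

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"sequence {self.seq_id!r} is empty")

    @property
    def taxon_id(self) -> str:
        """Taxon part of the ``taxonid|protid`` id convention (id itself if unprefixed)."""
        return self.seq_id.split("|", 1)[0]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """Aligned sequences: equal-length gapped rows, gap character '-'."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise DataError("an alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def columns(self) -> list[str]:
        return ["".join(s[i] for _, s in self.rows) for i in range(self.length)]

    def select_columns(self, keep: Iterable[int]) -> "Msa":
        idx = list(keep)
        return Msa([(i, "".join(s[j] for j in idx)) for i, s in self.rows])


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split: canonical orientation stores the lexicographically
    smallest side first so equal splits compare equal."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def of(side: Iterable[str], all_tips: Iterable[str]) -> "Bipartition":
        side_set = frozenset(side)
        other = frozenset(all_tips) - side_set
        if not side_set or not other:
            raise DataError("bipartition sides must both be nonempty")
        a, b = sorted((side_set, other), key=lambda s: tuple(sorted(s)))
        return Bipartition(a, b)

    @property
    def tips(self) -> frozenset[str]:
        return self.side_a | self.side_b


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: SeqKind = SeqKind.PROTEIN) -> list[SequenceRecord]:
    """Read FASTA; the header token before the first whitespace is the seq_id.

    Sequences are uppercased and '.' gaps normalized to '-'.  Duplicate ids
    and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace(".", GAP)
        records.append(SequenceRecord(rec.id, residues, kind))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def read_alignment_fasta(path: str | Path) -> Msa:
    recs = read_fasta(path)
    return Msa([(r.seq_id, r.residues) for r in recs])


def write_alignment_fasta(msa: Msa, path: str | Path) -> None:
    write_fasta([SequenceRecord(i, s) for i, s in msa.rows], path)


# ---------------------------------------------------------------------------
# Taxonomy TSV


def load_taxonomy(path: str | Path) -> dict[str, TaxonRecord]:
    """Load the taxonomy table: tab-separated ``taxon_id  domain  group
    [genome_gc]``, '#' comment lines allowed.

    Sequence ids resolve to taxa through the ``taxonid|protid`` prefix
    convention (see :func:`resolve_taxon`).
    """
    table: dict[str, TaxonRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected ≥3 tab-separated columns")
            taxon_id, domain_s, group = parts[0], parts[1], parts[2]
            try:
                domain = Domain(domain_s)
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: unknown domain {domain_s!r} "
                    f"(expected one of {[d.value for d in Domain]})"
                ) from None
            if not group:
                raise DataError(f"{path}:{lineno}: missing group for {taxon_id!r}")
            gc = None
            if len(parts) > 3 and parts[3] != "":
                gc = float(parts[3])
            if taxon_id in table:
                raise DataError(f"{path}:{lineno}: duplicate taxon_id {taxon_id!r}")
            table[taxon_id] = TaxonRecord(taxon_id, taxon_id, domain, group, gc)
    if not table:
        raise DataError(f"empty taxonomy table {path}")
    return table


def write_taxonomy(taxa: Iterable[TaxonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# taxon_id\tdomain\tgroup\tgenome_gc\n")
        for t in taxa:
            gc = "" if t.genome_gc is None else f"{t.genome_gc:.4f}"
            fh.write(f"{t.taxon_id}\t{t.domain.value}\t{t.group}\t{gc}\n")


def resolve_taxon(label: str, taxonomy: Mapping[str, TaxonRecord]) -> TaxonRecord:
    """Map a tip/sequence label to its TaxonRecord: exact match first, then the
    ``taxonid|protid`` prefix convention."""
    if label in taxonomy:
        return taxonomy[label]
    prefix = label.split("|", 1)[0]
    if prefix in taxonomy:
        return taxonomy[prefix]
    raise DataError(f"label {label!r} resolves to no taxon in the taxonomy table")
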