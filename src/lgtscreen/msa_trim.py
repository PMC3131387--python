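"""Alignment column trimming: gap threshold with a conservation floor.

The gap rule keeps a column when its non-gap fraction is at least the gap
threshold (default 0.25).  A conservation floor (default 0.50) then
guarantees a minimum fraction of the original columns survives: if the gap
rule kept fewer, discarded columns are re-added in order of decreasing
non-gap fraction (leftmost first on ties) until the floor is met.  Kept
columns always appear in their original order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GAP, DataError, Msa


@dataclass
class ColumnMask:
    keep: np.ndarray  # bool per column
    gap_fraction: np.ndarray  # float per column
    coverage_rank: np.ndarray  # column indices, best coverage first

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=float)
        if self.keep.shape != self.gap_fraction.shape:
            raise DataError("mask arrays must have equal length")

    def kept_indices(self) -> list[int]:
        return [int(i) for i in np.nonzero(self.keep)[0]]

    def to_tsv(self) -> str:
        lines = ["column_index\tkept"]
        lines += [f"{i}\t{int(k)}" for i, k in enumerate(self.keep)]
        return "\n".join(lines) + "\n"


def column_stats(msa: Msa) -> ColumnMask:
    """Gap fraction per column plus the coverage ranking used by the floor
    rule (decreasing non-gap fraction, leftmost first on ties)."""
    arr = np.array([list(s) for _, s in msa.rows])
    gap_fraction = (arr == GAP).mean(axis=0)
    # stable sort on gap fraction ascending = coverage descending, ties leftmost
    coverage_rank = np.argsort(gap_fraction, kind="stable")
    return ColumnMask(
        keep=np.zeros(msa.length, dtype=bool),
        gap_fraction=gap_fraction,
        coverage_rank=coverage_rank,
    )


def trim_alignment(
    msa: Msa, gap_threshold: float = 0.25, conserve_floor: float = 0.50
) -> tuple[Msa, ColumnMask]:
    """Apply the gap rule, then enforce the conservation floor (ceil of
    floor × original length columns) by re-adding best-covered columns."""
    if not (0.0 <= gap_threshold <= 1.0):
        raise DataError("gap_threshold must be in [0, 1]")
    if not (0.0 < conserve_floor <= 1.0):
        raise DataError("conserve_floor must be in (0, 1]")
    mask = column_stats(msa)
    nongap = 1.0 - mask.gap_fraction
    keep = nongap >= gap_threshold
    needed = math.ceil(conserve_floor * msa.length)
    if keep.sum() < needed:
        for col in mask.coverage_rank:
            if keep[col]:
                continue
            keep[col] = True
            if keep.sum() >= needed:
                break
    mask.keep = keep
    trimmed = msa.select_columns(mask.kept_indices())
    return trimmed, mask
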