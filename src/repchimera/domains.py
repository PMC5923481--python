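"""Alignment trimming, Walker A anchoring, domain splitting and logo matrices.

A two-domain replication protein carries an N-terminal HUH endonuclease and
a C-terminal superfamily 3 helicase.  The Walker A (P-loop) motif marks the
start of the helicase domain, so the full-length alignment is split at the
first Walker A column: columns ``[0, split)`` form the nuclease block and
``[split, L)`` the helicase block.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections import Counter

import numpy as np

from .io import GAP, AMINO_ACIDS, Alignment, ValidationError

DEFAULT_WALKER_A_PATTERN = "[GA].{4}GK[ST]"


class MotifNotFoundError(ValueError):
    """The Walker A pattern did not match the consensus sequence."""


@dataclasses.dataclass(frozen=True)
class DomainSplit:
    """Nuclease and helicase alignment blocks from one full-length alignment."""

    split_column: int
    nuclease_block: Alignment
    helicase_block: Alignment

    def __post_init__(self) -> None:
        if self.nuclease_block.ids != self.helicase_block.ids:
            raise ValidationError("domain blocks must share record order")

    @property
    def ids(self) -> list[str]:
        return self.nuclease_block.ids


@dataclasses.dataclass(frozen=True)
class LogoMatrix:
    """Position probability matrix with per-column information content.

    ``matrix`` is (columns x 20) over :data:`~repchimera.io.AMINO_ACIDS`
    order; probabilities are over non-gap, non-X residues.  Information is
    ``log2(20) - H`` in bits (no small-sample correction).  Columns that are
    entirely gaps carry zero information and are flagged.
    """

    motif_name: str
    matrix: np.ndarray
    information: np.ndarray
    all_gap: np.ndarray

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1)
        ok = self.all_gap | (np.abs(sums - 1.0) <= 1e-9)
        if not ok.all():
            raise ValidationError("logo columns must sum to 1")


def trim_columns(aln: Alignment, gap_keep_fraction: float = 0.2) -> Alignment:
    """Keep exactly the columns whose non-gap fraction is >= the threshold.

    Mirrors TrimAl's gap-threshold trimming: a column survives when at least
    ``gap_keep_fraction`` of its rows hold a residue.
    """
    n = len(aln)
    keep = [
        j
        for j in range(aln.length)
        if sum(c != GAP for c in aln.column(j)) / n >= gap_keep_fraction
    ]
    if not keep:
        raise ValidationError("trimming removed every column")
    if len(keep) == aln.length:
        return aln
    return aln.take_columns(keep)


def consensus(aln: Alignment) -> str:
    """Column-wise majority consensus.

    The consensus residue is the most frequent non-gap residue, ties broken
    alphabetically; an all-gap column yields ``-``.
    """
    out = []
    for j in range(aln.length):
        counts = Counter(c for c in aln.column(j) if c != GAP)
        if not counts:
            out.append(GAP)
            continue
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(best)
    return "".join(out)


def locate_walker_a(
    aln: Alignment, pattern: str = DEFAULT_WALKER_A_PATTERN
) -> int:
    """Alignment column of the first Walker A residue in the consensus.

    The residue-class pattern (default ``[GA]-x(4)-G-K-[ST]``) is matched
    against the ungapped majority consensus, restricted to its C-terminal
    half because the helicase domain is C-terminal.  The match start is
    mapped back through all-gap columns to an alignment column index.  With
    several matches in the C-terminal half the first is taken and a warning
    emitted.
    """
    cons = consensus(aln)
    columns = [j for j, c in enumerate(cons) if c != GAP]
    ungapped = "".join(cons[j] for j in columns)
    half = len(ungapped) // 2
    matches = [
        m.start() for m in re.finditer(pattern, ungapped) if m.start() >= half
    ]
    if not matches:
        raise MotifNotFoundError(
            f"pattern {pattern!r} not found in the C-terminal half of the "
            f"consensus: {ungapped}"
        )
    if len(matches) > 1:
        warnings.warn(
            f"{len(matches)} Walker A matches in the C-terminal half; "
            "taking the first",
            stacklevel=2,
        )
    return columns[matches[0]]


def split_alignment(aln: Alignment, split_column: int) -> DomainSplit:
    """Partition alignment columns at ``split_column``.

    The split column itself begins the helicase block (the Walker A motif's
    first residue opens the helicase domain).
    """
    if not 0 < split_column < aln.length:
        raise ValidationError(
            f"split column {split_column} out of range (0, {aln.length})"
        )
    nuc = aln.take_columns(range(split_column))
    hel = aln.take_columns(range(split_column, aln.length))
    return DomainSplit(split_column, nuc, hel)


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def logo_matrix(
    aln_block: Alignment,
    window: tuple[int, int] | None = None,
    motif_name: str = "motif",
) -> LogoMatrix:
    """Position probability matrix and information content for a window.

    ``window`` is a half-open column range within the block (default: the
    whole block).  Frequencies are over non-gap residues; ``X`` residues are
    treated as missing.  Information per column is ``log2(20) - H`` bits,
    so a perfectly conserved column scores ``log2(20) ~ 4.32`` bits.
    """
    start, stop = window if window is not None else (0, aln_block.length)
    if not (0 <= start < stop <= aln_block.length):
        raise ValidationError(f"window {start, stop} outside block columns")
    ncols = stop - start
    matrix = np.zeros((ncols, 20))
    info = np.zeros(ncols)
    all_gap = np.zeros(ncols, dtype=bool)
    for k, j in enumerate(range(start, stop)):
        counts = np.zeros(20)
        for c in aln_block.column(j):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        if total == 0:
            all_gap[k] = True
            continue
        p = counts / total
        matrix[k] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info[k] = np.log2(20) - entropy
    if all_gap.any():
        warnings.warn(
            f"{int(all_gap.sum())} all-gap column(s) in logo window; "
            "reported with zero information",
            stacklevel=2,
        )
    return LogoMatrix(motif_name, matrix, info, all_gap)
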