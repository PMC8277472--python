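"""Clade-diagnostic insertion/deletion signatures in a labelled protein MSA.

A lineage that inherited a gene vertically accumulates shared indels with
its relatives; a horizontally acquired copy, descending from a distant
donor, lacks them.  This module scans a clade-labelled alignment for
contiguous column blocks whose gap state (residues present = insertion,
residues absent = deletion) is near-fixed inside a focal clade and near-absent
outside it, and classifies candidate rows by how many of these diagnostic
blocks they carry.  Only gap-state signatures are scanned; residue-identity
signatures would require a substitution model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io import CladeLabelledAlignment, ValidationError


class BlockKind(str, enum.Enum):
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class SignatureBlock:
    """Contiguous alignment columns diagnostic for the focal clade.

    ``prevalence_in`` is the minimum over the block's columns of the
    focal-clade fraction carrying the clade state; ``prevalence_out`` the
    maximum over columns of the outside fraction carrying it — so the
    thresholds used in the scan hold at every column and are re-checkable
    post hoc.
    """

    start: int
    end: int  # half-open
    kind: BlockKind
    prevalence_in: float
    prevalence_out: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty block [{self.start}, {self.end})")


def gap_state_matrix(aln: CladeLabelledAlignment) -> np.ndarray:
    """Binary rows x columns matrix: 1 iff a residue (non-gap) is present."""
    arr = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows])
    return (arr != ord("-")).astype(np.uint8)


def find_diagnostic_blocks(
    aln: CladeLabelledAlignment,
    focal_clade: str,
    p_in: float = 0.9,
    p_out: float = 0.1,
    min_width: int = 2,
) -> list[SignatureBlock]:
    """Maximal runs of columns whose gap state is diagnostic for a clade.

    A column is insertion-diagnostic when residues are present in at least
    ``p_in`` of focal rows and at most ``p_out`` of the others;
    deletion-diagnostic with presence and absence swapped.  Maximal runs of
    the same kind of at least ``min_width`` columns are returned,
    non-overlapping and sorted by start.
    """
    if not p_in > p_out:
        raise ValueError(f"p_in ({p_in}) must exceed p_out ({p_out})")
    focal = np.array([c == focal_clade for c in aln.clades])
    if focal.sum() < 3:
        raise ValidationError(
            f"focal clade {focal_clade!r} has {int(focal.sum())} rows (need >= 3)"
        )
    present = gap_state_matrix(aln).astype(float)
    f_in = present[focal].mean(axis=0)  # focal presence fraction per column
    f_out = present[~focal].mean(axis=0)
    ins = (f_in >= p_in) & (f_out <= p_out)
    dele = ((1 - f_in) >= p_in) & ((1 - f_out) <= p_out)
    state = np.where(ins, 1, np.where(dele, 2, 0))
    blocks: list[SignatureBlock] = []
    n = len(state)
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        if j - i >= min_width:
            if state[i] == 1:
                kind = BlockKind.INSERTION
                prev_in = float(f_in[i:j].min())
                prev_out = float(f_out[i:j].max())
            else:
                kind = BlockKind.DELETION
                prev_in = float((1 - f_in[i:j]).min())
                prev_out = float((1 - f_out[i:j]).max())
            blocks.append(SignatureBlock(i, j, kind, prev_in, prev_out))
        i = j
    return blocks


class Membership(str, enum.Enum):
    MEMBER = "member"
    NON_MEMBER = "non_member"


def _carries(row_present: np.ndarray, block: SignatureBlock) -> bool:
    segment = row_present[block.start : block.end]
    if block.kind is BlockKind.INSERTION:
        return bool(segment.all())
    return bool((~segment.astype(bool)).all())


def classify_membership(
    candidate_row: str,
    blocks: list[SignatureBlock],
    n_columns: int,
    match_fraction: float = 0.8,
) -> Membership:
    """Classify an aligned candidate by its signature profile.

    The candidate must be aligned into the same coordinate system
    (``n_columns``).  It carries a block when it shows the clade state at
    every column of the block; it is a member iff it carries at least
    ``match_fraction`` of the blocks (by count).
    """
    if len(candidate_row) != n_columns:
        raise ValidationError(
            f"candidate length {len(candidate_row)} != alignment width {n_columns}"
        )
    if not blocks:
        raise ValidationError("no diagnostic blocks to classify against")
    present = (
        np.frombuffer(candidate_row.upper().encode("ascii"), dtype=np.uint8) != ord("-")
    )
    carried = sum(_carries(present, b) for b in blocks)
    frac = carried / len(blocks)
    return Membership.MEMBER if frac >= match_fraction else Membership.NON_MEMBER
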