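"""Reference-anchored alignment, per-column information content and
consensus-motif extraction.

Family members are each globally aligned to one reference sequence (BLOSUM62,
affine gaps, end gaps free) and their residues projected onto the reference's
columns; member insertions relative to the reference are discarded.  Column
numbering therefore always equals reference numbering — the same projection a
sequence logo over a chosen reference uses.

Information content follows the standard sequence-logo math: with column
frequencies p_a over observed (non-gap) residues,

    H  = -sum p_a log2 p_a                 (bits)
    IC = log2(20) - H - e_n                (bits)
    letter height_a = p_a * IC

where e_n is the optional small-sample correction (20-1)/(2 ln2 n), off by
default.

The consensus motif renders a reference window as tokens: a residue letter
where the column's majority residue reaches the conservation threshold, a
fixed spacer x_k over a run of k non-conserved columns, or a variable spacer
x_n when at least 5% of members have a projected gap inside the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._alphabet import AMINO_ACIDS, sanitize_protein

#: Default conservation level for emitting a residue token.  Chosen between
#: the retention of ordinary family columns and of anchor columns so that
#: only genuinely constrained positions read as letters.
DEFAULT_TAU_CONS = 0.8

GAP = "-"


@dataclass
class MSA:
    """Reference-anchored, pruned alignment: every column corresponds to one
    reference position (1-based), so n_cols == len(reference)."""

    reference_id: str
    rows: dict[str, str]
    n_cols: int

    def __post_init__(self) -> None:
        if any(len(r) != self.n_cols for r in self.rows.values()):
            raise ValueError("alignment rows differ in length")
        if self.reference_id not in self.rows:
            raise ValueError("reference row missing from MSA")
        if GAP in self.rows[self.reference_id]:
            raise ValueError("pruned MSA must have a gap-free reference row")

    def reference_position(self, column: int) -> int:
        """Reference position (1-based) of a 0-based column index."""
        return column + 1

    def column_counts(self, column: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows.values():
            ch = row[column]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        return counts


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def project_onto_reference(reference: str, member: str) -> str:
    """Align a member to the reference and return its residues per reference
    column (gaps where the member has a deletion; insertions dropped)."""
    aln = _ALIGNER.align(reference, member)[0]
    ref_row = str(aln[0])
    mem_row = str(aln[1])
    out = []
    for r, m in zip(ref_row, mem_row):
        if r != GAP:
            out.append(m)
    return "".join(out)


def anchor_msa(
    reference: str,
    members: Mapping[str, str],
    reference_id: str = "reference",
) -> MSA:
    """Star alignment of members onto the reference, pruned to reference
    columns."""
    reference = sanitize_protein(reference)
    if not reference:
        raise ValueError("empty reference")
    if not members:
        raise ValueError("empty member set")
    rows: dict[str, str] = {reference_id: reference}
    for mid in members:
        if mid == reference_id:
            raise ValueError(f"member id collides with reference id {mid!r}")
        rows[mid] = project_onto_reference(
            reference, sanitize_protein(members[mid])
        )
    return MSA(reference_id=reference_id, rows=rows, n_cols=len(reference))


def prune_to_reference(rows: Mapping[str, str], reference_id: str) -> MSA:
    """Drop the columns where the reference row is gapped (idempotent)."""
    if reference_id not in rows:
        raise ValueError(f"reference row {reference_id!r} missing")
    ref = rows[reference_id]
    keep = [j for j, ch in enumerate(ref) if ch != GAP]
    pruned = {
        rid: "".join(row[j] for j in keep) for rid, row in rows.items()
    }
    return MSA(reference_id=reference_id, rows=pruned, n_cols=len(keep))


@dataclass(frozen=True)
class LogoColumn:
    position: int
    counts: dict[str, int]
    entropy: float
    information: float
    heights: dict[str, float]


def column_information(
    counts: Mapping[str, int],
    position: int = 0,
    small_sample_correction: bool = False,
) -> LogoColumn:
    """Shannon entropy, information content and letter heights of a column."""
    total = sum(counts.values())
    if total < 1:
        raise ValueError("all-gap column: no residues to summarize")
    p = {a: c / total for a, c in counts.items() if c > 0}
    entropy = -sum(v * math.log2(v) for v in p.values())
    e_n = (
        (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * total)
        if small_sample_correction
        else 0.0
    )
    ic = math.log2(len(AMINO_ACIDS)) - entropy - e_n
    heights = {a: v * ic for a, v in p.items()}
    return LogoColumn(
        position=position, counts=dict(counts), entropy=entropy,
        information=ic, heights=heights,
    )


def logo_table(
    msa: MSA,
    window: tuple[int, int] | None = None,
    small_sample_correction: bool = False,
) -> list[LogoColumn]:
    """Per-reference-position logo columns over a window (default: all)."""
    lo, hi = window if window else (1, msa.n_cols)
    if not 1 <= lo <= hi <= msa.n_cols:
        raise ValueError(f"window {lo}-{hi} outside reference length {msa.n_cols}")
    return [
        column_information(
            msa.column_counts(j - 1), position=j,
            small_sample_correction=small_sample_correction,
        )
        for j in range(lo, hi + 1)
    ]


@dataclass(frozen=True)
class MotifConsensus:
    tokens: tuple[str, ...]
    tau_cons: float
    #: reference position of each residue token, parallel to ``letters``
    letter_positions: tuple[int, ...]

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if len(t) == 1 and t != "x")

    def __str__(self) -> str:
        return "".join(self.tokens)


def consensus_motif(
    msa: MSA,
    tau_cons: float = DEFAULT_TAU_CONS,
    window: tuple[int, int] | None = None,
    variable_gap_fraction: float = 0.05,
    min_support: float = 0.5,
) -> MotifConsensus:
    """Extract the consensus-motif token string over a reference window.

    A column emits its majority residue when that residue's frequency (over
    non-gap rows) reaches tau_cons and at least ``min_support`` of the rows
    carry a residue there (a gap-dominated column never reads as a letter);
    maximal runs of k non-conserved columns emit the fixed spacer
    ``x``/``x2``/…/``xk``, or the variable spacer ``xn`` when >=
    ``variable_gap_fraction`` of rows carry a gap inside the run.
    """
    lo, hi = window if window else (1, msa.n_cols)
    if not 1 <= lo <= hi <= msa.n_cols:
        raise ValueError(f"window {lo}-{hi} outside reference length {msa.n_cols}")
    n_rows = len(msa.rows)

    conserved: list[str | None] = []
    for j in range(lo - 1, hi):
        counts = msa.column_counts(j)
        total = sum(counts.values())
        letter = None
        if total and total / n_rows >= min_support:
            best, c = max(sorted(counts.items()), key=lambda kv: kv[1])
            if c / total >= tau_cons:
                letter = best
        conserved.append(letter)

    tokens: list[str] = []
    letter_positions: list[int] = []
    j = 0
    while j < len(conserved):
        if conserved[j] is not None:
            tokens.append(conserved[j])
            letter_positions.append(lo + j)
            j += 1
            continue
        k = j
        while k < len(conserved) and conserved[k] is None:
            k += 1
        run_cols = range(lo - 1 + j, lo - 1 + k)
        gapped_rows = sum(
            1
            for row in msa.rows.values()
            if any(row[c] == GAP for c in run_cols)
        )
        if gapped_rows / n_rows >= variable_gap_fraction:
            tokens.append("xn")
        else:
            width = k - j
            tokens.append("x" if width == 1 else f"x{width}")
        j = k
    return MotifConsensus(
        tokens=tuple(tokens),
        tau_cons=tau_cons,
        letter_positions=tuple(letter_positions),
    )
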