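"""Flank extraction and greedy incremental clustering of flank sequences.

Marker-domain proteins are grouped by the sequence on the far side of the
anchored domain: C-terminal flanks for the marker (FIX-type) hits, N-terminal
flanks for the toxin (PoNe-type) hits.  Clustering follows the greedy
incremental scheme of CD-HIT-style tools: sequences are processed longest
first, each joins the *most similar* existing representative among those
meeting both thresholds (identity >= 0.40 to the representative, length >=
0.50 of the representative), otherwise it founds a new cluster.

Pairwise identity is computed from a global end-gap-free alignment (BLOSUM62,
affine gaps) as identical aligned pairs divided by the shorter sequence's
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ._alphabet import sanitize_protein
from .profile_search import DomainHit


@dataclass(frozen=True)
class FlankSequence:
    protein_id: str
    side: str  # "N" or "C"
    sequence: str

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError(f"side must be 'N' or 'C', got {self.side!r}")


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[tuple[str, float]] = field(default_factory=list)


def extract_flank(
    protein: str, hit: DomainHit, side: str
) -> FlankSequence | None:
    """The residues outside the hit: side "C" -> (end+1 .. L), side "N" ->
    (1 .. start-1).  Returns None (with the caller expected to log a notice)
    when the domain abuts the terminus."""
    protein = sanitize_protein(protein)
    if not (1 <= hit.start <= hit.end <= len(protein)):
        raise ValueError(
            f"hit {hit.start}-{hit.end} outside protein of length {len(protein)}"
        )
    if side == "C":
        seq = protein[hit.end:]
    elif side == "N":
        seq = protein[: hit.start - 1]
    else:
        raise ValueError(f"side must be 'N' or 'C', got {side!r}")
    if not seq:
        return None
    return FlankSequence(protein_id=hit.protein_id, side=side, sequence=seq)


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


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residue pairs over the shorter sequence
    (global end-gap-free alignment, BLOSUM62).  Symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    a, b = sanitize_protein(a), sanitize_protein(b)
    # canonical argument order makes symmetry exact even on alignment ties
    x, y = sorted((a, b))
    alignment = _ALIGNER.align(x, y)[0]
    identities = alignment.counts().identities
    return min(1.0, identities / min(len(a), len(b)))


def greedy_cluster(
    flanks: Sequence[FlankSequence] | Mapping[str, str],
    identity_threshold: float = 0.40,
    length_ratio: float = 0.50,
) -> list[Cluster]:
    """Greedy incremental clustering against cluster representatives.

    Input order is canonicalized (length desc, protein_id asc), so the result
    is invariant to permutation.  A sequence joins the representative with
    maximal identity among those satisfying identity >= identity_threshold
    and len(seq) >= length_ratio * len(representative); ties go to the
    earliest-founded cluster; otherwise it founds a new cluster and becomes
    its representative.
    """
    if isinstance(flanks, Mapping):
        items = [
            FlankSequence(pid, "C", sanitize_protein(seq))
            for pid, seq in flanks.items()
        ]
    else:
        items = list(flanks)
    if not items:
        raise ValueError("no flank sequences to cluster")
    items.sort(key=lambda f: (-len(f.sequence), f.protein_id))

    clusters: list[Cluster] = []
    reps: list[FlankSequence] = []
    for flank in items:
        best_idx, best_ident = -1, -1.0
        for idx, rep in enumerate(reps):
            if len(flank.sequence) < length_ratio * len(rep.sequence):
                continue
            ident = pairwise_identity(flank.sequence, rep.sequence)
            if ident >= identity_threshold and ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx >= 0:
            clusters[best_idx].members.append((flank.protein_id, best_ident))
        else:
            clusters.append(
                Cluster(
                    cluster_id=len(clusters),
                    representative=flank.protein_id,
                    members=[(flank.protein_id, 1.0)],
                )
            )
            reps.append(flank)
    return clusters
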