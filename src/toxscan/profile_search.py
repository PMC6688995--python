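"""Profile construction and iterative profile-based homology search.

A family is modelled as a pseudocounted position-specific scoring matrix
(PSSM): per column j and residue a,

    f_{j,a} = (c_{j,a} + alpha * q_a) / (N_j + alpha)
    score(j, a) = log2(f_{j,a} / q_a)          [bits]

where c is the observed count, N_j the non-gap count in the column, q the
background distribution and alpha the pseudocount weight.  Scanning is
ungapped: every length-L window of a protein is scored as the sum of its
column scores, and non-overlapping windows above threshold are reported.

Statistical significance is calibrated empirically against seeded decoy
proteins drawn from the background: the expect value of a score s is the
expected number of decoys reaching s, with an exponential tail fit carrying
the mapping beyond the best decoy score.  The iterative search mirrors the
classic profile-refinement loop: scan, admit up to a fixed number of new
hits passing the inclusion threshold, realign the admitted hits to the
reference, rebuild the profile, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    BACKGROUND_VECTOR,
    encode_protein,
    sanitize_protein,
)


@dataclass(frozen=True)
class DomainHit:
    """One scored domain localization (1-based inclusive coordinates)."""

    protein_id: str
    profile: str
    start: int
    end: int
    score: float
    expect: float = float("nan")


@dataclass(frozen=True)
class SearchConfig:
    iterations: int = 5
    per_iteration_cap: int = 500
    inclusion_expect: float = 1e-6
    report_expect: float = 1e-9
    decoy_count: int = 1000
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.per_iteration_cap < 1:
            raise ValueError("iterations and cap must be >= 1")
        if self.inclusion_expect <= 0 or self.report_expect <= 0:
            raise ValueError("expect thresholds must be positive")


class ProfileMatrix:
    """Pseudocounted log-odds profile over the 20-letter alphabet.

    ``scores`` has shape (L, 21): index 20 is the score of X (always 0).
    """

    def __init__(self, name: str, freqs: np.ndarray, background: np.ndarray):
        if freqs.ndim != 2 or freqs.shape[1] != 20:
            raise ValueError("frequency matrix must be (L, 20)")
        if not np.allclose(freqs.sum(axis=1), 1.0):
            raise ValueError("column frequencies must sum to 1")
        self.name = name
        self.freqs = freqs
        self.background = background
        scores = np.log2(freqs / background[None, :])
        self.scores = np.concatenate(
            [scores, np.zeros((freqs.shape[0], 1))], axis=1
        )

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def score(self, j: int, residue: str) -> float:
        """Score (bits) of residue at 0-based column j."""
        if residue == "X":
            return 0.0
        return float(self.scores[j, AA_INDEX[residue]])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProfileMatrix)
            and self.name == other.name
            and np.array_equal(self.freqs, other.freqs)
            and np.array_equal(self.background, other.background)
        )


def _sanitize_gapped(row: str) -> str:
    return "".join(
        "-" if ch == "-" else sanitize_protein(ch) for ch in row
    )


def build_pssm(
    seed_alignment: Sequence[str],
    alpha: float = 1.0,
    background: Mapping[str, float] | np.ndarray | None = None,
    name: str = "profile",
) -> ProfileMatrix:
    """Build a ProfileMatrix from an aligned set of rows (gaps allowed,
    all rows one length).  A single unaligned sequence is a valid one-row
    alignment."""
    if not list(seed_alignment):
        raise ValueError("empty alignment")
    if alpha <= 0:
        raise ValueError("pseudocount weight must be > 0")
    rows = [_sanitize_gapped(r) for r in seed_alignment]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    if isinstance(background, Mapping):
        q = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
    elif background is None:
        q = BACKGROUND_VECTOR.copy()
    else:
        q = np.asarray(background, dtype=float)
    if (q <= 0).any() or not np.isclose(q.sum(), 1.0):
        raise ValueError("background must be positive and sum to 1")

    counts = np.zeros((L, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch in ("-", "X"):
                continue
            counts[j, AA_INDEX[ch]] += 1.0
    n_j = counts.sum(axis=1)
    freqs = (counts + alpha * q[None, :]) / (n_j + alpha)[:, None]
    return ProfileMatrix(name, freqs, q)


def _window_scores_encoded(seq: np.ndarray, pssm: ProfileMatrix) -> np.ndarray:
    L = pssm.length
    if len(seq) < L:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(seq, L)
    return pssm.scores[np.arange(L)[None, :], windows].sum(axis=1)


def window_scores(protein: str, pssm: ProfileMatrix) -> np.ndarray:
    """Score every length-L window of the protein (vectorized); empty array
    if the protein is shorter than the profile."""
    return _window_scores_encoded(encode_protein(sanitize_protein(protein)), pssm)


def scan_protein(
    protein: str | np.ndarray,
    pssm: ProfileMatrix,
    protein_id: str = "query",
    threshold: float = 0.0,
) -> list[DomainHit]:
    """Best non-overlapping ungapped windows above ``threshold`` (bits),
    sorted by score descending."""
    if isinstance(protein, str):
        scores = window_scores(protein, pssm)
    else:
        scores = _window_scores_encoded(protein, pssm)
    L = pssm.length
    hits: list[DomainHit] = []
    taken = np.zeros(len(scores), dtype=bool)
    for idx in np.argsort(-scores, kind="stable"):
        if scores[idx] <= threshold:
            break
        if taken[max(0, idx - L + 1): idx + L].any():
            continue
        taken[idx] = True
        hits.append(
            DomainHit(
                protein_id=protein_id,
                profile=pssm.name,
                start=int(idx) + 1,
                end=int(idx) + L,
                score=float(scores[idx]),
            )
        )
    return hits


class ExpectCalibration:
    """Empirical score -> expect mapping from decoy top scores.

    E(s) = (number of decoys whose best window reaches s) / n_decoys for s up
    to the best decoy score; beyond it, an exponential tail fitted to the top
    decile of decoy scores extrapolates, capped at 1/n_decoys so the mapping
    stays monotone non-increasing.
    """

    def __init__(self, decoy_scores: np.ndarray):
        if len(decoy_scores) < 100:
            raise ValueError("need at least 100 decoys for calibration")
        self.decoy_scores = np.sort(np.asarray(decoy_scores, dtype=float))
        self.n = len(self.decoy_scores)
        k = max(10, self.n // 10)
        tail = self.decoy_scores[-k:]
        self._tail_origin = float(self.decoy_scores[-1])
        self._tail_scale = float(max(np.mean(tail - tail[0]), 1e-3))

    def expect(self, score: float) -> float:
        if score <= self._tail_origin:
            n_ge = self.n - np.searchsorted(
                self.decoy_scores, score, side="left"
            )
            return float(n_ge) / self.n
        return (1.0 / self.n) * float(
            np.exp(-(score - self._tail_origin) / self._tail_scale)
        )

    def threshold_for(self, expect: float) -> float:
        """Smallest score whose empirical expect is <= the given value."""
        lo = float(self.decoy_scores[0]) - 1.0
        hi = self._tail_origin + self._tail_scale * 200.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self.expect(mid) <= expect:
                hi = mid
            else:
                lo = mid
        return hi


def calibrate_expect(
    pssm: ProfileMatrix,
    decoys: Mapping[str, str] | Sequence[str] | Sequence[np.ndarray],
    seed: int | None = None,
) -> ExpectCalibration:
    """Calibrate the empirical expect mapping of a profile against decoy
    proteins (their best window score each).  Decoys shorter than the profile
    contribute a floor score and never raise the threshold."""
    seqs = list(decoys.values()) if isinstance(decoys, Mapping) else list(decoys)
    if len(seqs) < 100:
        raise ValueError("need at least 100 decoys for calibration")
    tops = []
    for s in seqs:
        enc = encode_protein(sanitize_protein(s)) if isinstance(s, str) else s
        ws = _window_scores_encoded(enc, pssm)
        tops.append(float(ws.max()) if len(ws) else -1e9)
    return ExpectCalibration(np.array(tops))


def generate_decoys(
    lengths: Sequence[int], seed, background: np.ndarray | None = None
) -> dict[str, str]:
    """Background-emitted decoy proteome with the given lengths (seeded)."""
    rng = np.random.default_rng(seed)
    q = BACKGROUND_VECTOR if background is None else background
    aa = np.array(list(AMINO_ACIDS))
    return {
        f"DECOY_{i:05d}": "".join(rng.choice(aa, size=n, p=q))
        for i, n in enumerate(lengths)
    }


@dataclass
class SearchResult:
    hits: dict[str, DomainHit]
    profile: ProfileMatrix
    calibration: ExpectCalibration
    per_iteration_counts: list[int] = field(default_factory=list)


def iterate_search(
    seed_alignment: Sequence[str],
    database: Mapping[str, str],
    cfg: SearchConfig,
    name: str = "profile",
    reference: str | None = None,
) -> SearchResult:
    """Iterative profile search against a proteome.

    Per iteration: scan every protein not yet admitted, admit up to
    ``per_iteration_cap`` new proteins whose best hit passes the inclusion
    expect threshold (ties at the cap boundary broken by score desc, then
    protein_id), realign all admitted hit windows to the reference, rebuild
    the profile and recalibrate.  The admitted hit set never shrinks.
    """
    from .conservation import anchor_msa  # local import: avoids module cycle

    if not database:
        raise ValueError("empty database")
    ref = reference if reference is not None else seed_alignment[0].replace("-", "")
    ref = sanitize_protein(ref)

    rng = np.random.default_rng(cfg.seed)
    db_lengths = [len(s) for s in database.values()]
    decoy_lengths = [
        int(db_lengths[i]) for i in rng.integers(0, len(db_lengths), cfg.decoy_count)
    ]
    decoys = generate_decoys(decoy_lengths, int(rng.integers(0, 2**31 - 1)))
    decoy_enc = [encode_protein(s) for s in decoys.values()]
    db_enc = {
        pid: encode_protein(sanitize_protein(seq)) for pid, seq in database.items()
    }

    admitted: dict[str, DomainHit] = {}
    aligned_members: dict[str, str] = {}
    profile = build_pssm(seed_alignment, alpha=cfg.pseudocount, name=name)
    calibration = calibrate_expect(profile, decoy_enc)
    counts: list[int] = []

    for _ in range(cfg.iterations):
        threshold = calibration.threshold_for(cfg.inclusion_expect)
        candidates: list[DomainHit] = []
        for pid in sorted(db_enc):
            if pid in admitted:
                continue
            best = scan_protein(db_enc[pid], profile, pid, threshold=threshold)
            if best:
                hit = best[0]
                candidates.append(
                    DomainHit(
                        protein_id=pid, profile=name,
                        start=hit.start, end=hit.end, score=hit.score,
                        expect=calibration.expect(hit.score),
                    )
                )
        candidates.sort(key=lambda h: (-h.score, h.protein_id))
        for hit in candidates[: cfg.per_iteration_cap]:
            admitted[hit.protein_id] = hit
            window = sanitize_protein(database[hit.protein_id])[
                hit.start - 1 : hit.end
            ]
            aligned_members[hit.protein_id] = window
        counts.append(len(admitted))
        if aligned_members:
            msa = anchor_msa(ref, aligned_members, reference_id="__ref__")
            rows = [msa.rows[rid] for rid in sorted(msa.rows) if rid != "__ref__"]
            profile = build_pssm(rows or [ref], alpha=cfg.pseudocount, name=name)
            calibration = calibrate_expect(profile, decoy_enc)

    # re-localize the final hit set under the final profile and calibration
    final: dict[str, DomainHit] = {}
    for pid, hit in admitted.items():
        best = scan_protein(db_enc[pid], profile, pid, threshold=-1e9)
        top = best[0] if best else hit
        final[pid] = DomainHit(
            protein_id=pid, profile=name, start=top.start, end=top.end,
            score=top.score, expect=calibration.expect(top.score),
        )
    return SearchResult(
        hits=final, profile=profile, calibration=calibration,
        per_iteration_counts=counts,
    )
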