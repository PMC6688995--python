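"""Strand-aware genomic adjacency and effector/immunity neighborhood analysis.

"Upstream" and "downstream" are taken in gene orientation: for a plus-strand
gene the downstream neighbor is the next CDS by feature index, for a
minus-strand gene the previous one.  A neighbor only counts if it is the
immediately adjacent CDS *and* lies on the same strand; an opposite-strand
adjacent CDS yields none (the strict reading of "directly upstream"), unless
``skip_opposite`` is enabled, in which case intervening opposite-strand genes
are stepped over.

The headline statistic is effector/immunity pairing: the fraction of toxin
loci whose same-strand downstream neighbor encodes a protein with a DUF1911
immunity domain (DUF1910 co-presence tracked as a secondary flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import MISSING, CdsFeature, FeatureTable
from .profile_search import DomainHit

#: Domains counted as T6SS components when found upstream of a marker locus.
UPSTREAM_T6SS_DOMAINS = frozenset(
    {"VgrG", "TssL", "DUF4123",
     "COG3516", "COG3517", "COG3157", "COG3521", "COG3522", "COG3455",
     "COG3523", "COG3518", "COG3519", "COG3520", "COG3515", "COG3501"}
)

#: Delivery-domain precedence for architecture classification.
ARCHITECTURE_PRECEDENCE = (
    "PAAR", "DUF4280", "LXG", "WXG100", "DUF637", "Fil_haemagg_2", "VgrG", "SP",
)

SP_PHOBIUS = "SP_Phobius"
SP_SIGNALP = "SP_SignalP"


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage with half-up rounding to 2 decimals (1389/1546 -> 89.84)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def intergenic_distance(a: CdsFeature, b: CdsFeature) -> int:
    """Gap in bp between two CDS on a contig (0 for abutting genes)."""
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end - 1)


def adjacent_locus(
    feature_table: FeatureTable,
    focal: CdsFeature,
    direction: str,
    skip_opposite: bool = False,
) -> CdsFeature | None:
    """The immediately adjacent same-strand CDS in gene orientation, or None.

    direction "down": next CDS for + strand, previous for -; "up" reversed.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    contig = feature_table.contig(focal.assembly_id, focal.contig_id)
    if focal not in contig:
        raise KeyError(
            f"focal CDS {focal.protein_id!r} not in feature table"
        )
    step = 1 if (focal.strand == "+") == (direction == "down") else -1
    index = focal.feature_index + step
    by_index = {f.feature_index: f for f in contig}
    while index in by_index:
        neighbor = by_index[index]
        if neighbor.strand == focal.strand:
            return neighbor
        if not skip_opposite:
            return None
        index += step
    return None


@dataclass(frozen=True)
class LocusNeighborhood:
    focal: CdsFeature
    upstream: CdsFeature | None
    downstream: CdsFeature | None
    upstream_distance: int | None
    downstream_distance: int | None


def locus_neighborhood(
    feature_table: FeatureTable, focal: CdsFeature, skip_opposite: bool = False
) -> LocusNeighborhood:
    up = adjacent_locus(feature_table, focal, "up", skip_opposite)
    down = adjacent_locus(feature_table, focal, "down", skip_opposite)
    return LocusNeighborhood(
        focal=focal,
        upstream=up,
        downstream=down,
        upstream_distance=intergenic_distance(focal, up) if up else None,
        downstream_distance=intergenic_distance(focal, down) if down else None,
    )


@dataclass(frozen=True)
class PairingSummary:
    n_toxin_loci: int
    n_paired: int

    @property
    def percent_paired(self) -> float | None:
        if self.n_toxin_loci == 0:
            return None
        return round_percent(self.n_paired, self.n_toxin_loci)


def _domains_by_protein(annotations: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pid, name in zip(annotations["protein_id"], annotations["domain_name"]):
        out.setdefault(pid, set()).add(name)
    return out


def pair_immunity(
    toxin_loci: Sequence[CdsFeature],
    feature_table: FeatureTable,
    annotations: pd.DataFrame,
    skip_opposite: bool = False,
) -> tuple[PairingSummary, pd.DataFrame]:
    """Count toxin loci whose same-strand downstream neighbor carries DUF1911.

    Returns the summary plus a per-locus table with the neighbor identity,
    the pairing flag and a DUF1910 co-presence flag.
    """
    domains = _domains_by_protein(annotations)
    rows = []
    n_paired = 0
    for focal in toxin_loci:
        down = adjacent_locus(feature_table, focal, "down", skip_opposite)
        has_1911 = down is not None and "DUF1911" in domains.get(down.protein_id, set())
        has_1910 = down is not None and "DUF1910" in domains.get(down.protein_id, set())
        n_paired += has_1911
        rows.append(dict(
            assembly_id=focal.assembly_id,
            contig_id=focal.contig_id,
            protein_id=focal.protein_id,
            downstream_protein=down.protein_id if down else MISSING,
            downstream_distance=intergenic_distance(focal, down) if down else -1,
            paired=bool(has_1911),
            duf1910_copresent=bool(has_1911 and has_1910),
        ))
    summary = PairingSummary(n_toxin_loci=len(toxin_loci), n_paired=n_paired)
    table = pd.DataFrame(
        rows,
        columns=["assembly_id", "contig_id", "protein_id", "downstream_protein",
                 "downstream_distance", "paired", "duf1910_copresent"],
    )
    return summary, table


def summarize_upstream_domains(
    marker_loci: Sequence[CdsFeature],
    feature_table: FeatureTable,
    annotations: pd.DataFrame,
    skip_opposite: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Tabulate the domains of same-strand upstream neighbors of marker loci.

    Percentages are over loci that have an upstream neighbor.  The second
    return value is the T6SS-component share: the percentage of upstream
    genes carrying VgrG, TssL, DUF4123 or a core-component COG.
    """
    domains = _domains_by_protein(annotations)
    counts: dict[str, int] = {}
    n_with_upstream = 0
    n_t6ss = 0
    for focal in marker_loci:
        up = adjacent_locus(feature_table, focal, "up", skip_opposite)
        if up is None:
            continue
        n_with_upstream += 1
        doms = domains.get(up.protein_id, set())
        if doms & UPSTREAM_T6SS_DOMAINS:
            n_t6ss += 1
        for d in sorted(doms) or ["none"]:
            counts[d] = counts.get(d, 0) + 1
    if n_with_upstream == 0:
        return (
            pd.DataFrame(columns=["domain_name", "count", "percent"]),
            None,
        )
    table = pd.DataFrame(
        [
            (d, c, round_percent(c, n_with_upstream))
            for d, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["domain_name", "count", "percent"],
    )
    return table, round_percent(n_t6ss, n_with_upstream)


def signal_peptide_consensus(phobius_call: bool, signalp_call: bool) -> bool:
    """A protein counts as signal-peptide-bearing only when both predictors
    agree (missing calls are false)."""
    return bool(phobius_call) and bool(signalp_call)


@dataclass(frozen=True)
class ArchitectureClass:
    label: str
    evidence: tuple[str, ...] = ()


def classify_architecture(
    toxin_hit: DomainHit, annotations: pd.DataFrame
) -> ArchitectureClass:
    """Assign the delivery-domain architecture of a toxin protein.

    The first label in the precedence order whose domain annotation lies
    N-terminal to the toxin hit wins; SP requires the two-predictor consensus
    and, being a leader peptide, no position constraint beyond its own call.
    """
    mine = annotations[annotations["protein_id"] == toxin_hit.protein_id]
    doms = {
        row.domain_name: (int(row.start), int(row.end))
        for row in mine.itertuples(index=False)
    }
    for label in ARCHITECTURE_PRECEDENCE:
        if label == "SP":
            if signal_peptide_consensus(
                SP_PHOBIUS in doms, SP_SIGNALP in doms
            ):
                return ArchitectureClass("SP", (SP_PHOBIUS, SP_SIGNALP))
        elif label in doms and doms[label][0] < toxin_hit.start:
            return ArchitectureClass(label, (label,))
    return ArchitectureClass("none")
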