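"""Post-search curation of domain hits.

Three independent, idempotent filters, applied to the hit universe after the
iterative search:

* expect/length: keep hits with expect <= 1e-9; toxin-domain (PoNe-type)
  hits additionally require the whole protein to be at least 80 residues;
* contig ends: drop hits whose CDS is the first or last feature of its
  contig (likely truncated loci);
* multi-contig dedup: a protein accession appearing on more than one contig
  of the same assembly is collapsed to one copy when every copy has the same
  same-strand downstream gene (by product label) at the same intergenic
  distance — the signature of a duplicated contig.

Each removal is reason-coded so the report partitions the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import CdsFeature, FeatureTable
from .neighborhood import adjacent_locus, intergenic_distance
from .profile_search import DomainHit

REASONS = ("expect", "length", "contig_end", "duplicate")


@dataclass(frozen=True)
class LocatedHit:
    """A domain hit placed on a specific CDS (hence contig)."""

    hit: DomainHit
    feature: CdsFeature

    @property
    def key(self) -> tuple:
        return (
            self.feature.assembly_id,
            self.feature.contig_id,
            self.hit.protein_id,
            self.hit.profile,
        )


@dataclass
class CurationConfig:
    report_expect: float = 1e-9
    min_protein_len: int = 80
    #: profiles to which the length floor applies (toxin-domain hits)
    length_profiles: tuple[str, ...] = ("PoNe",)
    drop_contig_ends: bool = True
    dedup_multi_contig: bool = True

    def __post_init__(self) -> None:
        if self.report_expect <= 0 or self.min_protein_len < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CurationReport:
    kept: list[LocatedHit]
    removed: list[tuple[LocatedHit, str]] = field(default_factory=list)

    @property
    def removed_reasons(self) -> dict[tuple, str]:
        return {lh.key: reason for lh, reason in self.removed}

    def kept_keys(self) -> set[tuple]:
        return {lh.key for lh in self.kept}


def locate_hits(
    hits: Iterable[DomainHit], feature_table: FeatureTable
) -> list[LocatedHit]:
    """Attach each hit to every CDS carrying its protein (one LocatedHit per
    contig occurrence, so duplicated contigs yield duplicated located hits)."""
    by_protein: dict[str, list[CdsFeature]] = {}
    for f in feature_table:
        by_protein.setdefault(f.protein_id, []).append(f)
    located = []
    for hit in hits:
        feats = by_protein.get(hit.protein_id)
        if not feats:
            raise KeyError(f"hit protein {hit.protein_id!r} not in feature table")
        for f in feats:
            located.append(LocatedHit(hit=hit, feature=f))
    return sorted(located, key=lambda lh: lh.key)


def filter_expect_and_length(
    hits: Sequence[LocatedHit], cfg: CurationConfig
) -> CurationReport:
    """Keep hits with expect <= threshold and, for toxin-domain profiles,
    protein length >= the 80-aa floor (both boundaries inclusive)."""
    kept, removed = [], []
    for lh in hits:
        if not lh.hit.expect <= cfg.report_expect:  # NaN expect is removed too
            removed.append((lh, "expect"))
        elif (
            lh.hit.profile in cfg.length_profiles
            and lh.feature.length_aa < cfg.min_protein_len
        ):
            removed.append((lh, "length"))
        else:
            kept.append(lh)
    return CurationReport(kept=kept, removed=removed)


def drop_contig_end_hits(
    hits: Sequence[LocatedHit], feature_table: FeatureTable
) -> CurationReport:
    """Remove hits whose CDS is the first or last feature of its contig."""
    kept, removed = [], []
    for lh in hits:
        contig = feature_table.contig(
            lh.feature.assembly_id, lh.feature.contig_id
        )
        if not contig:
            raise KeyError(
                f"contig {lh.feature.contig_id!r} not in feature table"
            )
        max_index = contig[-1].feature_index
        if lh.feature.feature_index in (1, max_index):
            removed.append((lh, "contig_end"))
        else:
            kept.append(lh)
    return CurationReport(kept=kept, removed=removed)


def _downstream_signature(
    feature: CdsFeature, feature_table: FeatureTable
) -> tuple[str, int] | None:
    down = adjacent_locus(feature_table, feature, "down")
    if down is None:
        return None
    return (down.product, intergenic_distance(feature, down))


def dedup_multi_contig(
    hits: Sequence[LocatedHit], feature_table: FeatureTable
) -> CurationReport:
    """Collapse multi-contig copies of the same accession within an assembly
    when all copies share an identical same-strand downstream gene (product
    label) at an identical distance; the copy on the lexicographically
    smallest contig survives.

    The decision is a static predicate of the feature table (all contig
    occurrences of the accession), so the filters commute.
    """
    kept, removed = [], []
    for lh in hits:
        copies = feature_table.lookup_protein(
            lh.feature.assembly_id, lh.hit.protein_id
        )
        contigs = sorted({f.contig_id for f in copies})
        if len(contigs) < 2:
            kept.append(lh)
            continue
        signatures = {_downstream_signature(f, feature_table) for f in copies}
        if len(signatures) == 1 and lh.feature.contig_id != contigs[0]:
            removed.append((lh, "duplicate"))
        else:
            kept.append(lh)
    kept.sort(key=lambda x: x.key)
    removed.sort(key=lambda pair: pair[0].key)
    return CurationReport(kept=kept, removed=removed)


def curate(
    hits: Iterable[DomainHit],
    feature_table: FeatureTable,
    cfg: CurationConfig | None = None,
) -> CurationReport:
    """Apply the three filters; the kept set is order-invariant because each
    predicate depends only on the hit and the static feature table."""
    cfg = cfg or CurationConfig()
    located = locate_hits(hits, feature_table)
    report = filter_expect_and_length(located, cfg)
    removed = list(report.removed)
    current = report.kept
    if cfg.drop_contig_ends:
        r = drop_contig_end_hits(current, feature_table)
        removed.extend(r.removed)
        current = r.kept
    if cfg.dedup_multi_contig:
        r = dedup_multi_contig(current, feature_table)
        removed.extend(r.removed)
        current = r.kept
    removed.sort(key=lambda pair: pair[0].key)
    return CurationReport(kept=current, removed=removed)
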