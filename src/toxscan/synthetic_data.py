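"""Seeded synthetic genomes, proteomes and ground truth.

The generator plants a family of polymorphic-toxin effectors in otherwise
random bacterial genomes so that every downstream stage of the pipeline
(profile search, curation, clustering, neighborhood pairing, T6SS
classification, conservation logos, phylogeny) can be exercised and verified
against a known truth table, with no external downloads.

The planted family descends from a single 449-residue reference archetype:

* an N-terminal marker domain (FIX-like) at positions 43-121,
* a C-terminal nuclease domain (PoNe-like) at positions 283-449,
* inside the nuclease domain, a PD-(D/E)xK-style conserved motif spanning
  positions 294-354 whose anchor letters are K,G,E,G,I,D,Y,Y,E,K with the
  putative catalytic aspartate at position 335.

Family members are emitted by per-site substitution at a configurable
divergence; motif anchor columns mutate at one tenth of that rate, so the
planted conservation signal is recoverable by the logo stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS, BACKGROUND_VECTOR
from .genome_io import CdsFeature, FeatureTable

TRUTH_COLUMNS = [
    "assembly_id",
    "contig_id",
    "protein_id",
    "planted_domain",
    "domain_start",
    "domain_end",
    "paired_immunity",
    "genome_has_t6ss",
    "should_survive",
]

#: The 11 T6SS core-component COG labels plus the separately tracked VgrG COG.
T6SS_CORE_COGS = (
    "COG3516", "COG3517", "COG3157", "COG3521", "COG3522", "COG3455",
    "COG3523", "COG3518", "COG3519", "COG3520", "COG3515",
)
VGRG_COG = "COG3501"

UPSTREAM_T6SS_DOMAINS = ("VgrG", "TssL", "DUF4123")


@dataclass(frozen=True)
class ReferenceArchetype:
    """The planted 449-aa reference effector and its landmark coordinates
    (all 1-based inclusive)."""

    protein_id: str
    sequence: str
    fix_start: int = 43
    fix_end: int = 121
    pone_start: int = 283
    pone_end: int = 449
    catalytic_position: int = 335
    motif_start: int = 294
    motif_end: int = 354
    #: position -> conserved letter for the motif anchor columns
    anchors: tuple[tuple[int, str], ...] = (
        (294, "K"), (298, "G"), (299, "E"), (333, "G"), (334, "I"),
        (335, "D"), (338, "Y"), (348, "Y"), (352, "E"), (354, "K"),
    )

    @property
    def anchor_map(self) -> dict[int, str]:
        return dict(self.anchors)

    def fix_region(self) -> str:
        return self.sequence[self.fix_start - 1 : self.fix_end]

    def pone_region(self) -> str:
        return self.sequence[self.pone_start - 1 : self.pone_end]

    def n_terminus(self) -> str:
        """Residues 1..282, the delivery region preceding the nuclease."""
        return self.sequence[: self.pone_start - 1]


def reference_archetype() -> ReferenceArchetype:
    """Build the fixed reference archetype (deterministic constant)."""
    rng = np.random.default_rng(20190331)
    aa = np.array(list(AMINO_ACIDS))
    seq = list(rng.choice(aa, size=449, p=BACKGROUND_VECTOR))
    arch = ReferenceArchetype(protein_id="SYNEFF_0001", sequence="")
    for pos, letter in arch.anchors:
        seq[pos - 1] = letter
    return replace(arch, sequence="".join(seq))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults mirror the study conditions
    the pipeline is meant to reproduce (pairing 89.84%, T6SS co-occurrence
    >96%, 70% T6SS-component upstream genes)."""

    seed: int = 7
    n_genomes: int = 200
    contigs_per_genome: tuple[int, int] = (2, 4)
    genes_per_contig: tuple[int, int] = (6, 14)
    mean_protein_len: int = 300
    marker_rate: float = 0.8
    toxin_rate: float = 0.7
    pairing_rate: float = 0.8984
    t6ss_rate: float = 0.965
    upstream_t6ss_rate: float = 0.7014
    divergence: float = 0.3
    end_truncation_rate: float = 0.05
    duplicate_contig_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "marker_rate", "toxin_rate", "pairing_rate", "t6ss_rate",
            "upstream_t6ss_rate", "divergence", "end_truncation_rate",
            "duplicate_contig_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genomes < 0 or self.mean_protein_len < 1:
            raise ValueError("counts must be non-negative")
        for name in ("contigs_per_genome", "genes_per_contig"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid range {name}={lo, hi}")


def emit_family_member(
    archetype: ReferenceArchetype,
    divergence: float,
    seed,
    region: tuple[int, int] | None = None,
) -> str:
    """Emit one diverged family member of the archetype.

    Each site substitutes with probability ``divergence`` (to a different
    residue, drawn from the background renormalised over the other 19
    letters); motif anchor columns substitute at one tenth of that rate.
    Length is preserved (no indels).  ``region`` restricts the emission to a
    1-based inclusive slice of the archetype.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence must be in [0,1), got {divergence}")
    rng = np.random.default_rng(seed)
    lo, hi = region if region is not None else (1, len(archetype.sequence))
    anchors = archetype.anchor_map
    aa = np.array(list(AMINO_ACIDS))
    out = []
    template = archetype.sequence[lo - 1 : hi]
    # draw all random numbers positionally so output is seed-stable
    u = rng.random(len(template))
    for offset, ch in enumerate(template):
        pos = lo + offset
        rate = divergence * (0.1 if pos in anchors else 1.0)
        if u[offset] < rate:
            i = AMINO_ACIDS.index(ch) if ch in AMINO_ACIDS else None
            p = BACKGROUND_VECTOR.copy()
            if i is not None:
                p[i] = 0.0
            p /= p.sum()
            out.append(str(rng.choice(aa, p=p)))
        else:
            out.append(ch)
    return "".join(out)


def emit_decoy(rng: np.random.Generator, length: int) -> str:
    """A background (i.i.d.) protein of the given length."""
    aa = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(aa, size=length, p=BACKGROUND_VECTOR))


def emit_nucleotide_alignment(
    taxa: Iterable[str],
    seed,
    length: int = 600,
    divergence: float = 0.05,
    gap_rate: float = 0.02,
) -> dict[str, str]:
    """A star-shaped aligned nucleotide matrix over the given taxa: every row
    descends from one random ancestor with per-site substitutions at
    ``divergence`` and per-site gaps at ``gap_rate`` (exercises the
    conserved-site filter)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ancestor = rng.choice(bases, size=length)
    rows: dict[str, str] = {}
    for taxon in taxa:
        row = ancestor.copy()
        sub = rng.random(length) < divergence
        for i in np.nonzero(sub)[0]:
            others = [b for b in "ACGT" if b != row[i]]
            row[i] = others[rng.integers(len(others))]
        gap = rng.random(length) < gap_rate
        row[gap] = "-"
        rows[str(taxon)] = "".join(row)
    return rows


# ---------------------------------------------------------------------------
# corpus generation


class _GenomeBuilder:
    """Accumulates CDS rows, sequences and truth rows for one assembly."""

    def __init__(self, assembly_id: str, organism: str):
        self.assembly_id = assembly_id
        self.organism = organism
        self.features: list[CdsFeature] = []
        self.proteome: dict[str, str] = {}
        self.truth: list[dict] = []
        self._counter = 0

    def new_protein_id(self) -> str:
        self._counter += 1
        return f"{self.assembly_id}_P{self._counter:04d}"


def _place_contig(
    builder: _GenomeBuilder,
    contig_id: str,
    genes: list[dict],
    rng: np.random.Generator,
    gaps: list[int] | None = None,
) -> list[int]:
    """Lay genes along a contig with uniform [1,200] bp intergenic gaps and
    0.8 strand persistence; returns the gap list used (for exact duplication).

    Each gene dict: {protein_id, sequence, product, strand (optional)}.
    """
    if gaps is None:
        gaps = [int(rng.integers(1, 201)) for _ in genes]
    pos = gaps[0]
    strand = "+" if rng.random() < 0.5 else "-"
    for idx, gene in enumerate(genes):
        if gene.get("strand") is None:
            if idx > 0 and rng.random() >= 0.8:
                strand = "+" if strand == "-" else "-"
            gene["strand"] = strand
        else:
            strand = gene["strand"]
        length_nt = 3 * len(gene["sequence"]) + 3
        start = pos
        end = pos + length_nt - 1
        builder.features.append(
            CdsFeature(
                assembly_id=builder.assembly_id,
                organism=builder.organism,
                contig_id=contig_id,
                feature_index=idx + 1,
                start=start,
                end=end,
                strand=gene["strand"],
                protein_id=gene["protein_id"],
                product=gene["product"],
                length_aa=len(gene["sequence"]),
            )
        )
        builder.proteome.setdefault(gene["protein_id"], gene["sequence"])
        pos = end + 1 + (gaps[idx + 1] if idx + 1 < len(gaps) else 100)
    return gaps


def generate_corpus(
    config: SimulationConfig,
) -> tuple[FeatureTable, dict[str, str], pd.DataFrame]:
    """Generate (feature table, proteome, ground truth) for the configured
    corpus.  Pure function of the config (including its seed)."""
    archetype = reference_archetype()
    all_features: list[CdsFeature] = []
    proteome: dict[str, str] = {}
    truth_rows: list[dict] = []

    for g in range(config.n_genomes):
        rng = np.random.default_rng([config.seed, g])
        assembly_id = f"SYNASM{g:05d}"
        builder = _GenomeBuilder(assembly_id, f"Synthetica simulata str. {g}")

        has_marker = rng.random() < config.marker_rate
        is_toxin = has_marker and rng.random() < config.toxin_rate
        paired = is_toxin and rng.random() < config.pairing_rate
        has_t6ss = rng.random() < config.t6ss_rate
        end_trunc = has_marker and rng.random() < config.end_truncation_rate
        duplicate = has_marker and rng.random() < config.duplicate_contig_rate
        upstream_t6ss = has_marker and rng.random() < config.upstream_t6ss_rate

        n_contigs = int(rng.integers(config.contigs_per_genome[0],
                                     config.contigs_per_genome[1] + 1))
        marker_contig = int(rng.integers(n_contigs)) if has_marker else -1
        t6ss_contig = int(rng.integers(n_contigs)) if has_t6ss else -1

        for c in range(n_contigs):
            contig_id = f"{assembly_id}_C{c + 1:02d}"
            n_genes = int(rng.integers(config.genes_per_contig[0],
                                       config.genes_per_contig[1] + 1))
            genes: list[dict] = []

            def decoy_gene() -> dict:
                pid = builder.new_protein_id()
                length = int(np.clip(rng.normal(config.mean_protein_len,
                                                0.3 * config.mean_protein_len),
                                     50, 3 * config.mean_protein_len))
                return {
                    "protein_id": pid,
                    "sequence": emit_decoy(rng, length),
                    "product": "hypothetical protein",
                    "strand": None,
                }

            # reserve a trailing run for the T6SS cluster and an interior (or,
            # under end-truncation, terminal) slot for the marker locus; the
            # two regions never overlap
            t6ss_cogs: list[str] = []
            if c == t6ss_contig:
                k = int(rng.integers(9, 12))
                order = rng.permutation(len(T6SS_CORE_COGS))[:k]
                t6ss_cogs = [T6SS_CORE_COGS[i] for i in order]
            k = len(t6ss_cogs)

            marker_slot = -1
            if c == marker_contig:
                n_genes = max(n_genes, 4 + k)
                if end_trunc:
                    # a cluster occupies the contig tail, so fall back to the
                    # first CDS when both land on this contig
                    marker_slot = 0 if (k or rng.random() < 0.5) else n_genes - 1
                else:
                    marker_slot = int(rng.integers(1, n_genes - k - 3 + 1))
            elif k:
                n_genes = max(n_genes, k + 1)

            t6ss_slot = n_genes - k if k else -1

            for _ in range(n_genes):
                genes.append(decoy_gene())

            if marker_slot >= 0:
                # terminal markers take the strand that keeps the downstream
                # side (in gene orientation) on-contig
                if marker_slot == 0:
                    marker_strand = "+"
                elif marker_slot == n_genes - 1:
                    marker_strand = "-"
                else:
                    marker_strand = "+" if rng.random() < 0.5 else "-"
                pid = builder.new_protein_id()
                seq = emit_family_member(
                    archetype, config.divergence,
                    rng.integers(0, 2**31 - 1),
                    region=(1, 449) if is_toxin else (1, archetype.pone_start - 1),
                )
                genes[marker_slot] = {
                    "protein_id": pid,
                    "sequence": seq,
                    "product": "polymorphic toxin effector" if is_toxin
                               else "marker-domain protein",
                    "strand": marker_strand,
                }
                survives = not end_trunc
                truth_rows.append(dict(
                    assembly_id=assembly_id, contig_id=contig_id,
                    protein_id=pid, planted_domain="FIX",
                    domain_start=archetype.fix_start,
                    domain_end=archetype.fix_end,
                    paired_immunity=False, genome_has_t6ss=has_t6ss,
                    should_survive=survives,
                ))
                if is_toxin:
                    truth_rows.append(dict(
                        assembly_id=assembly_id, contig_id=contig_id,
                        protein_id=pid, planted_domain="PoNe",
                        domain_start=archetype.pone_start,
                        domain_end=archetype.pone_end,
                        paired_immunity=paired, genome_has_t6ss=has_t6ss,
                        should_survive=survives,
                    ))

                # neighbour in gene orientation: slot+1 for '+', slot-1 for '-'
                down_slot = marker_slot + 1 if marker_strand == "+" else marker_slot - 1
                up_slot = marker_slot - 1 if marker_strand == "+" else marker_slot + 1
                if is_toxin and paired:
                    if not 0 <= down_slot < n_genes:
                        raise AssertionError("paired toxin lacks a downstream slot")
                    ipid = builder.new_protein_id()
                    genes[down_slot] = {
                        "protein_id": ipid,
                        "sequence": emit_decoy(rng, int(rng.integers(110, 160))),
                        "product": "immunity protein",
                        "strand": marker_strand,
                    }
                    truth_rows.append(dict(
                        assembly_id=assembly_id, contig_id=contig_id,
                        protein_id=ipid, planted_domain="DUF1911",
                        domain_start=5, domain_end=90,
                        paired_immunity=False, genome_has_t6ss=has_t6ss,
                        should_survive=True,
                    ))
                    if rng.random() < 0.5:
                        truth_rows.append(dict(
                            assembly_id=assembly_id, contig_id=contig_id,
                            protein_id=ipid, planted_domain="DUF1910",
                            domain_start=91,
                            domain_end=len(genes[down_slot]["sequence"]),
                            paired_immunity=False, genome_has_t6ss=has_t6ss,
                            should_survive=True,
                        ))
                elif is_toxin and 0 <= down_slot < n_genes:
                    # unpaired: downstream gene is opposite strand half the
                    # time, a plain same-strand decoy otherwise
                    genes[down_slot]["strand"] = (
                        ("-" if marker_strand == "+" else "+")
                        if rng.random() < 0.5 else marker_strand
                    )
                if 0 <= up_slot < n_genes and up_slot != down_slot:
                    # the upstream neighbor always shares the marker's strand
                    # (so the configured upstream_t6ss_rate is exactly the
                    # T6SS-component share among loci with an upstream gene)
                    genes[up_slot]["strand"] = marker_strand
                    if upstream_t6ss:
                        dom = UPSTREAM_T6SS_DOMAINS[
                            int(rng.choice(3, p=[0.6, 0.25, 0.15]))
                        ]
                        genes[up_slot]["product"] = f"T6SS component {dom}"
                        truth_rows.append(dict(
                            assembly_id=assembly_id, contig_id=contig_id,
                            protein_id=genes[up_slot]["protein_id"],
                            planted_domain=dom,
                            domain_start=1,
                            domain_end=len(genes[up_slot]["sequence"]),
                            paired_immunity=False, genome_has_t6ss=has_t6ss,
                            should_survive=True,
                        ))

            if t6ss_slot >= 0:
                for j, cog in enumerate(t6ss_cogs):
                    slot = t6ss_slot + j
                    if genes[slot]["product"] != "hypothetical protein":
                        continue  # never overwrite a planted gene
                    genes[slot]["product"] = f"T6SS core component {cog}"
                    truth_rows.append(dict(
                        assembly_id=assembly_id, contig_id=contig_id,
                        protein_id=genes[slot]["protein_id"],
                        planted_domain=cog,
                        domain_start=1,
                        domain_end=len(genes[slot]["sequence"]),
                        paired_immunity=False, genome_has_t6ss=has_t6ss,
                        should_survive=True,
                    ))

            gaps = _place_contig(builder, contig_id, genes, rng)

            if c == marker_contig and duplicate and marker_slot >= 0:
                dup_id = f"{contig_id}_dup"
                exact = rng.random() < 0.5
                # the dedup rule compares the same-strand downstream gene;
                # without one, both copies carry an empty signature and the
                # duplicate is collapsed regardless of coordinate perturbation
                s = genes[marker_slot]["strand"]
                adj = marker_slot + 1 if s == "+" else marker_slot - 1
                has_down = (
                    0 <= adj < n_genes and genes[adj]["strand"] == s
                )
                dedupable = exact or not has_down
                dup_genes = [dict(gene) for gene in genes]
                dup_gaps = list(gaps)
                if not exact and has_down:
                    # perturb the gap downstream of the marker so the dedup
                    # rule sees a different intergenic distance
                    bump = marker_slot + 1 if s == "+" else marker_slot
                    dup_gaps[bump] += int(rng.integers(1, 51))
                _place_contig(builder, dup_id, dup_genes, rng, gaps=dup_gaps)
                # dedupable copies are removed (the original contig sorts
                # first); perturbed copies survive on both contigs
                for row in [r for r in truth_rows
                            if r["contig_id"] == contig_id
                            and r["planted_domain"] in ("FIX", "PoNe")]:
                    truth_rows.append({
                        **row, "contig_id": dup_id,
                        "should_survive": row["should_survive"] and not dedupable,
                    })

        all_features.extend(builder.features)
        proteome.update(builder.proteome)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(
        ["assembly_id", "contig_id", "protein_id", "planted_domain"]
    ).reset_index(drop=True)
    return FeatureTable(all_features), proteome, truth


def annotations_from_truth(truth: pd.DataFrame, proteome: dict[str, str]) -> pd.DataFrame:
    """Derive the external domain-annotation table the pipeline consumes
    (immunity domains, T6SS component COGs, upstream-component labels) from
    the ground truth.  FIX/PoNe rows are excluded: those are what the
    package's own profile scan must find."""
    rows = []
    seen = set()
    for r in truth.itertuples(index=False):
        if r.planted_domain in ("FIX", "PoNe", "decoy"):
            continue
        key = (r.protein_id, r.planted_domain)
        if key in seen:
            continue
        seen.add(key)
        rows.append(dict(
            protein_id=r.protein_id, domain_name=r.planted_domain,
            start=r.domain_start, end=r.domain_end,
            score=float("nan"), expect=float("nan"), source="external-table",
        ))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "domain_name", "start", "end", "score",
                 "expect", "source"],
    )


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("domain_start", "domain_end"):
        df[col] = df[col].astype(int)
    for col in ("paired_immunity", "genome_has_t6ss", "should_survive"):
        df[col] = df[col].map({"True": True, "False": False})
    return df
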