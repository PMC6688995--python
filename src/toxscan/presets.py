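"""Deterministic fixture presets mirroring the published corpus margins.

The discovery study's full hit universe depends on a reference-database
snapshot that cannot be rebuilt at desk scale.  These presets construct
synthetic locus tables with exactly the published marginal counts, so the
neighborhood, architecture and co-occurrence statistics can be recomputed
from first principles by the same code paths that process real tables:

* 1546 toxin loci, 1389 of them with a same-strand downstream immunity
  (DUF1911) gene  -> pairing 89.84%;
* 5000 marker loci with an upstream neighbor, 3507 of them T6SS components
  (VgrG/TssL/DUF4123)  -> upstream share 70.14%;
* 2881 marker proteins, 107 of them with an N-terminal PAAR or DUF4280
  delivery domain  -> architecture share 3.71%;
* 1000 marker genomes, 965 of them with >= 9 of the 11 T6SS core
  components  -> co-occurrence 96.50% (> 96%).
"""

from __future__ import annotations

import itertools

import pandas as pd

from .genome_io import CdsFeature, FeatureTable
from .profile_search import DomainHit
from .t6ss_cooccurrence import CORE_COGS, T6SSCall

_ANN_COLUMNS = ["protein_id", "domain_name", "start", "end", "score",
                "expect", "source"]


def _ann_row(pid: str, name: str, start: int = 1, end: int = 100) -> dict:
    return dict(protein_id=pid, domain_name=name, start=start, end=end,
                score=float("nan"), expect=float("nan"),
                source="external-table")


def preset_paper_pairing() -> tuple[FeatureTable, pd.DataFrame, list[CdsFeature]]:
    """1546 single-toxin contigs; the first 1389 carry a same-strand
    downstream DUF1911 gene, the rest a same-strand decoy without one."""
    features: list[CdsFeature] = []
    ann_rows: list[dict] = []
    toxin_loci: list[CdsFeature] = []
    for i in range(1546):
        asm = f"PAIRASM{i:05d}"
        contig = f"{asm}_C01"
        paired = i < 1389
        specs = [
            ("P0001", "hypothetical protein"),
            ("P0002", "polymorphic toxin effector"),
            ("P0003", "immunity protein" if paired else "hypothetical protein"),
        ]
        pos = 1
        for idx, (suffix, product) in enumerate(specs):
            length_aa = 300
            start, end = pos, pos + 3 * length_aa + 2
            features.append(
                CdsFeature(
                    assembly_id=asm, organism="Synthetica pairata",
                    contig_id=contig, feature_index=idx + 1,
                    start=start, end=end, strand="+",
                    protein_id=f"{asm}_{suffix}", product=product,
                    length_aa=length_aa,
                )
            )
            pos = end + 58
        toxin_loci.append(features[-2])
        if paired:
            ann_rows.append(_ann_row(f"{asm}_P0003", "DUF1911"))
            if i % 2 == 0:
                ann_rows.append(_ann_row(f"{asm}_P0003", "DUF1910", 101, 180))
    table = FeatureTable(features)
    return table, pd.DataFrame(ann_rows, columns=_ANN_COLUMNS), toxin_loci


def preset_paper_upstream() -> tuple[FeatureTable, pd.DataFrame, list[CdsFeature]]:
    """5000 marker loci, each with a same-strand upstream gene; 3507 of the
    upstream genes carry a T6SS-component label (cycled VgrG/TssL/DUF4123)."""
    features: list[CdsFeature] = []
    ann_rows: list[dict] = []
    marker_loci: list[CdsFeature] = []
    labels = itertools.cycle(["VgrG", "TssL", "DUF4123"])
    for i in range(5000):
        asm = f"UPASM{i:05d}"
        contig = f"{asm}_C01"
        pos = 1
        for idx, suffix in enumerate(("P0001", "P0002", "P0003")):
            length_aa = 250
            start, end = pos, pos + 3 * length_aa + 2
            features.append(
                CdsFeature(
                    assembly_id=asm, organism="Synthetica adjacentia",
                    contig_id=contig, feature_index=idx + 1,
                    start=start, end=end, strand="+",
                    protein_id=f"{asm}_{suffix}",
                    product="hypothetical protein", length_aa=length_aa,
                )
            )
            pos = end + 100
        marker_loci.append(features[-2])
        if i < 3507:
            ann_rows.append(_ann_row(f"{asm}_P0001", next(labels)))
        else:
            ann_rows.append(_ann_row(f"{asm}_P0001", "DUF9999"))
    table = FeatureTable(features)
    return table, pd.DataFrame(ann_rows, columns=_ANN_COLUMNS), marker_loci


def preset_paper_architecture() -> tuple[list[DomainHit], pd.DataFrame]:
    """2881 marker-domain proteins (hit at 43-121); 107 carry an N-terminal
    PAAR or DUF4280 annotation."""
    hits: list[DomainHit] = []
    ann_rows: list[dict] = []
    for i in range(2881):
        pid = f"FIXPROT{i:05d}"
        hits.append(
            DomainHit(protein_id=pid, profile="FIX", start=43, end=121,
                      score=100.0, expect=1e-30)
        )
        if i < 107:
            ann_rows.append(
                _ann_row(pid, "PAAR" if i % 2 == 0 else "DUF4280", 1, 40)
            )
    return hits, pd.DataFrame(ann_rows, columns=_ANN_COLUMNS)


def preset_paper_cooccurrence() -> tuple[list[str], dict[str, T6SSCall]]:
    """1000 marker-bearing genomes; 965 encode >= 9 core components (cycled
    9/10/11), the rest 8."""
    cogs = sorted(CORE_COGS)
    assemblies: list[str] = []
    calls: dict[str, T6SSCall] = {}
    for i in range(1000):
        asm = f"COASM{i:05d}"
        assemblies.append(asm)
        n = (9, 10, 11)[i % 3] if i < 965 else 8
        calls[asm] = T6SSCall(
            assembly_id=asm,
            components_present=frozenset(cogs[:n]),
            vgrg_present=(i % 2 == 0),
        )
    return assemblies, calls
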