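"""Readers and writers for the formats the pipeline touches.

Conventions used everywhere in the package:

* coordinates are 1-based and inclusive (NCBI feature-table style);
* strand is ``+`` or ``-``; minus-strand CDS are stored with start <= end;
* tables are tab-separated UTF-8 with a header row and ``.`` for missing
  values;
* protein FASTA is wrapped at 60 characters.

All readers validate and reject malformed records rather than coercing them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import sanitize_protein

FEATURE_COLUMNS = [
    "assembly_id",
    "organism",
    "contig_id",
    "feature_index",
    "start",
    "end",
    "strand",
    "protein_id",
    "product",
    "length_aa",
]

ANNOTATION_COLUMNS = [
    "protein_id",
    "domain_name",
    "start",
    "end",
    "score",
    "expect",
    "source",
]

MISSING = "."


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class CdsFeature:
    """One strand-aware CDS annotation on a contig."""

    assembly_id: str
    organism: str
    contig_id: str
    feature_index: int
    start: int
    end: int
    strand: str
    protein_id: str
    product: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.start > self.end:
            raise FormatError(
                f"start {self.start} > end {self.end} for {self.protein_id}"
            )
        if self.start < 1:
            raise FormatError(f"coordinates must be 1-based, got {self.start}")


class FeatureTable:
    """Collection of CdsFeature rows with per-contig ordering guarantees.

    Rows are kept sorted by (assembly, contig, start); ``feature_index`` is the
    1-based ordinal of a CDS within its contig by start coordinate.
    """

    def __init__(self, features: Iterable[CdsFeature]):
        feats = sorted(
            features, key=lambda f: (f.assembly_id, f.contig_id, f.start)
        )
        self.features: list[CdsFeature] = feats
        self._by_contig: dict[tuple[str, str], list[CdsFeature]] = {}
        for f in feats:
            self._by_contig.setdefault((f.assembly_id, f.contig_id), []).append(f)
        for key, group in self._by_contig.items():
            idx = [g.feature_index for g in group]
            if idx != sorted(idx) or len(set(idx)) != len(idx):
                raise FormatError(
                    f"feature_index not strictly increasing with start on "
                    f"contig {key[1]} of {key[0]}"
                )
        self._by_protein: dict[tuple[str, str], list[CdsFeature]] = {}
        for f in feats:
            self._by_protein.setdefault((f.assembly_id, f.protein_id), []).append(f)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.features == other.features

    def contig(self, assembly_id: str, contig_id: str) -> list[CdsFeature]:
        return self._by_contig.get((assembly_id, contig_id), [])

    def contigs(self) -> list[tuple[str, str]]:
        return sorted(self._by_contig)

    def assemblies(self) -> list[str]:
        return sorted({f.assembly_id for f in self.features})

    def lookup_protein(self, assembly_id: str, protein_id: str) -> list[CdsFeature]:
        """All CDS rows for a protein in an assembly (more than one only for
        deliberate duplicate contigs)."""
        return self._by_protein.get((assembly_id, protein_id), [])

    def at(self, assembly_id: str, contig_id: str, feature_index: int) -> CdsFeature | None:
        for f in self.contig(assembly_id, contig_id):
            if f.feature_index == feature_index:
                return f
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(f, c) for c in FEATURE_COLUMNS] for f in self.features],
            columns=FEATURE_COLUMNS,
        )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing column {col!r}")


def read_feature_table(path: str | Path, permissive: bool = False) -> FeatureTable:
    """Read a feature-table TSV.

    In permissive mode a row whose start exceeds its end (the convention some
    annotation exports use for minus-strand genes) is normalised to
    (min, max, strand '-'); in strict mode it is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, FEATURE_COLUMNS, "feature table")
    feats = []
    for row in df.itertuples(index=False):
        start, end, strand = int(row.start), int(row.end), row.strand
        if start > end:
            if permissive:
                start, end, strand = end, start, "-"
            else:
                raise FormatError(
                    f"start {start} > end {end} for {row.protein_id} "
                    "(use permissive=True to normalize)"
                )
        feats.append(
            CdsFeature(
                assembly_id=row.assembly_id,
                organism=row.organism,
                contig_id=row.contig_id,
                feature_index=int(row.feature_index),
                start=start,
                end=end,
                strand=strand,
                protein_id=row.protein_id,
                product=row.product,
                length_aa=int(row.length_aa),
            )
        )
    return FeatureTable(feats)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a domain-annotation TSV (precomputed or internal-scan calls)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, "annotation table")
    df = df.copy()
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    for col in ("score", "expect"):
        df[col] = df[col].replace(MISSING, "nan").astype(float)
    if (df["start"] < 1).any() or (df["start"] > df["end"]).any():
        raise FormatError("annotation coordinates must satisfy 1 <= start <= end")
    if (df["expect"].dropna() < 0).any():
        raise FormatError("negative expect value")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df[ANNOTATION_COLUMNS].copy()
    out["score"] = out["score"].map(lambda v: MISSING if pd.isna(v) else f"{v:.3f}")
    out["expect"] = out["expect"].map(lambda v: MISSING if pd.isna(v) else f"{v:.3g}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered {id: sequence} mapping.

    Duplicate headers are rejected; non-canonical letters map to X.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        proteome[rec.id] = sanitize_protein(str(rec.seq))
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gaps allowed); all rows must share one length."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise FormatError("alignment rows differ in length")
    return rows


def write_aligned_fasta(rows: Mapping[str, str], path: str | Path) -> None:
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise FormatError("alignment rows differ in length")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylogeny.PhyloTree (or compatible node) to Newick with
    6-decimal branch lengths."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree.to_newick())
        fh.write("\n")
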