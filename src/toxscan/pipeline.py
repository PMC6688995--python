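"""End-to-end orchestration: simulate -> scan -> curate -> cluster ->
neighbors -> t6ss -> logo -> tree, as one seeded, logged run that writes a
report bundle with a content-hash manifest.

All randomness fans out from one pipeline seed through documented per-stage
child seeds, so identical configuration yields byte-identical bundles.
Floats are printed with fixed precision (percentages 2 dp, identities 3 dp,
branch lengths 6 dp) and files are LF-normalized for the same reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation, flank_clustering, neighborhood, phylogeny
from . import synthetic_data as synth
from .genome_io import (
    MISSING,
    FeatureTable,
    write_annotations,
    write_aligned_fasta,
    write_fasta,
    write_feature_table,
    write_newick,
)
from .hit_curation import CurationConfig, CurationReport, curate
from .profile_search import DomainHit, SearchConfig, iterate_search
from .t6ss_cooccurrence import calls_to_frame, classify_genomes, cooccurrence

logger = logging.getLogger("toxscan")

#: fixed odd multiplier for per-stage child-seed derivation (documented)
_SEED_STEP = 9973


def child_seed(seed: int, stage_index: int) -> int:
    return (seed * _SEED_STEP + stage_index) % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "toxscan_run"
    seed: int = 7
    simulation: synth.SimulationConfig | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    identity_threshold: float = 0.40
    length_ratio: float = 0.50
    skip_opposite: bool = False
    include_vgrg: bool = False
    tau_cons: float = conservation.DEFAULT_TAU_CONS
    motif_window: tuple[int, int] = (294, 354)
    tree_max_taxa: int = 40

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = synth.SimulationConfig(seed=child_seed(self.seed, 1))


@dataclass
class ReportBundle:
    out_dir: Path
    kept_fix: CurationReport
    kept_pone: CurationReport
    pairing: neighborhood.PairingSummary
    upstream_share: float | None
    cooccurrence: tuple[int, int, float | None]
    motif: conservation.MotifConsensus | None
    tree_newick: str | None
    manifest: dict


def _fmt_pct(value: float | None) -> str:
    return MISSING if value is None else f"{value:.2f}"


def _hits_frame(report: CurationReport) -> pd.DataFrame:
    rows = [
        dict(
            assembly_id=lh.feature.assembly_id,
            contig_id=lh.feature.contig_id,
            protein_id=lh.hit.protein_id,
            profile=lh.hit.profile,
            start=lh.hit.start,
            end=lh.hit.end,
            bits=f"{lh.hit.score:.3f}",
            expect=f"{lh.hit.expect:.3g}",
        )
        for lh in report.kept
    ]
    return pd.DataFrame(
        rows,
        columns=["assembly_id", "contig_id", "protein_id", "profile",
                 "start", "end", "bits", "expect"],
    )


def _removed_frame(report: CurationReport) -> pd.DataFrame:
    rows = [
        dict(
            assembly_id=lh.feature.assembly_id,
            contig_id=lh.feature.contig_id,
            protein_id=lh.hit.protein_id,
            profile=lh.hit.profile,
            reason=reason,
        )
        for lh, reason in report.removed
    ]
    return pd.DataFrame(
        rows,
        columns=["assembly_id", "contig_id", "protein_id", "profile", "reason"],
    )


def _clusters_frame(clusters: list[flank_clustering.Cluster]) -> pd.DataFrame:
    rows = [
        dict(
            cluster_id=c.cluster_id,
            representative=c.representative,
            protein_id=pid,
            identity=f"{ident:.3f}",
        )
        for c in clusters
        for pid, ident in c.members
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "representative", "protein_id", "identity"]
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_all(config: PipelineConfig) -> ReportBundle:
    """Run every stage on a simulated corpus and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    archetype = synth.reference_archetype()

    logger.info("simulate: %d genomes", config.simulation.n_genomes)
    features, proteome, truth = synth.generate_corpus(config.simulation)
    annotations = synth.annotations_from_truth(truth, proteome)
    write_feature_table(features, out / "features.tsv")
    write_fasta(proteome, out / "proteome.fasta")
    synth.write_ground_truth(truth, out / "truth.tsv")
    write_annotations(annotations, out / "annotations.tsv")

    # --- iterative profile search for the marker and toxin domains
    searches: dict[str, dict[str, DomainHit]] = {}
    for idx, (name, seed_seq) in enumerate(
        [("FIX", archetype.fix_region()), ("PoNe", archetype.pone_region())]
    ):
        if proteome:
            cfg = SearchConfig(
                iterations=config.search.iterations,
                per_iteration_cap=config.search.per_iteration_cap,
                inclusion_expect=config.search.inclusion_expect,
                report_expect=config.search.report_expect,
                decoy_count=config.search.decoy_count,
                seed=child_seed(config.seed, 10 + idx),
                pseudocount=config.search.pseudocount,
            )
            result = iterate_search([seed_seq], proteome, cfg, name=name)
            searches[name] = result.hits
            logger.info("scan %s: %d hits", name, len(result.hits))
        else:
            searches[name] = {}

    reports: dict[str, CurationReport] = {}
    for name in ("FIX", "PoNe"):
        report = curate(searches[name].values(), features, config.curation)
        reports[name] = report
        logger.info(
            "curate %s: kept %d, removed %d", name, len(report.kept),
            len(report.removed),
        )
        _write_tsv(_hits_frame(report), out / f"kept_{name.lower()}.tsv")
        _write_tsv(_removed_frame(report), out / f"removed_{name.lower()}.tsv")

    # --- flank clustering: C-flanks of marker hits, N-flanks of toxin hits
    for name, side in (("FIX", "C"), ("PoNe", "N")):
        flanks = []
        seen = set()
        for lh in reports[name].kept:
            if lh.hit.protein_id in seen:
                continue
            seen.add(lh.hit.protein_id)
            flank = flank_clustering.extract_flank(
                proteome[lh.hit.protein_id], lh.hit, side
            )
            if flank is None:
                logger.info(
                    "flank %s: %s abuts the terminus, skipped", name,
                    lh.hit.protein_id,
                )
                continue
            flanks.append(flank)
        clusters = (
            flank_clustering.greedy_cluster(
                flanks, config.identity_threshold, config.length_ratio
            )
            if flanks
            else []
        )
        _write_tsv(_clusters_frame(clusters), out / f"clusters_{name.lower()}.tsv")
        logger.info("cluster %s: %d clusters / %d flanks", name, len(clusters),
                    len(flanks))

    # --- neighborhood pairing and upstream summary
    toxin_loci = [lh.feature for lh in reports["PoNe"].kept]
    pairing, pairs_table = neighborhood.pair_immunity(
        toxin_loci, features, annotations, config.skip_opposite
    )
    _write_tsv(pairs_table, out / "pairs.tsv")
    _write_tsv(
        pd.DataFrame(
            [dict(
                n_toxin_loci=pairing.n_toxin_loci,
                n_paired=pairing.n_paired,
                percent_paired=_fmt_pct(pairing.percent_paired),
            )]
        ),
        out / "pairing_summary.tsv",
    )

    marker_loci = [lh.feature for lh in reports["FIX"].kept]
    upstream_table, upstream_share = neighborhood.summarize_upstream_domains(
        marker_loci, features, annotations, config.skip_opposite
    )
    _write_tsv(upstream_table, out / "upstream_summary.tsv")

    # --- T6SS calls and marker co-occurrence
    calls = classify_genomes(features, annotations, config.include_vgrg)
    _write_tsv(calls_to_frame(calls), out / "t6ss_calls.tsv")
    marker_assemblies = sorted({f.assembly_id for f in marker_loci})
    cooc = (
        cooccurrence(marker_assemblies, calls)
        if marker_assemblies
        else (0, 0, None)
    )
    _write_tsv(
        pd.DataFrame(
            [dict(n_marker_genomes=cooc[0], n_with_t6ss=cooc[1],
                  percent=_fmt_pct(cooc[2]))]
        ),
        out / "cooccurrence.tsv",
    )

    # --- conservation logo + motif over toxin-domain members
    motif = None
    toxin_members = {
        lh.hit.protein_id: proteome[lh.hit.protein_id]
        for lh in reports["PoNe"].kept
    }
    if toxin_members:
        msa = conservation.anchor_msa(
            archetype.sequence, toxin_members, reference_id=archetype.protein_id
        )
        logo = conservation.logo_table(msa, window=config.motif_window)
        logo_rows = [
            dict(
                position=col.position,
                n=sum(col.counts.values()),
                entropy=f"{col.entropy:.4f}",
                information=f"{col.information:.4f}",
                top_residue=max(sorted(col.counts), key=col.counts.get),
            )
            for col in logo
        ]
        _write_tsv(
            pd.DataFrame(
                logo_rows,
                columns=["position", "n", "entropy", "information",
                         "top_residue"],
            ),
            out / "logo.tsv",
        )
        motif = conservation.consensus_motif(
            msa, tau_cons=config.tau_cons, window=config.motif_window
        )
        (out / "motif.txt").write_text(str(motif) + "\n", encoding="utf-8")
        logger.info("motif: %s", motif)
    else:
        _write_tsv(
            pd.DataFrame(columns=["position", "n", "entropy", "information",
                                  "top_residue"]),
            out / "logo.tsv",
        )
        (out / "motif.txt").write_text("", encoding="utf-8")

    # --- distance phylogeny of marker-bearing genomes
    tree_newick = None
    taxa = marker_assemblies[: config.tree_max_taxa]
    if len(taxa) >= 2:
        aln = synth.emit_nucleotide_alignment(
            taxa, child_seed(config.seed, 20)
        )
        write_aligned_fasta(aln, out / "marker_genomes.aln.fasta")
        dm = phylogeny.mismatch_matrix(aln)
        tree = phylogeny.nj_tree(dm)
        write_newick(tree, out / "tree.nwk")
        tree_newick = tree.to_newick()
    else:
        (out / "tree.nwk").write_text("", encoding="utf-8")

    manifest = _build_manifest(config, out)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return ReportBundle(
        out_dir=out,
        kept_fix=reports["FIX"],
        kept_pone=reports["PoNe"],
        pairing=pairing,
        upstream_share=upstream_share,
        cooccurrence=cooc,
        motif=motif,
        tree_newick=tree_newick,
        manifest=manifest,
    )


def _build_manifest(config: PipelineConfig, out: Path) -> dict:
    hashes = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    cfg = asdict(config)
    return {"config": cfg, "seed": config.seed, "files": hashes}
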