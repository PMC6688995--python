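"""Strand-aware adjacency, effector/immunity pairing, upstream summaries and
architecture classification."""

import math

import pandas as pd
import pytest

from toxscan.genome_io import CdsFeature, FeatureTable
from toxscan.neighborhood import (
    ArchitectureClass,
    adjacent_locus,
    classify_architecture,
    pair_immunity,
    round_percent,
    signal_peptide_consensus,
    summarize_upstream_domains,
)
from toxscan.presets import preset_paper_pairing, preset_paper_upstream
from toxscan.profile_search import DomainHit
from toxscan.synthetic_data import SimulationConfig, generate_corpus


def feature(index, strand, pid, contig="C1"):
    start = index * 1000
    return CdsFeature(
        assembly_id="ASM1", organism="Synthetica", contig_id=contig,
        feature_index=index, start=start, end=start + 500, strand=strand,
        protein_id=pid, product="hypothetical protein", length_aa=160,
    )


def ann(pid, domain, start=1, end=100):
    return dict(protein_id=pid, domain_name=domain, start=start, end=end,
                score=float("nan"), expect=float("nan"),
                source="external-table")


class TestAdjacency:
    def test_plus_strand_downstream_is_next_index(self):
        table = FeatureTable([feature(5, "+", "A"), feature(6, "+", "B")])
        focal = table.features[0]
        assert adjacent_locus(table, focal, "down").protein_id == "B"
        assert adjacent_locus(table, focal, "up") is None

    def test_opposite_strand_neighbor_is_none(self):
        table = FeatureTable([feature(5, "+", "A"), feature(6, "-", "B")])
        assert adjacent_locus(table, table.features[0], "down") is None

    def test_skip_opposite_steps_over(self):
        table = FeatureTable(
            [feature(5, "+", "A"), feature(6, "-", "B"), feature(7, "+", "C")]
        )
        found = adjacent_locus(
            table, table.features[0], "down", skip_opposite=True
        )
        assert found.protein_id == "C"

    def test_minus_strand_at_contig_start_has_no_downstream(self):
        table = FeatureTable([feature(1, "-", "A"), feature(2, "-", "B")])
        assert adjacent_locus(table, table.features[0], "down") is None
        assert adjacent_locus(table, table.features[0], "up").protein_id == "B"

    def test_adjacency_antisymmetric(self, small_corpus):
        table, _, _ = small_corpus
        for focal in table.features[:300]:
            down = adjacent_locus(table, focal, "down")
            if down is not None:
                assert adjacent_locus(table, down, "up") == focal


class TestPairing:
    def test_paper_pairing_preset_reports_8984_percent(self):
        table, annotations, toxin_loci = preset_paper_pairing()
        summary, _ = pair_immunity(toxin_loci, table, annotations)
        assert (summary.n_toxin_loci, summary.n_paired) == (1546, 1389)
        assert summary.percent_paired == 89.84

    def test_zero_loci_percent_undefined(self):
        table, annotations, _ = preset_paper_pairing()
        summary, per_locus = pair_immunity([], table, annotations)
        assert summary.percent_paired is None and per_locus.empty

    def test_percent_recomputes_from_counts(self):
        assert round_percent(1389, 1546) == 89.84
        assert round_percent(1, 3) == 33.33
        assert round_percent(1, 8) == 12.50

    def test_ground_truth_cross_check(self, small_corpus):
        """n_paired equals the truth table's paired count exactly (over loci
        whose downstream neighbor is intact)."""
        from toxscan.synthetic_data import annotations_from_truth

        table, proteome, truth = small_corpus
        annotations = annotations_from_truth(truth, proteome)
        pone = truth[truth.planted_domain == "PoNe"]
        loci = []
        for row in pone.itertuples(index=False):
            loci.extend(
                f for f in table.lookup_protein(row.assembly_id, row.protein_id)
                if f.contig_id == row.contig_id
            )
        summary, per_locus = pair_immunity(loci, table, annotations)
        assert summary.n_paired == int(pone.paired_immunity.sum())
        merged = per_locus.merge(
            pone, on=["assembly_id", "contig_id", "protein_id"]
        )
        assert (merged.paired == merged.paired_immunity).all()


class TestUpstreamSummary:
    def test_paper_upstream_preset_reports_7014_percent(self):
        table, annotations, marker_loci = preset_paper_upstream()
        _, share = summarize_upstream_domains(marker_loci, table, annotations)
        assert share == 70.14

    def test_no_upstream_neighbors_empty_table(self):
        table = FeatureTable([feature(1, "+", "A"), feature(2, "+", "B")])
        annotations = pd.DataFrame([ann("A", "VgrG")])
        summary, share = summarize_upstream_domains(
            [table.features[0]], table, annotations
        )
        assert summary.empty and share is None

    def test_all_vgrg_upstream_is_100_percent(self):
        table = FeatureTable([feature(1, "+", "UP"), feature(2, "+", "M")])
        annotations = pd.DataFrame([ann("UP", "VgrG")])
        _, share = summarize_upstream_domains(
            [table.features[1]], table, annotations
        )
        assert share == 100.0

    def test_configured_70_percent_rate_recovered(self):
        """On a clean corpus the upstream T6SS-component share falls in the
        99% binomial CI of the configured 0.70."""
        from toxscan.synthetic_data import annotations_from_truth

        cfg = SimulationConfig(
            seed=21, n_genomes=250, marker_rate=1.0, upstream_t6ss_rate=0.70,
            end_truncation_rate=0.0, duplicate_contig_rate=0.0,
        )
        table, proteome, truth = generate_corpus(cfg)
        annotations = annotations_from_truth(truth, proteome)
        fix = truth[truth.planted_domain == "FIX"]
        loci = []
        for row in fix.itertuples(index=False):
            loci.extend(
                f for f in table.lookup_protein(row.assembly_id, row.protein_id)
                if f.contig_id == row.contig_id
            )
        _, share = summarize_upstream_domains(loci, table, annotations)
        n = len(loci)
        half = 100 * 2.576 * math.sqrt(0.7 * 0.3 / n)
        assert abs(share - 70.0) <= half


class TestArchitecture:
    def toxin_hit(self):
        return DomainHit(protein_id="P", profile="PoNe", start=283, end=449,
                         score=100.0, expect=1e-20)

    def test_lxg_delivery_domain(self):
        annotations = pd.DataFrame([ann("P", "LXG", 1, 200)])
        assert classify_architecture(self.toxin_hit(), annotations).label == "LXG"

    def test_delivery_domain_must_be_n_terminal(self):
        annotations = pd.DataFrame([ann("P", "PAAR", 300, 360)])
        assert classify_architecture(self.toxin_hit(), annotations).label == "none"

    def test_signal_peptide_requires_both_predictors(self):
        both = pd.DataFrame([ann("P", "SP_Phobius", 1, 25),
                             ann("P", "SP_SignalP", 1, 23)])
        one = pd.DataFrame([ann("P", "SP_Phobius", 1, 25)])
        assert classify_architecture(self.toxin_hit(), both).label == "SP"
        assert classify_architecture(self.toxin_hit(), one).label == "none"

    def test_precedence_paar_before_sp(self):
        annotations = pd.DataFrame([
            ann("P", "SP_Phobius", 1, 25), ann("P", "SP_SignalP", 1, 23),
            ann("P", "PAAR", 30, 120),
        ])
        assert classify_architecture(self.toxin_hit(), annotations).label == "PAAR"

    @pytest.mark.parametrize(
        "phobius,signalp,expected",
        [(True, True, True), (True, False, False),
         (False, True, False), (False, False, False)],
    )
    def test_consensus_rule(self, phobius, signalp, expected):
        assert signal_peptide_consensus(phobius, signalp) is expected
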