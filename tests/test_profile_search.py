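"""PSSM math, window scanning, empirical calibration and iterative search."""

import math

import numpy as np
import pytest

from toxscan._alphabet import AMINO_ACIDS
from toxscan.profile_search import (
    SearchConfig,
    build_pssm,
    calibrate_expect,
    generate_decoys,
    iterate_search,
    scan_protein,
    window_scores,
)
from toxscan.synthetic_data import emit_family_member

UNIFORM = {a: 0.05 for a in AMINO_ACIDS}


class TestBuildPssm:
    def test_background_frequency_scores_zero(self):
        # a column whose pseudocounted frequency equals the background has
        # log-odds 0: achieved exactly by an all-gap column
        pssm = build_pssm(["-"], alpha=1.0, background=UNIFORM)
        assert np.allclose(pssm.scores[0, :20], 0.0)

    def test_ten_glycines_uniform_background(self):
        # f_G = (10 + 0.05)/11, score_G = log2(18.2727) = 4.192 bits;
        # any other residue: log2((0.05/11)/0.05) = -3.459 bits
        pssm = build_pssm(["G"] * 10, alpha=1.0, background=UNIFORM)
        assert pssm.score(0, "G") == pytest.approx(4.192, abs=5e-4)
        assert pssm.score(0, "A") == pytest.approx(-3.459, abs=5e-4)

    def test_column_frequencies_form_simplex(self, archetype):
        pssm = build_pssm([archetype.pone_region()])
        assert np.allclose(pssm.freqs.sum(axis=1), 1.0)
        assert np.isfinite(pssm.scores).all()

    def test_single_row_toxin_region_has_167_columns(self, archetype):
        pssm = build_pssm([archetype.pone_region()])
        assert pssm.length == 167

    def test_rebuild_is_bit_identical(self, archetype):
        rows = [archetype.pone_region(), archetype.pone_region()]
        assert build_pssm(rows) == build_pssm(list(rows))

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_pssm([])
        with pytest.raises(ValueError):
            build_pssm(["AC"], alpha=0.0)


class TestScanProtein:
    def test_short_protein_yields_no_hits(self, archetype):
        pssm = build_pssm([archetype.pone_region()])
        assert scan_protein("ACDEFGHIK", pssm) == []

    def test_archetype_self_scan_recovers_planted_coordinates(self, archetype):
        pssm = build_pssm([archetype.pone_region()], name="PoNe")
        hits = scan_protein(archetype.sequence, pssm)
        assert (hits[0].start, hits[0].end) == (
            archetype.pone_start, archetype.pone_end
        )

    def test_shuffled_archetype_scores_strictly_lower(self, archetype):
        pssm = build_pssm([archetype.pone_region()])
        planted = scan_protein(archetype.sequence, pssm)[0].score
        rng = np.random.default_rng(0)
        seq = np.array(list(archetype.sequence))
        for _ in range(100):
            shuffled = "".join(rng.permutation(seq))
            ws = window_scores(shuffled, pssm)
            assert ws.max() < planted

    def test_window_score_additivity_against_per_residue_oracle(self, archetype):
        pssm = build_pssm([archetype.fix_region()])
        protein = archetype.sequence
        ws = window_scores(protein, pssm)
        L = pssm.length
        for offset in (0, 42, 100, len(protein) - L):
            expected = sum(
                pssm.score(j, protein[offset + j]) for j in range(L)
            )
            assert ws[offset] == pytest.approx(expected, abs=1e-9)

    def test_hits_sorted_and_non_overlapping(self, archetype):
        double = archetype.pone_region() + "G" * 10 + archetype.pone_region()
        pssm = build_pssm([archetype.pone_region()])
        hits = scan_protein(double, pssm, threshold=100.0)
        assert len(hits) == 2
        assert hits[0].score >= hits[1].score
        spans = sorted((h.start, h.end) for h in hits)
        assert spans[0][1] < spans[1][0]


@pytest.fixture(scope="module")
def setup(archetype):
    pssm = build_pssm([archetype.pone_region()], name="PoNe")
    decoys = generate_decoys([300] * 1000, seed=4)
    return pssm, decoys, calibrate_expect(pssm, decoys)


class TestCalibration:
    def test_empirical_definition_at_e_01(self, setup):
        pssm, decoys, cal = setup
        threshold = cal.threshold_for(1e-2)
        n_above = sum(
            1 for s in decoys.values()
            if window_scores(s, pssm).max() > threshold
        )
        assert n_above <= 10

    def test_monotone_non_increasing(self, setup):
        _, _, cal = setup
        grid = np.concatenate([cal.decoy_scores, [cal.decoy_scores[-1] + 50]])
        evals = [cal.expect(s) for s in grid]
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_extrapolation_below_one_over_n(self, setup):
        _, _, cal = setup
        assert cal.expect(cal.decoy_scores[-1] + 1e-6) <= 1.0 / cal.n

    def test_planted_members_pass_e_01_threshold(self, setup, archetype):
        pssm, _, cal = setup
        threshold = cal.threshold_for(1e-2)
        detected = 0
        for i in range(200):
            member = emit_family_member(
                archetype, 0.3, [7, i], region=(283, 449)
            )
            if window_scores(member, pssm).max() > threshold:
                detected += 1
        assert detected >= 180

    def test_fresh_decoy_false_positive_rate_bounded(self, setup):
        # on decoys not used for calibration, the fraction above the E=x
        # threshold stays within 2x (binomial slack)
        pssm, _, cal = setup
        fresh = generate_decoys([300] * 1000, seed=99)
        for e in (1e-1, 1e-2):
            threshold = cal.threshold_for(e)
            frac = np.mean(
                [window_scores(s, pssm).max() > threshold for s in fresh.values()]
            )
            assert frac <= 2 * e

    def test_too_few_decoys_rejected(self, setup):
        pssm, _, _ = setup
        with pytest.raises(ValueError):
            calibrate_expect(pssm, generate_decoys([300] * 50, seed=1))


class TestIterateSearch:
    def test_seed_only_database_is_fixed_point(self, archetype):
        seed_seq = archetype.pone_region()
        result = iterate_search(
            [seed_seq], {"seed": seed_seq},
            SearchConfig(iterations=3, decoy_count=200, seed=0),
        )
        assert set(result.hits) == {"seed"}
        assert result.per_iteration_counts == [1, 1, 1]

    def test_cap_admits_min_iteration_members(self, archetype):
        members = {
            f"M{i}": emit_family_member(archetype, 0.05, [3, i],
                                        region=(283, 449))
            for i in range(5)
        }
        result = iterate_search(
            [archetype.pone_region()], members,
            SearchConfig(iterations=5, per_iteration_cap=1,
                         decoy_count=200, seed=0),
        )
        assert result.per_iteration_counts == [1, 2, 3, 4, 5]

    def test_refinement_does_not_lose_sensitivity(self, archetype):
        """Recall over a planted family is non-decreasing across iterations."""
        family = {
            f"FAM{i:03d}": emit_family_member(archetype, 0.35, [11, i],
                                              region=(283, 449))
            for i in range(150)
        }
        rng = np.random.default_rng(2)
        decoys = generate_decoys(
            [int(n) for n in rng.integers(150, 500, 800)], seed=5
        )
        database = {**family, **decoys}
        result = iterate_search(
            [archetype.pone_region()], database,
            SearchConfig(iterations=5, decoy_count=300, seed=0),
        )
        assert result.per_iteration_counts[-1] >= result.per_iteration_counts[0]
        recall = sum(1 for pid in result.hits if pid.startswith("FAM")) / 150
        assert recall >= 0.9

    def test_deterministic_given_seed(self, archetype):
        db = {
            f"M{i}": emit_family_member(archetype, 0.2, [5, i],
                                        region=(283, 449))
            for i in range(20)
        }
        cfg = SearchConfig(iterations=2, decoy_count=150, seed=42)
        r1 = iterate_search([archetype.pone_region()], db, cfg)
        r2 = iterate_search([archetype.pone_region()], db, cfg)
        assert r1.hits == r2.hits and r1.profile == r2.profile
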