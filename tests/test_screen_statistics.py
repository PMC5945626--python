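import math

import numpy as np
import pytest

from tagmute.mutation_calling import Allele, CdnaVariant, classify_frame, collapse_alleles
from tagmute.screen_statistics import (
    derive_minimal_mutation,
    estimate_locus_copy_number,
    inframe_enrichment_test,
    mc_proximity_test,
    normalize_recruitment_curve,
    per_base_density,
)

from .oracles import binom_tail


class TestInframeEnrichment:
    def test_degenerate_lower_tail(self):
        res = inframe_enrichment_test(0, 8)
        assert res.p_value == 1.0
        assert res.ci_low == 0.0 and res.ci_high == 1.0

    def test_all_successes(self):
        res = inframe_enrichment_test(6, 6, 1 / 3)
        assert res.p_value == pytest.approx((1 / 3) ** 6, rel=1e-12)

    def test_partial_tail(self):
        res = inframe_enrichment_test(7, 9, 1 / 3)
        assert res.p_value == pytest.approx(binom_tail(7, 9, 1 / 3), rel=1e-12)
        assert res.p_value == pytest.approx(0.00828, abs=5e-6)

    def test_matches_pmf_tail_oracle_all_n_up_to_12(self):
        for n in range(1, 13):
            for k in range(0, n + 1):
                for p0 in (1 / 3, 0.5, 0.1):
                    res = inframe_enrichment_test(k, n, p0)
                    assert res.p_value == pytest.approx(binom_tail(k, n, p0), rel=1e-10), (k, n, p0)

    def test_ci_is_one_sided_exact(self):
        # lower bound satisfies P(X >= k | p = ci_low) = 0.05
        res = inframe_enrichment_test(6, 6, 1 / 3)
        assert binom_tail(6, 6, res.ci_low) == pytest.approx(0.05, rel=1e-6)
        res2 = inframe_enrichment_test(7, 9, 1 / 3)
        assert binom_tail(7, 9, res2.ci_low) == pytest.approx(0.05, rel=1e-6)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            inframe_enrichment_test(0, 0)
        with pytest.raises(ValueError):
            inframe_enrichment_test(5, 3)


class TestMcProximity:
    def test_saturated_window_gives_p_one(self):
        res = mc_proximity_test([(50, 1.0)], [10], (1, 101), window_bp=200, n_iterations=1000, seed=1)
        assert res.frac_indels_within == 1.0
        assert res.p_value == 1.0

    def test_no_indels_within_window(self):
        res = mc_proximity_test(
            [(90 + i, 1.0) for i in range(10)], [10], (1, 101), window_bp=5, n_iterations=1000, seed=1
        )
        assert res.frac_indels_within == 0.0
        assert res.p_value == 1.0

    def test_single_indel_matches_analytic_tail(self):
        # 1 indel at the cut, window 5, interval length 101 -> 11 eligible
        # positions; p converges to 11/101. Averaging over independent seeds
        # tests the estimator, not one draw.
        n_iter = 50_000
        seeds = [0, 1, 2, 3]
        ps = [
            mc_proximity_test([(51, 1.0)], [51], (1, 101), window_bp=5, n_iterations=n_iter, seed=s).p_value
            for s in seeds
        ]
        q = 11 / 101
        se = math.sqrt(q * (1 - q) / (n_iter * len(seeds)))
        assert abs(np.mean(ps) - q) <= 3 * se

    def test_deterministic_under_fixed_seed(self):
        a = mc_proximity_test([(51, 1.0)], [51], (1, 101), 5, 2000, seed=42)
        b = mc_proximity_test([(51, 1.0)], [51], (1, 101), 5, 2000, seed=42)
        assert a == b

    def test_read_weighted_fraction(self):
        res = mc_proximity_test([(51, 9.0), (5, 1.0)], [51], (1, 101), 5, 1000, seed=1)
        assert res.frac_indels_within == 0.5
        assert res.frac_reads_within == 0.9

    def test_empty_cut_sites_rejected(self):
        with pytest.raises(ValueError):
            mc_proximity_test([(5, 1.0)], [], (1, 101), 5, 1000, seed=1)


def _inframe_allele(transcript, c_start, length, count):
    seq = transcript.coding_sequence
    a = classify_frame(
        Allele(
            variants=(CdnaVariant("deletion", c_start, c_start + length - 1, seq[c_start - 1 : c_start + length - 1], ""),),
            read_count=count,
        ),
        transcript,
    )
    return a


class TestPerBaseDensity:
    def test_formula_and_filter(self, toy_transcript):
        alleles = [_inframe_allele(toy_transcript, 100, 3, 50)]
        table = collapse_alleles(alleles)
        coverage = {pos: 10_000 for pos in range(1, 181)}
        coverage[150] = 400
        dens = {d.c_pos: d for d in per_base_density(table, coverage)}
        assert dens[100].density == pytest.approx(5.0)
        assert dens[101].mutant_reads == 50 and dens[102].mutant_reads == 50
        assert dens[103].mutant_reads == 0 and dens[103].density == 0.0
        assert dens[150].pass_filter is False
        assert dens[501 - 401].pass_filter is True  # any covered base > 500

    def test_coverage_exactly_500_fails_strict_filter(self, toy_transcript):
        table = collapse_alleles([_inframe_allele(toy_transcript, 10, 3, 1)])
        dens = per_base_density(table, {10: 500, 11: 501, 12: 502})
        flags = {d.c_pos: d.pass_filter for d in dens}
        assert flags == {10: False, 11: True, 12: True}

    def test_mass_conservation(self, toy_transcript):
        alleles = [
            _inframe_allele(toy_transcript, 60, 3, 7),
            _inframe_allele(toy_transcript, 90, 6, 11),
        ]
        table = collapse_alleles(alleles)
        coverage = {pos: 1000 for pos in range(1, 181)}
        dens = per_base_density(table, coverage)
        assert sum(d.mutant_reads for d in dens) == 7 * 3 + 11 * 6

    def test_frameshift_excluded_by_default(self, toy_transcript):
        seq = toy_transcript.coding_sequence
        fs = classify_frame(
            Allele(variants=(CdnaVariant("deletion", 100, 103, seq[99:103], ""),), read_count=5),
            toy_transcript,
        )
        table = collapse_alleles([fs])
        dens = per_base_density(table, {pos: 1000 for pos in range(95, 115)})
        assert all(d.mutant_reads == 0 for d in dens)
        dens_all = per_base_density(table, {pos: 1000 for pos in range(95, 115)}, inframe_only=False)
        assert sum(d.mutant_reads for d in dens_all) == 20

    def test_zero_coverage_with_mutants_is_error(self, toy_transcript):
        table = collapse_alleles([_inframe_allele(toy_transcript, 100, 3, 5)])
        with pytest.raises(ValueError):
            per_base_density(table, {100: 0, 101: 1000, 102: 1000})


class TestMinimalMutation:
    def test_intersection_core(self, toy_transcript):
        # alleles deleting residue windows {40-43}, {41-42}, {39-44}
        a1 = _inframe_allele(toy_transcript, 118, 12, 1)
        a2 = _inframe_allele(toy_transcript, 121, 6, 1)
        a3 = _inframe_allele(toy_transcript, 115, 18, 1)
        cores = [set(a.protein_change.affected_residues) for a in (a1, a2, a3)]
        expected = cores[0] & cores[1] & cores[2]
        res = derive_minimal_mutation([a1, a2, a3], protein=toy_transcript.protein)
        assert set(res.residues) == expected and expected

    def test_single_allele_returns_own_set(self, toy_transcript):
        a = _inframe_allele(toy_transcript, 127, 3, 1)
        res = derive_minimal_mutation([a], protein=toy_transcript.protein)
        assert set(res.residues) == set(a.protein_change.affected_residues)
        assert res.label == "43delM"

    def test_disjoint_alleles_flagged(self, toy_transcript):
        a1 = _inframe_allele(toy_transcript, 10, 3, 1)
        a2 = _inframe_allele(toy_transcript, 100, 3, 1)
        res = derive_minimal_mutation([a1, a2], protein=toy_transcript.protein)
        assert "no_common_core" in res.flags

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            derive_minimal_mutation([])

    def test_kS_deletion_family_label(self):
        """An allele family all deleting K119/S120 yields the 119_120delKS label."""
        from tagmute.synthetic_data import make_synthetic_transcript

        t = make_synthetic_transcript()
        # deletions of codons 119-120 (c.355-360), 118-121, 117-122
        fams = [
            _inframe_allele(t, 355, 6, 10),
            _inframe_allele(t, 352, 12, 5),
            _inframe_allele(t, 349, 18, 2),
        ]
        res = derive_minimal_mutation(fams, protein=t.protein)
        assert res.residues == frozenset({119, 120})
        assert res.label == "119_120delKS"


class TestCopyNumber:
    @pytest.mark.parametrize(
        "fractions,expected",
        [([0.4, 0.2, 0.2, 0.2], 5), ([0.5, 0.5], 2), ([1.0], 1)],
    )
    def test_examples(self, fractions, expected):
        assert estimate_locus_copy_number(fractions, max_copies=8) == expected

    def test_grid_search_oracle(self):
        # brute-force oracle over N = 1..8
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_true = int(rng.integers(2, 7))
            counts = rng.multinomial(n_true, np.ones(n_true) / n_true)
            fr = [c / n_true for c in counts if c > 0]
            best = None
            for n in range(1, 9):
                cost = max(min(abs(f - k / n) for k in range(n + 1)) for f in fr)
                if best is None or cost < best[1] - 1e-12:
                    best = (n, cost)
            assert estimate_locus_copy_number(fr, max_copies=8) == best[0]

    def test_input_errors(self):
        with pytest.raises(ValueError):
            estimate_locus_copy_number([1.5])
        with pytest.raises(ValueError):
            estimate_locus_copy_number([0.5, 0.5], max_copies=0)


class TestRecruitmentCurve:
    def test_basic_normalisation(self):
        curve = normalize_recruitment_curve([10, 20, 30], [10, 10, 10])
        assert curve.normalized == (0.0, 0.5, 1.0)

    def test_flat_signal_flagged(self):
        curve = normalize_recruitment_curve([10, 10, 10], [10, 10, 10])
        assert set(curve.normalized) == {0.0}
        assert "no_signal" in curve.flags

    def test_max_is_one_for_random_positive_series(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            raw = rng.uniform(5, 50, size=20)
            bg = rng.uniform(0, 4, size=20)
            curve = normalize_recruitment_curve(raw, bg)
            assert max(curve.normalized) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            normalize_recruitment_curve([1, 2, 3], [1, 2])
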