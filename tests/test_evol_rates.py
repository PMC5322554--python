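"""NG86 dN/dS machinery: threading, occupancy filtering, counting vs an
exhaustive path-enumeration oracle, saturation filters, and parameter
recovery against the simulator's recorded substitutions."""

import math
from itertools import permutations

import numpy as np
import pytest

from epiensemble.evol_rates import (
    CodonAlignment,
    codon_path_differences,
    codon_site_fractions,
    compare_groups,
    filter_columns,
    jukes_cantor,
    ng86_pairwise,
    paralog_rate_contrast,
    rate_for_cds_pair,
    thread_codon_alignment,
)
from epiensemble.io_formats import InputError
from epiensemble.synthetic_data import (
    SENSE_CODONS,
    STOP_CODONS,
    evolve_codons,
    random_cds,
    translate_cds,
    translate_codon,
)


class TestThreading:
    def test_ungapped_pair_is_codon_concatenation(self):
        cds = {"a": "ATGGCTAAA", "b": "ATGGCCAAA"}
        aln = thread_codon_alignment([("a", "MAK"), ("b", "MAK")], cds)
        assert aln.rows == ["ATGGCTAAA", "ATGGCCAAA"]

    def test_protein_gap_becomes_codon_gap(self):
        cds = {"a": "ATGGCTAAA", "b": "ATGAAA"}
        aln = thread_codon_alignment([("a", "MAK"), ("b", "M-K")], cds)
        assert aln.rows[1] == "ATG---AAA"
        assert aln.rows[1][6:9] == "AAA"

    def test_translation_mismatch_names_sequence_and_position(self):
        cds = {"a": "ATGGCTAAA"}
        with pytest.raises(InputError, match="a.*residue 2"):
            thread_codon_alignment([("a", "MVK")], cds)

    def test_round_trip_on_random_simulated_pairs(self, rng):
        for _ in range(10):
            cds = random_cds(60, rng)
            protein = translate_cds(cds)
            aln = thread_codon_alignment([("x", protein)], {"x": cds})
            assert translate_cds(aln.rows[0]) == protein


class TestFilterColumns:
    def test_two_row_gapped_column_removed(self):
        aln = CodonAlignment(ids=["a", "b"], rows=["ATGGCT", "ATG---"])
        out = filter_columns(aln)
        assert out.rows == ["ATG", "ATG"]

    def test_gapless_alignment_unchanged(self):
        aln = CodonAlignment(ids=["a", "b"], rows=["ATGGCT", "ATGGCC"])
        assert filter_columns(aln).rows == aln.rows

    def test_boundary_occupancy_retained(self):
        # 5 rows, 3 present = exactly 0.6 -> kept
        rows = ["ATG", "ATG", "ATG", "---", "---"]
        aln = CodonAlignment(ids=list("abcde"), rows=rows)
        assert filter_columns(aln, 0.6).rows == rows

    def test_empty_result_rejected(self):
        aln = CodonAlignment(ids=["a", "b", "c"], rows=["ATG", "---", "---"])
        with pytest.raises(InputError):
            filter_columns(aln, 0.6)


def site_fractions_oracle(codon):
    """Independent recount of synonymous site fractions."""
    s = 0.0
    for i in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += translate_codon(alt) == translate_codon(codon)
        if valid:
            s += syn / valid
    return s


def path_differences_oracle(c1, c2):
    """Exhaustive single-step path enumeration, stop-avoiding paths first."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    ok, allp = [], []
    for order in permutations(diff):
        cur, syn, non, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            stop = stop or nxt in STOP_CODONS
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        allp.append((syn, non))
        if not stop:
            ok.append((syn, non))
    use = ok or allp
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


class TestNg86Counts:
    def test_site_fractions_match_oracle_on_all_61_codons(self):
        for codon in SENSE_CODONS:
            s, n = codon_site_fractions(codon)
            assert s == pytest.approx(site_fractions_oracle(codon))
            assert s + n == pytest.approx(3.0)

    def test_path_counts_match_oracle_on_all_61x61_pairs(self):
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                got = codon_path_differences(c1, c2)
                exp = path_differences_oracle(c1, c2)
                assert got == pytest.approx(exp), (c1, c2)

    def test_path_counts_symmetric(self):
        for c1 in SENSE_CODONS[::7]:
            for c2 in SENSE_CODONS[::5]:
                assert codon_path_differences(c1, c2) == pytest.approx(
                    codon_path_differences(c2, c1)
                )


class TestNg86Pairwise:
    def test_identical_sequences_excluded_as_ds_zero(self, rng):
        cds = random_cds(100, rng)
        est = ng86_pairwise(cds, cds)
        assert est.dn == est.ds == 0.0
        assert est.excluded == "ds_zero" and est.omega is None

    def test_symmetry(self, rng):
        a = random_cds(200, rng)
        b = evolve_codons(a, 0.2, 0.3, 2.0, 5).descendant
        assert ng86_pairwise(a, b) == ng86_pairwise(b, a)

    def test_site_conservation_invariant(self, rng):
        for seed in range(5):
            a = random_cds(150, np.random.default_rng(seed))
            b = evolve_codons(a, 0.3, 0.2, 2.0, seed).descendant
            est = ng86_pairwise(a, b)
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)
            assert est.nd <= est.n_sites and est.sd <= est.s_sites

    def test_saturated_ds_flagged(self, rng):
        a = random_cds(300, rng)
        b = evolve_codons(a, 3.0, 0.8, 2.0, 9).descendant
        est = ng86_pairwise(a, b)
        assert est.excluded == "ds_saturated"
        assert math.isinf(est.ds) or est.ds > 1.0

    def test_gapped_codons_skipped_pairwise(self):
        est = ng86_pairwise("ATG---GCTAAA", "ATGCCCGCCAAA")
        assert est.n_codons == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ng86_pairwise("ATGGCT", "ATG")

    @pytest.mark.parametrize("omega_true", [0.1, 0.5])
    def test_omega_recovery_median_within_005(self, omega_true):
        # 10 seeds at 3000 codons, dS ~ 0.3 split over two branches
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(10_000 + seed)
            anc = random_cds(3000, rng)
            a = evolve_codons(anc, 0.15, omega_true, 2.0, rng).descendant
            b = evolve_codons(anc, 0.15, omega_true, 2.0, rng).descendant
            est = ng86_pairwise(a, b, kappa=2.0)  # generator's kappa
            assert est.usable
            errors.append(abs(est.omega - omega_true))
        assert np.median(errors) <= 0.05


class TestJukesCantor:
    def test_monotone_on_valid_range(self):
        ps = np.linspace(0, 0.74, 50)
        ds = [jukes_cantor(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))

    def test_diverges_at_three_quarters(self):
        assert math.isinf(jukes_cantor(0.75))

    def test_small_p_close_to_p(self):
        assert jukes_cantor(0.01) == pytest.approx(0.01, rel=0.02)


class TestParalogContrast:
    def test_fast_evolving_retrocopy_more_diverged(self, rng):
        ref = random_cds(300, rng)
        spliced = evolve_codons(ref, 0.1, 0.1, 2.0, 1).descendant
        retro = evolve_codons(ref, 2.5, 0.9, 2.0, 2).descendant
        contrast = paralog_rate_contrast(ref, spliced, retro)
        assert contrast.more_diverged == "paralog2"
        assert contrast.estimate_2.ds > contrast.estimate_1.ds
        assert contrast.estimate_2.excluded == "ds_saturated"

    def test_identical_paralogs_give_identical_estimates(self, rng):
        ref = random_cds(100, rng)
        par = evolve_codons(ref, 0.2, 0.2, 2.0, 3).descendant
        contrast = paralog_rate_contrast(ref, par, par)
        assert contrast.estimate_1 == contrast.estimate_2
        assert contrast.more_diverged == "tie"

    def test_paralog_equal_to_reference_has_zero_ds(self, rng):
        ref = random_cds(100, rng)
        other = evolve_codons(ref, 0.3, 0.2, 2.0, 4).descendant
        contrast = paralog_rate_contrast(ref, ref, other)
        assert contrast.estimate_1.ds == 0.0
        assert contrast.estimate_1.excluded == "ds_zero"


class TestCompareGroups:
    def test_identical_groups_p_one_t_zero(self, rng):
        anc = random_cds(500, rng)
        ests = []
        for seed in range(3):
            d = evolve_codons(anc, 0.2, 0.2, 2.0, seed).descendant
            ests.append(ng86_pairwise(anc, d))
        res = compare_groups(ests, list(ests))
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_separated_omega_groups_detected(self):
        group_a, group_b = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            anc = random_cds(400, rng)
            a = evolve_codons(anc, 0.3, 0.1, 2.0, rng).descendant
            group_a.append(ng86_pairwise(anc, a))
            rng2 = np.random.default_rng(1000 + seed)
            anc2 = random_cds(400, rng2)
            b = evolve_codons(anc2, 0.3, 0.5, 2.0, rng2).descendant
            group_b.append(ng86_pairwise(anc2, b))
        res = compare_groups(group_a, group_b)
        assert res.p_value < 0.01
        assert res.means[0] < res.means[1]

    def test_excluded_estimates_dropped_and_counted(self, rng):
        anc = random_cds(300, rng)
        good = [
            ng86_pairwise(anc, evolve_codons(anc, 0.2, 0.2, 2.0, s).descendant)
            for s in range(3)
        ]
        bad = ng86_pairwise(anc, anc)  # ds_zero
        res = compare_groups(good + [bad], good)
        assert res.n_excluded == (1, 0)
        assert res.ns == (3, 3)

    def test_too_few_usable_rejected(self, rng):
        anc = random_cds(100, rng)
        est = ng86_pairwise(anc, evolve_codons(anc, 0.2, 0.2, 2.0, 1).descendant)
        with pytest.raises(InputError):
            compare_groups([est], [est, est])
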