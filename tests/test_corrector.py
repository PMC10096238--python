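"""Run fixers, the multi-pass driver, and the QV computation."""

import math

import pytest

from helpers import exact_table, exact_thresholds
from kmerpolish.corrector import (
    QV_CAP,
    CorrectionKind,
    compute_qv,
    fix_run_exact_k,
    fix_run_long,
    fix_run_short,
    polish,
    polish_pass,
)
from kmerpolish.kmerdb import KmerCountTable, KmerParams, count_kmers
from kmerpolish.scanner import classify_kmers, extract_runs, window_counts
from kmerpolish.simgen import generate_genome
from kmerpolish.thresholds import Thresholds

THR3 = Thresholds(c_eq=31, r_t=15, a_t=8)


def one_run(contig, table, thr):
    profile = classify_kmers(contig, table, thr)
    runs = extract_runs(profile, contig, table, thr)
    assert len(runs) == 1
    return runs[0]


class TestFixRunExactK:
    def test_substitution_restores_truth(self):
        table = exact_table("AAACCCGGG", 3, depth=30)
        run = one_run("AAACTCGGG", table, THR3)
        corr = fix_run_exact_k(run, "AAACTCGGG", table, THR3)
        assert corr is not None
        assert (corr.position, corr.removed, corr.added) == (4, "T", "C")
        assert corr.kind is CorrectionKind.SUBSTITUTION
        fixed = corr.apply("AAACTCGGG")
        assert fixed == "AAACCCGGG"
        assert all(c >= THR3.r_t for c in window_counts(fixed, table))

    def test_unverifiable_run_makes_no_modification(self):
        # a table that contains nothing near the run: no candidate verifies
        table = exact_table("TTTTTTTTT", 3, depth=30)
        contig = "AAACTCGGG"
        profile = classify_kmers(contig, table, THR3)
        runs = extract_runs(profile, contig, table, THR3)
        for run in runs:
            if run.correctable and run.length_L == 3:
                assert fix_run_exact_k(run, contig, table, THR3) is None

    def test_novel_base_insertion_fixed_by_deletion(self):
        genome = generate_genome(2_000, seed=3)
        k = 7
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        p = 1000
        ins = "A" if genome[p - 1] != "A" else "C"  # novel base: L == K run
        bad = genome[:p] + ins + genome[p:]
        new, corrs = polish_pass(bad, table, thr)
        assert new == genome
        assert len(corrs) == 1
        assert corrs[0].kind is CorrectionKind.INSERTION_INTO_ASSEMBLY


class TestFixRunShort:
    def test_deleted_base_is_reinserted(self):
        table = exact_table("ACGTGCA", 3, depth=30)
        assert table.counts == {"ACG": 60, "CAC": 30, "GCA": 60}
        contig = "ACGGCA"  # T deleted from the truth
        run = one_run(contig, table, THR3)
        assert run.length_L == 2
        corr = fix_run_short(run, contig, table, THR3)
        assert corr is not None
        assert (corr.position, corr.added) == (3, "T")
        assert corr.kind is CorrectionKind.DELETION_FROM_ASSEMBLY
        fixed = corr.apply(contig)
        assert fixed == "ACGTGCA"
        assert all(c >= THR3.r_t for c in window_counts(fixed, table))

    def test_homopolymer_extra_base_deleted(self):
        genome = "GATTACCCGTTGACGGATCAATTGAC"
        k = 5
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        p = genome.index("CCC")
        bad = genome[:p] + "C" + genome[p:]  # ACCCG -> ACCCCG
        new, corrs = polish_pass(bad, table, thr)
        assert new == genome
        assert len(corrs) == 1

    def test_homopolymer_multibase_deletion_reinserted(self):
        # the homopolymer (6 C) must be shorter than k, otherwise the k-mer
        # spectrum cannot determine the copy number at all
        genome = "GATTAGTCACCCCCCGTTGACGGATCAATTGAC"
        k = 7
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        p = genome.index("CCCCCC")
        bad = genome[:p] + genome[p + 3 :]  # drop three Cs
        new, corrs = polish_pass(bad, table, thr)
        assert new == genome

    def test_phasing_substitution(self):
        genome = generate_genome(3_000, seed=9)
        k = 7
        table = exact_table(genome, k, depth=60)
        # add the alternate haplotype's k-mers: one base differs
        p = 1500
        alt_base = "A" if genome[p] != "A" else "G"
        alt = genome[p - k : p] + alt_base + genome[p + 1 : p + k + 1]
        alt_tab = exact_table(alt, k, depth=60)
        merged = dict(table.counts)
        for km, c in alt_tab.counts.items():
            merged[km] = merged.get(km, 0) + c
        table = KmerCountTable(table.params, merged, table.total_kmers_counted)
        thr = exact_thresholds(60)
        # assembly mixed haplotypes: alt base at p plus a primary-haplotype
        # base within k positions is NOT an error here; the simple case is a
        # lone wrong base whose context matches neither haplotype elsewhere
        bad = genome[:p] + alt_base + genome[p + 1 :]
        new, _ = polish_pass(bad, table, thr)
        # either haplotype is a valid reliable sequence; no damage done
        assert new in (genome, bad)


class TestFixRunLong:
    @pytest.fixture()
    def two_sub_fixture(self):
        genome = generate_genome(10_000, seed=7)
        k = 17
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        p = 5000
        b1 = "A" if genome[p] != "A" else "C"
        b2 = "G" if genome[p + 8] != "G" else "T"
        bad = genome[:p] + b1 + genome[p + 1 :]
        bad = bad[:p + 8] + b2 + bad[p + 9 :]
        return genome, bad, table, thr

    def test_path_replacement_restores_truth(self, two_sub_fixture):
        genome, bad, table, thr = two_sub_fixture
        new, corrs = polish_pass(bad, table, thr)
        assert new == genome
        assert len(corrs) == 1
        assert corrs[0].kind is CorrectionKind.PATH_REPLACEMENT

    def test_path_cap_gives_up(self):
        # two tandem near-identical segments create a genuine branch in the
        # k-mer graph; with max_paths=1 the search must give up
        k = 7
        unit = "ACGTTGACCTGATTACA"
        genome = ("GATCCGT" + unit + "GGG" + unit + "TCCAGTA") * 1
        table = exact_table(genome + genome, k, depth=60)
        thr = exact_thresholds(60)
        contig = genome
        profile = classify_kmers(contig, table, thr)
        runs = extract_runs(profile, contig, table, thr)
        # force a long artificial run over the repeat to drive the search
        from kmerpolish.scanner import UnreliableRun

        run = UnreliableRun(
            contig_id="c",
            start=8,
            length_L=k + 10,
            span_SL=contig[8 : 8 + 2 * k + 9],
            left_anchor=contig[7 : 7 + k],
            right_anchor=contig[8 + k + 10 : 8 + 2 * k + 10],
        )
        full = fix_run_long(run, contig, table, thr, max_paths=5000)
        capped = fix_run_long(run, contig, table, thr, max_paths=1)
        assert capped is None or full is not None  # cap can only lose fixes
        assert capped is None

    def test_coverage_hole_run_yields_no_edit(self, two_sub_fixture):
        # run whose interior already matches the only reliable path: NONE
        genome, _, table, thr = two_sub_fixture
        from kmerpolish.scanner import UnreliableRun

        k = table.params.k
        s, L = 3000, k + 5
        run = UnreliableRun(
            contig_id="c",
            start=s,
            length_L=L,
            span_SL=genome[s : s + L + k - 1],
            left_anchor=genome[s - 1 : s - 1 + k],
            right_anchor=genome[s + L : s + L + k],
        )
        assert fix_run_long(run, genome, table, thr) is None


class TestPolishDriver:
    def test_error_free_contig_unchanged(self):
        genome = generate_genome(5_000, seed=2)
        table = exact_table(genome, 7, depth=60)
        thr = exact_thresholds(60)
        new, corrs = polish_pass(genome, table, thr)
        assert new == genome and corrs == []

    def test_two_independent_errors_fixed_in_one_pass(self):
        genome = generate_genome(10_000, seed=4)
        k = 17
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        p1, p2 = 3000, 3000 + 3 * k  # > 2K apart
        bad = list(genome)
        for p in (p1, p2):
            bad[p] = "A" if genome[p] != "A" else "T"
        new, corrs = polish_pass("".join(bad), table, thr)
        assert new == genome
        assert len(corrs) == 2

    def test_idempotence_after_convergence(self):
        genome = generate_genome(8_000, seed=6)
        k = 17
        table = exact_table(genome, k, depth=60)
        thr = exact_thresholds(60)
        bad = genome[:4000] + ("C" if genome[4000] != "C" else "G") + genome[4001:]
        out3, rep3 = polish([("c", bad)], table, thr, passes=3, compute_qv_report=False)
        out6, rep6 = polish([("c", bad)], table, thr, passes=6, compute_qv_report=False)
        assert out3 == out6
        assert rep3.corrections_per_pass[-1] == 0
        assert all(n == 0 for n in rep6.corrections_per_pass[1:])

    def test_passes_must_be_positive(self):
        table = exact_table("ACGTACG", 3, depth=30)
        with pytest.raises(ValueError):
            polish([("c", "ACGTACG")], table, THR3, passes=0)


class TestComputeQV:
    def test_worked_example(self):
        rep = compute_qv(100, 1_000_000, 37)
        assert rep.e_k == pytest.approx(1 / 10_000, rel=0, abs=0)
        expected_eb = 1 - (1 - 1e-4) ** (1 / 37)
        assert rep.e_b == pytest.approx(expected_eb, rel=1e-9)
        assert rep.qv == pytest.approx(-10 * math.log10(expected_eb), rel=1e-9)
        assert round(rep.qv, 1) == 55.7

    def test_zero_error_limit_hits_cap(self):
        rep = compute_qv(0, 1_000_000, 37)
        assert rep.e_k == 0 and rep.e_b == 0 and rep.qv == QV_CAP

    def test_first_order_small_rate_approximation(self):
        # e_b -> e_k / K as e_k -> 0
        for e_k_num in (1, 10, 100):
            rep = compute_qv(e_k_num, 1_000_000, 37)
            assert rep.e_b == pytest.approx(rep.e_k / 37, rel=0.01)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            compute_qv(1, 0, 37)
        with pytest.raises(ValueError):
            compute_qv(5, 4, 37)
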