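"""Conversion classes, Mendelian trio rules, exact HWE test, MAF."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelforge.validation import (MISSING, ConversionClass, GenotypeMatrix,
                                   TrioSet, classify_conversion, estimate_maf,
                                   hwe_exact_test, hwe_pvalues, maf_all,
                                   mendelian_check)


def matrix(calls, lines=None, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    samples = [f"smp{i}" for i in range(calls.shape[0])]
    snps = [f"snp{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(samples, snps, calls, lines, chroms)


# -- conversion classes -------------------------------------------------

def test_conversion_classes():
    # 100 samples, 3 SNPs: failed (3 missing), monomorphic (1 het only),
    # polymorphic
    calls = np.zeros((100, 3), dtype=np.int8)
    calls[:3, 0] = MISSING
    calls[0, 1] = 1
    calls[:10, 2] = 1
    cls = classify_conversion(matrix(calls))
    assert cls["snp0"] == ConversionClass.failed
    assert cls["snp1"] == ConversionClass.monomorphic_low_allele_count
    assert cls["snp2"] == ConversionClass.polymorphic


def test_conversion_boundaries():
    # exactly at call-rate threshold: 98/100 called -> not failed
    calls = np.ones((100, 2), dtype=np.int8)
    calls[:2, 0] = MISSING
    calls[:3, 1] = MISSING
    cls = classify_conversion(matrix(calls))
    assert cls["snp0"] == ConversionClass.polymorphic
    assert cls["snp1"] == ConversionClass.failed
    # minor count exactly 2 is polymorphic (threshold is "below 2")
    calls = np.zeros((50, 2), dtype=np.int8)
    calls[0, 0] = 2          # minor count 2
    calls[0, 1] = 1          # minor count 1
    cls = classify_conversion(matrix(calls))
    assert cls["snp0"] == ConversionClass.polymorphic
    assert cls["snp1"] == ConversionClass.monomorphic_low_allele_count


def test_failed_takes_precedence_over_monomorphic():
    calls = np.zeros((10, 1), dtype=np.int8)
    calls[:5, 0] = MISSING
    assert classify_conversion(matrix(calls))["snp0"] == ConversionClass.failed


# -- Mendelian ----------------------------------------------------------

def trio_matrix(gs, gd, go, chrom="Chr1"):
    return (matrix([[gs], [gd], [go]], chroms=[chrom]),
            TrioSet([("smp0", "smp1", "smp2")]))


@pytest.mark.parametrize("gs, gd, go, ok", [
    (0, 0, 0, True), (0, 0, 1, False), (0, 0, 2, False),
    (0, 2, 1, True), (0, 2, 0, False), (0, 2, 2, False),  # obligate het
    (1, 1, 0, True), (1, 1, 1, True), (1, 1, 2, True),
    (2, 2, 2, True), (2, 2, 1, False),
    (0, 1, 0, True), (0, 1, 1, True), (0, 1, 2, False),
])
def test_mendel_rules(gs, gd, go, ok):
    m, t = trio_matrix(gs, gd, go)
    flags, counts = mendelian_check(m, t)
    assert flags["snp0"] is (not ok)
    assert counts["n_inconsistent_trios"].iloc[0] == (0 if ok else 1)


def test_mendel_missing_is_consistent():
    m, t = trio_matrix(0, 0, MISSING)
    flags, _ = mendelian_check(m, t)
    assert flags["snp0"] is False
    m, t = trio_matrix(MISSING, 0, 2)
    assert mendelian_check(m, t)[0]["snp0"] is False


def test_mendel_sex_chromosome_skipped():
    m, t = trio_matrix(0, 0, 2, chrom="ChrZ")
    assert mendelian_check(m, t)[0]["snp0"] is False
    assert mendelian_check(m, t, autosomes_only=False)[0]["snp0"] is True


def test_mendel_counts_multiple_trios():
    calls = [[0], [0], [2],   # trio 1 inconsistent
             [1], [1], [2],   # trio 2 consistent
             [2], [2], [0]]   # trio 3 inconsistent
    m = matrix(calls, chroms=["Chr1"])
    t = TrioSet([("smp0", "smp1", "smp2"), ("smp3", "smp4", "smp5"),
                 ("smp6", "smp7", "smp8")])
    flags, counts = mendelian_check(m, t)
    assert flags["snp0"] is True
    assert counts["n_inconsistent_trios"].iloc[0] == 2


def test_trioset_validation_and_roundtrip(tmp_path):
    with pytest.raises(ValueError, match="duplicates"):
        TrioSet([("a", "b", "a")])
    t = TrioSet([("s1", "d1", "o1"), ("s2", "d2", "o2")])
    p = tmp_path / "trios.tsv"
    t.to_tsv(p)
    assert TrioSet.from_tsv(p).trios == t.trios


# -- exact HWE ----------------------------------------------------------

def test_hwe_known_values():
    # 1/2/1: all het counts {0,2} -> weights 4!/ (1!2!1!) * 4 = 48 for
    # h=2, 4!/(2!0!2!) = 6 for h=0; observed h=2 is the most probable,
    # so every outcome is counted: p = 1
    assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)
    # 2/0/2: p = 6/54... enumerate: weights h=0:6, h=2:48, h=4:? rare=4
    # hets 0,2,4: w4 = 4!/(0!4!0!)*16 = 16 -> p = 6/70
    assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70)
    # monomorphic: a single outcome, p = 1
    assert hwe_exact_test(0, 0, 10) == pytest.approx(1.0)
    assert hwe_exact_test(10, 0, 0) == pytest.approx(1.0)
    # all-het with equal alleles is the HWE-extreme direction but still
    # the observed outcome is included
    assert 0 < hwe_exact_test(0, 100, 0) < 1e-20


def test_hwe_input_validation():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 1)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_allele_relabel_symmetry():
    for a, h, b in [(3, 2, 1), (0, 5, 2), (7, 1, 0), (2, 2, 2)]:
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a))


def test_hwe_midp_smaller():
    p = hwe_exact_test(5, 1, 5)
    pm = hwe_exact_test(5, 1, 5, midp=True)
    assert pm < p <= 1.0


def brute_force_hwe(n_AA, n_AB, n_BB):
    """Oracle: exact conditional distribution by enumerating all ordered
    allele pairings of the observed allele multiset into n genotypes."""
    n = n_AA + n_AB + n_BB
    n_a = 2 * n_AA + n_AB
    # P(h hets | allele counts) proportional to multinomial weight; the
    # oracle derives it from first principles: number of distinct ways to
    # form the genotype configuration from labelled alleles
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # labelled-individuals count: choose which individuals get which
        # genotype, times the 2^h orderings of alleles within hets
        weights[h] = (comb(n, hom_rare) * comb(n - hom_rare, h)) * 2 ** h
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_AB]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def test_hwe_matches_enumeration_oracle_all_small_tables():
    for n in range(1, 9):
        for n_AA in range(n + 1):
            for n_AB in range(n - n_AA + 1):
                n_BB = n - n_AA - n_AB
                got = hwe_exact_test(n_AA, n_AB, n_BB)
                want = brute_force_hwe(n_AA, n_AB, n_BB)
                assert got == pytest.approx(want, rel=1e-10), (n_AA, n_AB, n_BB)


def test_hwe_pvalues_skips_missing_only_columns():
    calls = np.array([[0, MISSING], [1, MISSING], [1, MISSING], [2, MISSING]],
                     dtype=np.int8)
    ps = hwe_pvalues(matrix(calls))
    assert "snp1" not in ps
    assert ps["snp0"] == pytest.approx(hwe_exact_test(1, 2, 1))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_hwe_is_probability(a, h, b):
    if a + h + b == 0:
        return
    p = hwe_exact_test(a, h, b)
    assert 0 < p <= 1.0


# -- MAF ----------------------------------------------------------------

def test_maf_examples():
    calls = np.array([[0], [0], [1], [1]], dtype=np.int8)   # alt freq 0.25
    assert estimate_maf(matrix(calls), "snp0") == pytest.approx(0.25)
    calls = np.array([[2], [2], [2], [1]], dtype=np.int8)   # alt 7/8, folded
    assert estimate_maf(matrix(calls), "snp0") == pytest.approx(0.125)
    calls = np.array([[0], [2]], dtype=np.int8)
    assert estimate_maf(matrix(calls), "snp0") == pytest.approx(0.5)
    calls = np.array([[0], [0]], dtype=np.int8)
    assert estimate_maf(matrix(calls), "snp0") == 0.0


def test_maf_missing_and_subset():
    calls = np.array([[2], [MISSING], [0], [0]], dtype=np.int8)
    m = matrix(calls, lines=["A", "A", "B", "B"])
    assert estimate_maf(m, "snp0") == pytest.approx(1 / 3)
    assert estimate_maf(m, "snp0", line_subset=["A"]) == pytest.approx(0.0)  # 2/2 folded
    assert np.isnan(estimate_maf(matrix([[MISSING]], lines=["A"]), "snp0"))
    with pytest.raises(ValueError, match="line labels"):
        estimate_maf(matrix(calls), "snp0", line_subset=["A"])


def test_maf_all_matches_scalar():
    rng = np.random.default_rng(0)
    calls = rng.integers(-1, 3, size=(40, 25)).astype(np.int8)
    m = matrix(calls, lines=["A"] * 20 + ["B"] * 20)
    vec = maf_all(m)
    for sid in m.snp_ids:
        one = estimate_maf(m, sid)
        assert (np.isnan(one) and np.isnan(vec[sid])) or one == pytest.approx(vec[sid])
    sub = maf_all(m, line_subset=["B"])
    assert sub["snp3"] == pytest.approx(estimate_maf(m, "snp3", line_subset=["B"]))


# -- matrix I/O ---------------------------------------------------------

def test_genotype_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    calls = rng.integers(-1, 3, size=(6, 8)).astype(np.int8)
    m = matrix(calls)
    p = tmp_path / "g.tsv"
    m.to_tsv(p)
    back = GenotypeMatrix.from_tsv(p)
    assert back.samples == m.samples and back.snp_ids == m.snp_ids
    assert np.array_equal(back.calls, m.calls)
    assert "NA" in p.read_text()


def test_matrix_validation():
    with pytest.raises(ValueError, match="shape"):
        GenotypeMatrix(["a"], ["x", "y"], np.zeros((1, 3)))
    with pytest.raises(ValueError, match="missing"):
        GenotypeMatrix(["a"], ["x"], np.array([[5]]))
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeMatrix(["a", "a"], ["x"], np.zeros((2, 1)))
    m = matrix([[0, 1]])
    with pytest.raises(KeyError, match="ghost"):
        m.sample_idx("ghost")
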