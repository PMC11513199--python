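"""Marker informativeness statistics and their enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opilio.core import NoDataError, ValidationError, genotype
from opilio.markers import (
    allele_frequencies,
    combined_exclusion,
    effective_allele_count,
    exclusion_probability,
    hwe_test,
    linkage_test,
    locus_summary,
)

from conftest import hwe_sample

G = genotype


# ---------------------------------------------------------------------------
# allele frequencies

def test_allele_frequencies_direct_counts():
    assert allele_frequencies([G(1, 1), G(1, 2)]) == {1: 0.75, 2: 0.25}
    assert allele_frequencies([G(1, 1)]) == {1: 1.0}


def test_allele_frequencies_skip_nulls_and_error_on_empty():
    assert allele_frequencies([None, G(3, 4)]) == {3: 0.5, 4: 0.5}
    with pytest.raises(NoDataError):
        allele_frequencies([None, None], locus="L1")


def test_allele_frequencies_match_independent_tally(rng):
    # 33 genotypes over a 15-allele ladder, hand-tallied
    labels = list(range(100, 130, 2))
    draws = rng.choice(labels, size=(33, 2))
    gs = [G(int(a), int(b)) for a, b in draws]
    tally = {}
    for a, b in draws:
        tally[int(a)] = tally.get(int(a), 0) + 1
        tally[int(b)] = tally.get(int(b), 0) + 1
    expected = {a: c / 66 for a, c in tally.items()}
    got = allele_frequencies(gs)
    assert got.keys() == expected.keys()
    for a in expected:
        assert got[a] == pytest.approx(expected[a])


# ---------------------------------------------------------------------------
# locus summary

@pytest.mark.parametrize("h_exp, n_eff", [(0.824, 5.7), (0.863, 7.3), (0.664, 3.0)])
def test_effective_allele_count_roundtrips_printed_heterozygosities(h_exp, n_eff):
    assert round(effective_allele_count(h_exp), 1) == n_eff


def test_locus_summary_monomorphic_flagged():
    s = locus_summary([G(5, 5)] * 10, "L")
    assert s.monomorphic
    assert s.h_obs == 0 and s.h_exp == 0 and s.n_eff == 1 and s.f_is == 0


def test_locus_summary_unbiased_h_exp():
    # 2 AA, 2 AB: p_A = 0.75; H_E = (8/7)(1 - 0.625) = 0.42857...
    s = locus_summary([G(1, 1), G(1, 1), G(1, 2), G(1, 2)], "L")
    assert s.h_exp == pytest.approx((8 / 7) * (1 - 0.75**2 - 0.25**2))
    assert s.h_obs == 0.5
    assert s.n_eff == pytest.approx(1 / (1 - s.h_exp))


@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=3, max_size=60))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_locus_summary_invariants(pairs):
    gs = [G(a, b) for a, b in pairs]
    s = locus_summary(gs, "L")
    if not s.monomorphic:
        # reported N_eff is exactly the inverse complement of reported H_E
        assert s.n_eff == pytest.approx(1 / (1 - s.h_exp))
    freqs = allele_frequencies(gs)
    # uncorrected effective allele count is bounded by the observed count
    assert 1 / sum(p * p for p in freqs.values()) <= s.n_alleles + 1e-9
    assert s.freq_max * s.n_alleles >= 1 - 1e-9
    assert 0 <= s.h_obs <= 1 and 0 <= s.p_excl <= 1


# ---------------------------------------------------------------------------
# exclusion probability vs brute-force Mendelian enumeration

def brute_force_exclusion(freqs):
    """Enumerate mother x father x offspring x random-male genotype draws."""
    alleles = list(freqs)
    gspace = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]

    def gp(g):
        return freqs[g[0]] ** 2 if g[0] == g[1] else 2 * freqs[g[0]] * freqs[g[1]]

    total = 0.0
    for m in gspace:
        for f in gspace:
            for ma in set(m):
                pm = 0.5 if m[0] != m[1] else 1.0
                for fa in set(f):
                    pf = 0.5 if f[0] != f[1] else 1.0
                    o = tuple(sorted((ma, fa)))
                    paternal = set()
                    if o[1] in m:
                        paternal.add(o[0])
                    if o[0] in m:
                        paternal.add(o[1])
                    p_excluded = sum(g for g in (gp(x) for x in gspace
                                                 if not set(x) & paternal))
                    total += gp(m) * gp(f) * pm * pf * p_excluded
    return total


@pytest.mark.parametrize(
    "freqs",
    [
        {1: 0.5, 2: 0.5},
        {1: 1 / 3, 2: 1 / 3, 3: 1 / 3},
        {i: 1 / 6 for i in range(6)},
        {1: 0.7, 2: 0.2, 3: 0.1},
        {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        {1: 0.55, 2: 0.25, 3: 0.1, 4: 0.05, 5: 0.03, 6: 0.02},
    ],
)
def test_exclusion_probability_matches_enumeration(freqs):
    assert exclusion_probability(freqs) == pytest.approx(
        brute_force_exclusion(freqs), abs=1e-12
    )


def test_exclusion_probability_known_values():
    assert exclusion_probability({1: 1.0}) == 0.0
    assert exclusion_probability({1: 0.5, 2: 0.5}) == pytest.approx(0.1875)


def test_exclusion_probability_rejects_bad_frequencies():
    with pytest.raises(ValidationError):
        exclusion_probability({1: 0.5, 2: 0.4})


def test_combined_exclusion():
    assert combined_exclusion([0.5, 0.5]) == pytest.approx(0.75)
    assert combined_exclusion([0.0]) == 0.0
    with pytest.raises(ValidationError):
        combined_exclusion([1.5])


# ---------------------------------------------------------------------------
# Hardy-Weinberg and linkage tests

def test_hwe_exact_proportions_not_rejected():
    gs = [G(1, 1)] * 25 + [G(1, 2)] * 50 + [G(2, 2)] * 25
    assert hwe_test(gs, reps=2000, seed=1) > 0.5


def test_hwe_all_homozygotes_rejected():
    gs = [G(1, 1)] * 25 + [G(2, 2)] * 25
    assert hwe_test(gs, reps=2000, seed=1) < 0.001


def test_hwe_monomorphic_and_preconditions():
    assert hwe_test([G(1, 1)] * 10, reps=2000, seed=0) == 1.0
    with pytest.raises(NoDataError):
        hwe_test([G(1, 2)] * 3, reps=2000, seed=0)
    with pytest.raises(ValidationError):
        hwe_test([G(1, 2)] * 10, reps=10, seed=0)


def test_hwe_deterministic_given_seed():
    gs = [G(1, 1)] * 20 + [G(1, 2)] * 20 + [G(2, 2)] * 10
    assert hwe_test(gs, reps=2000, seed=7) == hwe_test(gs, reps=2000, seed=7)


def test_linkage_duplicated_locus_maximal_association(rng):
    gs = hwe_sample(rng, {1: 0.4, 2: 0.3, 3: 0.3}, 80)
    assert linkage_test(gs, list(gs), reps=999, seed=3) <= 2 / 1000 + 1e-12


def test_linkage_monomorphic_pair():
    a = [G(1, 1)] * 30
    b = [G(2, 3)] * 30
    assert linkage_test(a, b, reps=1000, seed=0) == 1.0


def test_linkage_independent_loci_not_rejected(rng):
    a = hwe_sample(rng, {1: 0.5, 2: 0.5}, 100)
    b = hwe_sample(rng, {3: 0.6, 4: 0.4}, 100)
    assert linkage_test(a, b, reps=999, seed=5) > 0.01


# ---------------------------------------------------------------------------
# type-I error calibration (null simulations)

def test_hwe_type_one_error_calibrated(rng):
    freqs = {a: 0.25 for a in range(4)}
    rejections = 0
    n_sims = 1000
    for i in range(n_sims):
        gs = hwe_sample(rng, freqs, 50)
        if hwe_test(gs, reps=1000, seed=i) <= 0.05:
            rejections += 1
    assert abs(rejections / n_sims - 0.05) <= 0.02


def test_linkage_type_one_error_calibrated(rng):
    freqs = {a: 0.25 for a in range(4)}
    rejections = 0
    n_sims = 400
    for i in range(n_sims):
        a = hwe_sample(rng, freqs, 50)
        b = hwe_sample(rng, freqs, 50)
        if linkage_test(a, b, reps=500, seed=i) <= 0.05:
            rejections += 1
    assert abs(rejections / n_sims - 0.05) <= 0.03
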