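"""Closed-form model layer: E(N), the p-hat inversion, Jukes-Cantor
transform, the distance estimators, and the analytic variance of N."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spacedist import (
    DnaSequence,
    EvoModelParams,
    SimConfig,
    background_q,
    count_matches,
    distance_dN,
    distance_dRC,
    distance_dloc,
    estimate_p,
    expected_N,
    jc_distance,
    jc_match_probability,
    parse_pattern,
    PatternSet,
    random_pattern_set,
    random_sequence,
    reverse_complement,
    simulate_pair,
    evolve_jc,
    variance_N,
    variance_N_normalized,
)
from .conftest import random_dna, single_pattern_set


# -- background match probability ---------------------------------------------

@pytest.mark.parametrize(
    "freqs, q",
    [((0.25, 0.25, 0.25, 0.25), 0.25), ((1, 0, 0, 0), 1.0), ((0.5, 0.5, 0, 0), 0.5)],
)
def test_background_q_from_frequencies(freqs, q):
    assert background_q(freqs) == pytest.approx(q)


def test_background_q_validates_input():
    with pytest.raises(ValueError):
        background_q((0.5, 0.5, 0.5, 0))
    assert background_q(fixed=0.25) == 0.25


# -- expected N ---------------------------------------------------------------

def test_expected_N_direct_evaluation():
    params = EvoModelParams(p=0.75, q=0.25, k=3, length=4, m=1, L=10)
    # 7 * 0.421875 + 42 * 0.015625
    assert expected_N(params) == pytest.approx(3.609375)


def test_expected_N_collapses_when_p_equals_q():
    params = EvoModelParams(p=0.25, q=0.25, k=4, length=6, m=3, L=50)
    assert expected_N(params) == pytest.approx(3 * (50 - 6 + 1) ** 2 * 0.25**4)


def test_expected_N_diagonal_only_when_background_vanishes():
    params = EvoModelParams(p=1.0, q=1e-300, k=5, length=5, m=2, L=30)
    assert expected_N(params) == pytest.approx(2 * (30 - 5 + 1))


def test_expected_N_missing_fields_error():
    with pytest.raises(ValueError):
        expected_N(EvoModelParams(p=0.5, L=None), "global")
    with pytest.raises(ValueError):
        expected_N(EvoModelParams(p=0.5, L=100), "local")


# -- p-hat inversion ----------------------------------------------------------

@given(
    p=st.floats(0.3, 1.0),
    q=st.floats(0.05, 0.3),
    k=st.integers(2, 12),
    extra=st.integers(0, 6),
    m=st.integers(1, 20),
    L=st.integers(50, 5000),
)
def test_estimate_p_inverts_expected_N(p, q, k, extra, m, L):
    """estimate_p(expected_N(p)) recovers p to 1e-9 for any parameter tuple."""
    if p < q:
        p, q = q, p
    params = EvoModelParams(p=p, q=q, k=k, length=k + extra, m=m, L=L)
    p_hat, status = estimate_p(expected_N(params), params)
    assert status in ("ok", "saturated")
    assert p_hat == pytest.approx(p, abs=1e-9)


def test_estimate_p_rc_inverts_rc_expectation():
    params = EvoModelParams(p=0.6, q=0.25, k=5, length=8, m=4, L1=300, L2=500)
    p_hat, status = estimate_p(expected_N(params, "rc"), params, "rc")
    assert status == "ok" and p_hat == pytest.approx(0.6, abs=1e-9)


def test_estimate_p_local_inverts_local_expectation():
    params = EvoModelParams(p=0.7, q=0.25, k=5, length=8, m=2, L1=400, L2=600, L_hom=200)
    p_hat, status = estimate_p(expected_N(params, "local"), params, "local")
    assert status == "ok" and p_hat == pytest.approx(0.7, abs=1e-9)


def test_estimate_p_zero_count_flags_nonpositive_radicand():
    params = EvoModelParams(q=0.25, k=3, length=4, m=1, L=100)
    p_hat, status = estimate_p(0, params)
    assert p_hat is None and status == "radicand_nonpositive"


# -- Jukes-Cantor transform ---------------------------------------------------

def test_jc_distance_values_and_domain():
    assert jc_distance(1.0) == (pytest.approx(0.0), "ok")
    assert jc_distance(0.7)[0] == pytest.approx(0.38312, abs=1e-5)
    d, status = jc_distance(0.25)
    assert d is None and status == "jc_domain_violation"


@given(st.floats(0.2500001, 1.0), st.floats(0.2500001, 1.0))
def test_jc_distance_is_strictly_decreasing(a, b):
    if a == b:
        return
    lo, hi = sorted((a, b))
    assert jc_distance(hi)[0] < jc_distance(lo)[0]


def test_jc_transform_inverts_match_probability():
    for d in (0.05, 0.3, 0.8, 1.5):
        est, _ = jc_distance(jc_match_probability(d))
        assert est == pytest.approx(d, rel=1e-12)


# -- distance estimators ------------------------------------------------------

def test_identical_sequences_have_zero_binary_distance(rng):
    # high weight makes background correction and word collisions < 1e-6
    s = random_dna(rng, 2000)
    res = distance_dN(s, s, single_pattern_set("1" * 16), mode="binary")
    assert res.status == "ok"
    assert res.d == pytest.approx(0.0, abs=1e-6)


def test_disjoint_alphabet_pair_is_undefined():
    s1 = DnaSequence("a", "A" * 50)
    s2 = DnaSequence("b", "C" * 50)
    res = distance_dN(s1, s2, single_pattern_set("111"))
    assert res.d is None and res.status == "radicand_nonpositive"


def test_dN_recovers_simulated_distance(rng):
    """Mean multiple-pattern estimate at d=0.5 stays within +/-0.05."""
    pset = random_pattern_set(9, 15, 20, seed=99)
    est = []
    for _ in range(5):
        s1, s2 = simulate_pair(SimConfig(L=30_000, d=0.5), rng)
        res = distance_dN(s1, s2, pset)
        assert res.ok
        est.append(res.d)
    assert np.mean(est) == pytest.approx(0.5, abs=0.05)


def test_dloc_matches_dN_for_global_homology(rng):
    """With L_hom = L the local estimator differs from d_N only by the
    fringe difference between L* and (L-l)(L-l+1)."""
    pset = random_pattern_set(9, 15, 10, seed=42)
    s1, s2 = simulate_pair(SimConfig(L=100_000, d=0.3), rng)
    d_glob = distance_dN(s1, s2, pset).d
    d_loc = distance_dloc(s1, s2, pset, L_hom=100_000).d
    assert abs(d_loc - d_glob) < 0.01


def test_dloc_recovers_embedded_homology(rng):
    """A 5 kb homologous segment (d=0.2) inside unrelated 25 kb flanks is
    recovered once the homology length is supplied."""
    pset = random_pattern_set(9, 15, 10, seed=4)
    est = []
    for _ in range(20):
        core = random_dna(rng, 5000, "core")
        s1 = DnaSequence("s1", random_dna(rng, 25_000).residues + core.residues
                         + random_dna(rng, 25_000).residues)
        evolved = evolve_jc(core, 0.2, rng)
        s2 = DnaSequence("s2", random_dna(rng, 25_000).residues + evolved.residues
                         + random_dna(rng, 25_000).residues)
        res = distance_dloc(s1, s2, pset, L_hom=5000)
        if res.d is not None:
            est.append(res.d)
    assert np.mean(est) == pytest.approx(0.2, abs=0.1)


def test_dloc_homology_shorter_than_pattern_errors(rng):
    s1, s2 = random_dna(rng, 100, "a"), random_dna(rng, 100, "b")
    with pytest.raises(ValueError):
        distance_dloc(s1, s2, random_pattern_set(3, 6, 2, seed=1), L_hom=5)


def test_dRC_is_exactly_strand_invariant(rng):
    pset = random_pattern_set(5, 8, 5, seed=21)
    s1, s2 = random_dna(rng, 400, "a"), random_dna(rng, 400, "b")
    flipped = reverse_complement(s2)
    for mode in ("full", "binary"):
        a = distance_dRC(s1, s2, pset, mode)
        b = distance_dRC(s1, flipped, pset, mode)
        assert a.N_used == b.N_used
        assert a.d == b.d and a.status == b.status


def test_dRC_recovers_distance_with_half_strand_flipped(rng):
    """Flipping the second half of S2 onto the other strand must not
    perturb the strand-aware estimate."""
    pset = random_pattern_set(9, 15, 20, seed=77)
    est = []
    for _ in range(5):
        s1, s2 = simulate_pair(SimConfig(L=30_000, d=0.3), rng)
        half = len(s2) // 2
        flipped = DnaSequence(
            "flip",
            s2.residues[:half]
            + reverse_complement(DnaSequence("h", s2.residues[half:])).residues,
        )
        res = distance_dRC(s1, flipped, pset)
        assert res.ok
        est.append(res.d)
    assert np.mean(est) == pytest.approx(0.3, abs=0.05)


def test_dRC_unrelated_sequences_mostly_undefined(rng):
    pset = random_pattern_set(9, 15, 10, seed=31)
    statuses = []
    for _ in range(20):
        s1 = random_dna(rng, 5000, "a")
        s2 = random_dna(rng, 5000, "b")
        statuses.append(distance_dRC(s1, s2, pset).status)
    # the background-corrected radicand is zero in expectation for
    # unrelated pairs, so roughly half the replicates are undefined
    assert statuses.count("radicand_nonpositive") >= 6


# -- variance of N ------------------------------------------------------------

def test_variance_vanishes_when_p_and_q_are_one():
    pset = single_pattern_set("1101")
    assert variance_N(1.0, 1.0, pset, 500) == 0.0


def test_periodic_pattern_variance_equals_contiguous():
    """The periodic pattern 10101 has the same covariance structure as the
    contiguous pattern of its weight: odd shifts contribute nothing, even
    shifts reproduce the contiguous overlap profile.  The variance is
    identical once the window counts are matched (10101 spans two more
    positions, so compare at L and L-2) and agrees up to that fringe at
    equal L."""
    for p in (0.3, 0.75):
        v_periodic = variance_N(p, 0.25, single_pattern_set("10101"), 2000)
        v_contig = variance_N(p, 0.25, single_pattern_set("111"), 2000)
        v_contig_matched = variance_N(p, 0.25, single_pattern_set("111"), 1998)
        assert v_periodic == pytest.approx(v_contig_matched, rel=1e-12)
        assert v_periodic == pytest.approx(v_contig, rel=5e-3)


def test_variance_requires_homogeneous_patterns():
    with pytest.raises(Exception):
        variance_N(0.75, 0.25, PatternSet((parse_pattern("111"), parse_pattern("1101"))), 100)


def test_variance_rejects_invalid_probabilities():
    with pytest.raises(ValueError):
        variance_N(0.2, 0.25, single_pattern_set("111"), 100)  # p < q


def test_mean_and_variance_of_N_match_monte_carlo(rng):
    """Empirical mean and variance of N over 2000 gap-free pairs at L=1000
    agree with the closed forms within 3 standard errors (contiguous
    pattern, p=0.75)."""
    pset = single_pattern_set("1" * 8)
    p = 0.75
    d = jc_distance(p)[0]
    n_rep = 2000
    Ns = np.empty(n_rep)
    for r in range(n_rep):
        s1, s2 = simulate_pair(SimConfig(L=1000, d=d), rng)
        Ns[r] = count_matches(s1, s2, pset).N
    params = EvoModelParams(p=p, q=0.25, k=8, length=8, m=1, L=1000)
    mean_se = Ns.std(ddof=1) / math.sqrt(n_rep)
    assert abs(Ns.mean() - expected_N(params)) < 3 * mean_se
    var_emp = Ns.var(ddof=1)
    var_se = var_emp * math.sqrt(2.0 / (n_rep - 1))
    assert abs(var_emp - variance_N(p, 0.25, pset, 1000)) < 3 * var_se


@pytest.mark.parametrize("p", [0.3, 0.75])
def test_variance_ordering_contiguous_spaced_multiple(p):
    """At L=16000, k=8: Var(N/m) contiguous > single non-periodic spaced
    pattern > random multi-pattern set (m=10)."""
    L, q = 16_000, 0.25
    contig = single_pattern_set("1" * 8)
    single = random_pattern_set(8, 14, 1, seed=3)
    multi = random_pattern_set(8, 14, 10, seed=3)
    v_contig = variance_N_normalized(p, q, contig, L)
    v_single = variance_N_normalized(p, q, single, L)
    v_multi = variance_N_normalized(p, q, multi, L)
    assert v_contig > v_single > v_multi
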