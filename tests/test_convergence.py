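"""Codon-identity counting and the two Monte-Carlo null models."""

import numpy as np
import pytest

from midas_mhc.convergence import (
    CodonIdentityCounts,
    ancestry_null,
    convergence_null,
    convergence_test,
    estimate_p_syn,
    expected_identity,
    observed_codon_identity,
    pooled_codon_usage,
)


def test_single_shared_allele_gives_full_identity():
    pool = {"a1": "TTTGGG"}
    counts = observed_codon_identity(pool, pool, [1, 2])
    assert counts.proportion == 1.0
    assert counts.n_identical_aa == 2


def test_synonymous_codon_pair_counts_amino_but_not_codon():
    counts = observed_codon_identity({"a": "TTT"}, {"b": "TTC"}, [1])
    assert counts.n_identical_aa == 1
    assert counts.n_identical_codon == 0


def test_different_amino_acids_do_not_count():
    counts = observed_codon_identity({"a": "TTTAAA"}, {"b": "GGGAAA"}, [1, 2])
    assert counts.n_identical_aa == 1  # only the Lys codon


def test_empty_pool_errors():
    with pytest.raises(ValueError, match="empty"):
        observed_codon_identity({}, {"b": "TTT"}, [1])


def test_result_invariant_to_allele_ordering():
    A = {"a1": "TTTGGGCAT", "a2": "TTCGGACAC"}
    B = {"b1": "TTAGGGCAT", "b2": "TTTGGCCAT"}
    c1 = observed_codon_identity(A, B, [1, 2, 3])
    c2 = observed_codon_identity(dict(reversed(list(A.items()))),
                                 dict(reversed(list(B.items()))), [3, 2, 1])
    assert (c1.n_identical_aa, c1.n_identical_codon) == (c2.n_identical_aa, c2.n_identical_codon)


def test_single_codon_amino_acid_always_identical_in_null():
    counts = CodonIdentityCounts(n_identical_aa=50, n_identical_codon=48,
                                 aa_events={"M": 50})
    usage = {"M": {"ATG": 1.0}}
    null = convergence_null(counts, usage, reps=200, seed=0)
    assert (null == 50).all()


def test_convergence_null_mean_matches_sum_of_squared_frequencies():
    counts = CodonIdentityCounts(n_identical_aa=1000, n_identical_codon=500,
                                 aa_events={"G": 1000})
    usage = {"G": {c: 0.25 for c in ("GGT", "GGC", "GGA", "GGG")}}
    null = convergence_null(counts, usage, reps=1000, seed=1)
    mean_prop = null.mean() / 1000
    se = null.std(ddof=1) / 1000 / np.sqrt(1000)
    assert abs(mean_prop - 0.25) < 3 * se
    assert expected_identity(usage, counts.aa_events) == pytest.approx(0.25)


def test_ancestry_null_closed_form_and_psyn_zero():
    counts = CodonIdentityCounts(n_identical_aa=500, n_identical_codon=400,
                                 aa_events={"F": 500})
    usage = {"F": {"TTT": 0.5, "TTC": 0.5}}
    all_identical = ancestry_null(counts, 0.0, usage, reps=100, seed=2)
    assert (all_identical == 500).all()
    # p_syn = 0.2, uniform 2-codon usage: q = 0.8 + 0.2 * 0.5 = 0.9
    null = ancestry_null(counts, 0.2, usage, reps=1000, seed=3)
    mean_prop = null.mean() / 500
    se = null.std(ddof=1) / 500 / np.sqrt(1000)
    assert abs(mean_prop - 0.9) < 3 * se
    assert expected_identity(usage, counts.aa_events, p_syn=0.2) == pytest.approx(0.9)


def test_missing_amino_acid_in_usage_errors():
    counts = CodonIdentityCounts(n_identical_aa=1, n_identical_codon=1,
                                 aa_events={"W": 1})
    with pytest.raises(ValueError, match="absent"):
        convergence_null(counts, {"M": {"ATG": 1.0}}, reps=10, seed=0)


def test_p_syn_estimator_inverts_recoincidence():
    # pools identical except a synonymous difference at codon 2 of one allele
    A = {"a1": "TTTGGG", "a2": "TTTGGA"}
    B = {"b1": "TTTGGG", "b2": "TTTGGA"}
    usage = pooled_codon_usage(A, B, pseudocount=0.0)
    p = estimate_p_syn(A, B, exclude_positions=[1], usage=usage)
    # raw difference fraction at codon 2 is 0.5; f2 for Gly here is 0.5
    assert p == pytest.approx(0.5 / (1 - 0.5))


def test_full_test_on_hand_built_pools():
    A = {"a1": "TTTGGGAAA", "a2": "TTTGGAAAA"}
    B = {"b1": "TTTGGGAAA"}
    res = convergence_test(A, B, [1], reps=500, seed=5)
    assert res.counts.n_identical_aa == 2
    assert res.observed_proportion == 1.0
    assert 1 / 501 <= res.p_ancestry_mc <= 1.0
    assert 1 / 501 <= res.p_convergence_mc <= 1.0
    assert res.preferred_scenario in ("co_ancestry", "convergence")


def test_no_shared_states_errors():
    with pytest.raises(ValueError, match="no shared amino-acid states"):
        convergence_test({"a": "TTT"}, {"b": "GGG"}, [1], reps=10, seed=0)
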