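"""Divergence statistics: GLM/LM models, multivariate pool test, NMDS."""

import numpy as np
import pandas as pd
import pytest

from midas_mhc.divergence import (
    diversity_models,
    multivariate_pool_test,
    nmds,
    pairwise_pool_tests,
)
from midas_mhc.io import GenotypeTable
from tests.conftest import make_genotypes


def _two_group_samples(n_per: int) -> pd.DataFrame:
    n = 2 * n_per
    return pd.DataFrame({
        "individual_id": [f"i{j}" for j in range(n)],
        "population": ["p1"] * n_per + ["p2"] * n_per,
        "lake": ["l1"] * n_per + ["l2"] * n_per,
        "lake_type": ["crater"] * n,
        "habitat": ["limnetic"] * n,
    })


def _binary_matrix(rng, probs_a, probs_b, n_per):
    Y = np.vstack([
        rng.random((n_per, len(probs_a))) < probs_a,
        rng.random((n_per, len(probs_b))) < probs_b,
    ]).astype(int)
    Y[Y.sum(axis=1) == 0, -1] = 1  # no empty individuals
    return Y


def test_statistic_zero_when_groups_identical():
    samples = _two_group_samples(6)
    Y = np.tile([1, 0, 1, 0, 1], (12, 1))
    Y[:, 0] = [1, 0] * 6  # one variable allele, same pattern in both groups
    gt = make_genotypes(Y, samples)
    with pytest.warns(UserWarning, match="dropping"):
        res = multivariate_pool_test(gt, terms=["lake"], n_resamples=49, seed=0)
    assert res.terms["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert set(res.dropped_alleles) == {"a2", "a3", "a4", "a5"}


def test_statistic_additive_over_alleles():
    rng = np.random.default_rng(1)
    samples = _two_group_samples(20)
    probs_a = np.array([0.8, 0.3, 0.5, 0.5])
    probs_b = np.array([0.2, 0.7, 0.5, 0.5])
    Y = _binary_matrix(rng, probs_a, probs_b, 20)
    gt = make_genotypes(Y, samples)
    res = multivariate_pool_test(gt, terms=["lake"], n_resamples=9, seed=0)
    uni = res.univariate["lake"]
    assert res.terms["statistic"].iloc[0] == pytest.approx(uni["statistic"].sum())


def test_planted_presence_shift_detected_with_flagged_alleles():
    rng = np.random.default_rng(2)
    n_per, n_planted, n_noise = 40, 10, 20
    samples = _two_group_samples(n_per)
    probs_a = np.array([0.8] * n_planted + [0.5] * n_noise)
    probs_b = np.array([0.2] * n_planted + [0.5] * n_noise)
    Y = _binary_matrix(rng, probs_a, probs_b, n_per)
    gt = make_genotypes(Y, samples)
    res = multivariate_pool_test(gt, terms=["lake"], n_resamples=199, seed=3)
    assert res.terms["p_value"].iloc[0] < 0.05
    uni = res.univariate["lake"]
    planted = [f"a{j + 1}" for j in range(n_planted)]
    flagged = set(uni.loc[uni["p_adj"] < 0.05, "allele"])
    assert len(flagged & set(planted)) >= 8


def test_adjusted_pvalues_dominate_raw():
    rng = np.random.default_rng(4)
    samples = _two_group_samples(15)
    Y = _binary_matrix(rng, np.full(12, 0.5), np.full(12, 0.5), 15)
    gt = make_genotypes(Y, samples)
    res = multivariate_pool_test(gt, terms=["lake"], n_resamples=99, seed=5)
    uni = res.univariate["lake"]
    assert (uni["p_adj"] >= uni["p_raw"] - 1e-12).all()


def test_sequential_terms_with_interaction_run():
    rng = np.random.default_rng(6)
    n = 80
    samples = pd.DataFrame({
        "individual_id": [f"i{j}" for j in range(n)],
        "population": [f"p{j % 4 + 1}" for j in range(n)],
        "lake": ["l1"] * 40 + ["l2"] * 40,
        "lake_type": ["crater"] * n,
        "habitat": (["limnetic"] * 20 + ["rocky"] * 20) * 2,
    })
    Y = (rng.random((n, 15)) < 0.5).astype(int)
    Y[Y.sum(axis=1) == 0, 0] = 1
    gt = make_genotypes(Y, samples)
    res = multivariate_pool_test(gt, terms=["lake", "habitat", "lake:habitat"],
                                 n_resamples=49, seed=7)
    assert list(res.terms["term"]) == ["lake", "habitat", "lake:habitat"]
    assert (res.terms["statistic"] >= 0).all()


def test_pairwise_tests_apply_bh_correction(small_truth):
    out = pairwise_pool_tests(small_truth.genotypes, "population",
                              n_resamples=49, seed=1)
    assert len(out) == 6  # 4 populations
    assert (out["p_bh"] >= out["p_raw"] - 1e-12).all()
    order = out.sort_values("p_raw")
    assert order["p_bh"].is_monotonic_increasing


def test_diversity_models_single_level_factor_errors(small_truth, small_catalog):
    from midas_mhc.diversity import individual_diversity
    idx = individual_diversity(small_truth.genotypes, small_catalog)
    idx["lake"] = "only_one"
    with pytest.raises(ValueError, match="fewer than 2 levels"):
        diversity_models(idx, design=["lake"])


def test_diversity_models_detect_planted_count_effect():
    rng = np.random.default_rng(8)
    n_per = 40
    rows = []
    for g, (lake, mean) in enumerate([("l1", 6.0), ("l2", 8.0)]):
        for j in range(n_per):
            rows.append({
                "individual_id": f"i{g}_{j}", "population": f"p{g + 1}",
                "lake": lake, "lake_type": "crater", "habitat": "limnetic",
                "n_alleles": max(1, rng.poisson(mean)),
                "pi": rng.normal(0.25, 0.02),
            })
    idx = pd.DataFrame(rows)
    res = diversity_models(idx, count_responses=["n_alleles"],
                           continuous_responses=["pi"], design=["lake"],
                           posthoc_factors=["lake"])
    tab = res.table.set_index(["response", "term"])
    assert tab.loc[("n_alleles", "lake"), "p_value"] < 0.05
    assert tab.loc[("pi", "lake"), "p_value"] > 0.001  # no planted effect
    assert ("n_alleles", "lake") in res.posthoc


def test_nmds_separates_disjoint_allele_blocks():
    samples = _two_group_samples(10)
    rng = np.random.default_rng(9)
    left = (rng.random((10, 8)) < 0.7).astype(int)
    right = (rng.random((10, 8)) < 0.7).astype(int)
    Y = np.zeros((20, 16), int)
    Y[:10, :8] = left
    Y[10:, 8:] = right
    Y[Y.sum(axis=1) == 0, 0] = 1
    Y[10:][Y[10:].sum(axis=1) == 0, 8] = 1
    gt = make_genotypes(Y, samples)
    res = nmds(gt, n_dims=2, n_starts=15, seed=0)
    axis = res.coordinates["MDS1"].to_numpy()
    # complete separation of the two blocks on the first axis
    assert (axis[:10].max() < axis[10:].min()) or (axis[10:].max() < axis[:10].min())


def test_nmds_deterministic_given_seed(small_truth):
    a = nmds(small_truth.genotypes, n_dims=3, n_starts=10, seed=4)
    b = nmds(small_truth.genotypes, n_dims=3, n_starts=10, seed=4)
    assert a.stress == b.stress
    assert np.allclose(a.coordinates.iloc[:, 1:], b.coordinates.iloc[:, 1:])


def test_nmds_rejects_degenerate_input(toy_samples):
    Y = np.ones((3, 4), int)
    gt = make_genotypes(Y, toy_samples)
    with pytest.raises(ValueError, match="zero dissimilarity"):
        nmds(gt, n_dims=1, n_starts=2, seed=0)
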