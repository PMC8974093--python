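"""Distance estimators: p-distances, Nei-Gojobori dN/dS, codon Z-test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import Seq

from midas_mhc.diversity import (
    DistanceConfig,
    codon_differences,
    codon_site_fractions,
    codon_z_test,
    individual_diversity,
    nei_gojobori,
    p_distance,
    pairwise_nei_gojobori,
)
from midas_mhc.synthdata import SimulationConfig, simulate_allele_pool, simulate_populations


# ---------------------------------------------------------------------------
# independent brute-force oracle for Nei-Gojobori codon counts

_SENSE = [c for c in ("".join(p) for p in itertools.product("TCAG", repeat=3))
          if str(Seq(c).translate()) != "*"]


def _oracle_sites(codon):
    """Fraction of the three possible changes per position that are synonymous."""
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        for nt in "TCAG":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            m_aa = str(Seq(mut).translate())
            if m_aa != "*" and m_aa == aa:
                s += 1 / 3
    return s, 3 - s


def _oracle_diffs(c1, c2):
    """Average synonymous/nonsynonymous steps over minimal paths, skipping
    paths through stop codons (all paths if every one is blocked)."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    clean, blocked = [], []
    for order in itertools.permutations(pos):
        cur, sd, nd, hit_stop = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if str(Seq(nxt).translate()) == "*":
                hit_stop = True
                nd += 1
            elif str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else clean).append((sd, nd))
    use = clean or blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.sampled_from(_SENSE), st.sampled_from(_SENSE))
def test_codon_counts_match_bruteforce_path_enumeration(c1, c2):
    assert codon_site_fractions(c1) == pytest.approx(_oracle_sites(c1))
    sd, nd = codon_differences(c1, c2)
    osd, ond = _oracle_diffs(c1, c2)
    assert sd == pytest.approx(osd)
    assert nd == pytest.approx(ond)


def test_worked_example_single_codon_pair():
    # TTT vs TTA: mean synonymous sites 0.5, one nonsynonymous difference
    r = nei_gojobori(["TTT", "TTA"], DistanceConfig(bootstrap=0))
    assert r.ds == 0.0
    assert r.dn == pytest.approx(-0.75 * np.log(1 - 4 / 3 * 0.4), rel=1e-9)


def test_identical_sequences_have_zero_distances():
    seqs = ["ATGGCATTA"] * 4
    r = nei_gojobori(seqs, DistanceConfig(bootstrap=0))
    assert r.dn == 0.0 and r.ds == 0.0
    assert p_distance(seqs, DistanceConfig(bootstrap=0)).distance == 0.0


def test_jc_correction_undefined_error_names_pair():
    # every codon differs nonsynonymously -> pN = 1 >= 3/4
    with pytest.raises(ValueError, match="Jukes-Cantor"):
        nei_gojobori(["TGGTGGTGG", "CCCCCCCCC"], DistanceConfig(bootstrap=0))


def test_p_distance_hand_counts():
    a = "A" * 142
    b = "A" * 141 + "T"
    r = p_distance([a, b], DistanceConfig(bootstrap=50, seed=0))
    assert r.distance == pytest.approx(1 / 142)
    with pytest.raises(ValueError, match="at least 2"):
        p_distance([a])
    with pytest.raises(ValueError, match="comparable"):
        p_distance(["--", "AA"], DistanceConfig(bootstrap=0))


def test_gamma_corrected_distance_exceeds_plain():
    seqs = ["ATGGCATTA", "ATGGGATTC"]
    plain = p_distance(seqs, DistanceConfig(bootstrap=0)).distance
    gamma = p_distance(seqs, DistanceConfig(bootstrap=0, gamma_shape=0.39)).distance
    assert gamma > plain


def test_pairwise_symmetry_and_nonnegativity(small_catalog):
    seqs = list(small_catalog.alleles.values())[:12]
    dn, ds = pairwise_nei_gojobori(seqs)
    assert np.allclose(dn, dn.T) and np.allclose(ds, ds.T)
    assert (dn >= 0).all() and (ds >= 0).all()


def test_bootstrap_se_shrinks_with_duplicated_sequences(small_catalog):
    seqs = list(small_catalog.alleles.values())[:6]
    cfg = DistanceConfig(bootstrap=200, seed=1)
    base = p_distance(seqs, cfg)
    dup = p_distance(seqs * 4, cfg)
    # duplicating sequences leaves the mean-over-pairs nearly unchanged but
    # only tightens the site bootstrap
    assert dup.se <= base.se * 1.25


def test_z_test_zero_when_alignment_has_no_differences():
    r = codon_z_test(["ATGGCATTA"] * 3, DistanceConfig(bootstrap=100, seed=0))
    assert r.z == 0.0


def test_z_test_detects_planted_nonsynonymous_excess():
    # codon-locked pools differ only by amino-acid-changing codons, i.e. a
    # pure nonsynonymous excess at the variable ~30% of codons
    hits = 0
    runs = 5
    for i in range(runs):
        cfg = SimulationConfig(n_alleles=50, fragment_codons=30,
                               prop_variable_sites=0.3, site_sub_prob=0.3,
                               codon_locked_pool=True, seed=100 + i)
        cat = simulate_allele_pool(cfg)
        r = codon_z_test(list(cat.alleles.values()),
                         DistanceConfig(bootstrap=500, seed=i, deletion="partial"))
        hits += (r.z > 0) and (r.p_value < 0.05)
    assert hits >= 4


def test_individual_diversity_hand_count_and_single_allele(small_catalog, toy_samples):
    import pandas as pd
    from midas_mhc.io import AlleleCatalog, GenotypeTable

    base = "ATG" + "GCA" * 46
    var2 = base[:4] + "T" + base[5:11] + "T" + base[12:]  # differs at 2 of 141 sites
    cat = AlleleCatalog(alleles={"x": base, "y": var2})
    m = pd.DataFrame([[1, 1], [1, 0], [1, 1]], index=["i1", "i2", "i3"],
                     columns=["x", "y"])
    gt = GenotypeTable(matrix=m, samples=toy_samples)
    idx = individual_diversity(gt, cat).set_index("individual_id")
    assert idx.loc["i1", "pi"] == pytest.approx(2 / 141)
    assert idx.loc["i2", "n_alleles"] == 1
    assert np.isnan(idx.loc["i2", "pi"])


def test_aa_pdist_and_dn_positively_correlated(small_truth, small_catalog):
    idx = individual_diversity(small_truth.genotypes, small_catalog).dropna()
    r = np.corrcoef(idx["aa_p_dist"], idx["dn"])[0, 1]
    assert r > 0
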