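"""The generator reproduces the structure the pipeline assumes, bit-reproducibly."""

import numpy as np
import pytest

from midas_mhc.io import translate_nt
from midas_mhc.synthdata import (
    SimulationConfig,
    codon_resample,
    empirical_codon_usage,
    simulate_allele_pool,
    simulate_populations,
    simulate_reads,
    synonymous_shuffle,
    write_reads_fastq,
)


def test_pool_is_unique_and_stop_free():
    cfg = SimulationConfig(n_alleles=150, seed=1)
    cat = simulate_allele_pool(cfg)
    assert len(cat) == 150
    assert len(set(cat.alleles.values())) == 150
    assert all("*" not in t for t in cat.translations.values())
    assert all(len(s) == 141 for s in cat.alleles.values())


def test_single_allele_pool_is_the_ancestral_sequence():
    cfg = SimulationConfig(n_alleles=1, seed=3)
    cat = simulate_allele_pool(cfg)
    assert list(cat.alleles) == ["ac001"]


def test_same_seed_reproduces_catalog_and_fastq_bytes(tmp_path):
    cfg = SimulationConfig(n_alleles=12, n_populations=2,
                           n_individuals_per_population=2,
                           depth_mean=120, depth_range=(80, 200),
                           scenario="none", seed=7)
    runs = []
    for d in ("a", "b"):
        cat = simulate_allele_pool(cfg)
        truth = simulate_populations(cat, cfg)
        reads = simulate_reads(truth, cfg)
        paths = write_reads_fastq(reads, tmp_path / d)
        runs.append((cat.alleles, {p.name: p.read_bytes() for p in paths}))
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]


def test_infeasible_pool_request_errors():
    cfg = SimulationConfig(n_alleles=100, fragment_codons=2,
                           prop_variable_sites=0.2, seed=0)
    with pytest.raises(ValueError, match="unique alleles"):
        simulate_allele_pool(cfg)


def test_planted_artifacts_have_expected_defects():
    cfg = SimulationConfig(n_alleles=10, plant_stop_allele=True,
                           plant_nonclassical=True, seed=5)
    cat = simulate_allele_pool(cfg)
    assert len(cat.alleles["art_frameshift"]) == 140
    assert not cat.classical["nonclassical01"]


def test_codon_locked_pool_shares_codons_at_shared_residues():
    cfg = SimulationConfig(n_alleles=20, codon_locked_pool=True, seed=9)
    cat = simulate_allele_pool(cfg)
    seqs = list(cat.alleles.values())
    for s in seqs[1:]:
        a, b = seqs[0], s
        for i in range(47):
            ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
            if translate_nt(ca) == translate_nt(cb):
                assert ca == cb


def test_co_ancestry_with_psyn_zero_gives_full_codon_identity():
    cfg = SimulationConfig(n_alleles=8, n_populations=2,
                           n_individuals_per_population=2,
                           pool_size_range=(4, 4), scenario="co_ancestry",
                           p_syn=0.0, codon_locked_pool=True, seed=2)
    cat = simulate_allele_pool(cfg)
    truth = simulate_populations(cat, cfg)
    pa, pb = truth.scenario_pair
    for a in truth.pools[pa]:
        assert truth.pop_sequences[pa][a] == truth.pop_sequences[pb][a]
    assert truth.provenance.empty


def test_synonymous_shuffle_preserves_translation_and_records_changes():
    rng = np.random.default_rng(0)
    seq = "CTTCGAATGGGC" * 4  # Leu Arg Met Gly: Met cannot change
    new, changed = synonymous_shuffle(seq, 1.0, rng)
    assert translate_nt(new) == translate_nt(seq)
    n_codons = len(seq) // 3
    # every degenerate codon changed (p=1) and was recorded; Met never changes
    assert len(changed) == n_codons - 4  # 4 Met codons
    for i in range(n_codons):
        codon_old, codon_new = seq[3 * i : 3 * i + 3], new[3 * i : 3 * i + 3]
        if codon_old == "ATG":
            assert codon_new == "ATG"
        else:
            assert codon_new != codon_old


def test_codon_resample_matches_expected_identity_for_uniform_usage():
    # uniform usage over the 4 codons of Gly: two independent draws agree 1/4
    usage = {"G": {c: 0.25 for c in ("GGT", "GGC", "GGA", "GGG")}}
    rng = np.random.default_rng(4)
    n = 4000
    hits = 0
    for _ in range(n):
        a, _ = codon_resample("GGT", usage, rng)
        b, _ = codon_resample("GGT", usage, rng)
        hits += a == b
    p = hits / n
    se = np.sqrt(0.25 * 0.75 / n)
    assert abs(p - 0.25) < 3 * se


def test_co_ancestry_codon_identity_matches_closed_form():
    # two lineages, per-codon synonymous change prob p: identity at a shared
    # codon is (1-p)^2 plus a small re-coincidence term; the term is bounded
    # above by p^2, so the MC mean must land between (1-p)^2 and (1-p)^2+p^2
    p = 0.2
    rng = np.random.default_rng(8)
    seq = "CTTCGAGGCAGT" * 20  # all degenerate codons
    n_codons = len(seq) // 3
    n = 400
    ident = 0
    for _ in range(n):
        a, _ = synonymous_shuffle(seq, p, rng)
        b, _ = synonymous_shuffle(seq, p, rng)
        ident += sum(a[3 * i : 3 * i + 3] == b[3 * i : 3 * i + 3]
                     for i in range(n_codons))
    frac = ident / (n * n_codons)
    lo, hi = (1 - p) ** 2, (1 - p) ** 2 + p**2
    se = np.sqrt(frac * (1 - frac) / (n * n_codons))
    assert lo - 3 * se < frac < hi + 3 * se


def test_error_free_reads_are_exact_allele_copies(small_catalog):
    cfg = SimulationConfig(n_alleles=30, n_populations=2,
                           n_individuals_per_population=3,
                           pool_size_range=(6, 8),
                           depth_mean=500, depth_range=(300, 900),
                           sub_error_rate=0.0, indel_error_rate=0.0,
                           scenario="none", seed=11)
    truth = simulate_populations(small_catalog, cfg)
    reads = simulate_reads(truth, cfg)
    allele_seqs = set(small_catalog.alleles.values())
    for ind, rs in reads.items():
        assert set(rs) <= allele_seqs
        true_seqs = {small_catalog.alleles[a]
                     for a in truth.genotypes.alleles_of(ind)}
        assert set(rs) == true_seqs


def test_substitution_errors_match_binomial_expectation(small_catalog):
    rate = 0.01
    cfg = SimulationConfig(n_alleles=30, n_populations=2,
                           n_individuals_per_population=1,
                           pool_size_range=(4, 4),
                           depth_mean=2000, depth_range=(2000, 2000),
                           depth_sigma=1e-6,
                           sub_error_rate=rate, indel_error_rate=0.0,
                           scenario="none", seed=13)
    truth = simulate_populations(small_catalog, cfg)
    reads = simulate_reads(truth, cfg)
    L = 141
    mismatches = []
    for ind, rs in reads.items():
        true_seqs = [small_catalog.alleles[a]
                     for a in truth.genotypes.alleles_of(ind)]
        for r in rs:
            best = min(sum(x != y for x, y in zip(r, t)) for t in true_seqs)
            mismatches.append(best)
    mean = np.mean(mismatches)
    expect = L * rate
    se = np.sqrt(L * rate * (1 - rate) / len(mismatches))
    assert abs(mean - expect) < 3 * se
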