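"""Frequency-threshold allele calling and coding filters."""

import numpy as np
import pytest

from midas_mhc.genotyping import (
    Genotyper,
    GenotypingConfig,
    call_alleles,
    denoise_reads,
    filter_coding,
)
from midas_mhc.synthdata import SimulationConfig, simulate_allele_pool, simulate_populations, simulate_reads

SEQ = "ATG" + "GCA" * 46  # 141 bp, stop-free


def _variant(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


def test_identical_reads_form_one_full_paf_cluster():
    clusters = denoise_reads([SEQ] * 1000)
    assert len(clusters) == 1
    assert clusters[0].paf == 1.0
    assert clusters[0].sequence == SEQ


def test_minor_one_substitution_variant_absorbed_under_error_model():
    # expected >=1-error reads from the major variant easily exceed 50
    reads = [SEQ] * 950 + [_variant(SEQ, 10, "T")] * 50
    clusters = denoise_reads(reads, GenotypingConfig(sub_error_rate=0.01))
    assert len(clusters) == 1
    assert clusters[0].sequence == SEQ
    assert clusters[0].count == 1000


def test_two_true_alleles_with_zero_error_stay_separate():
    other = _variant(SEQ, 10, "T")
    reads = [SEQ] * 600 + [other] * 400
    clusters = denoise_reads(reads, GenotypingConfig(sub_error_rate=0.0,
                                                     indel_error_rate=0.0))
    assert [round(c.paf, 2) for c in clusters] == [0.6, 0.4]
    assert sum(c.paf for c in clusters) <= 1.0 + 1e-12


def test_denoising_is_read_order_invariant():
    rng = np.random.default_rng(0)
    reads = [SEQ] * 500 + [_variant(SEQ, 5, "C")] * 300 + [_variant(SEQ, 9, "G")] * 7
    shuffled = list(rng.permutation(reads))
    a = denoise_reads(reads, GenotypingConfig())
    b = denoise_reads(shuffled, GenotypingConfig())
    assert [(c.sequence, c.count) for c in a] == [(c.sequence, c.count) for c in b]


def test_empty_read_set_errors():
    with pytest.raises(ValueError, match="empty"):
        denoise_reads([])


def _clusters(pafs, seqs=None):
    seqs = seqs or [_variant(SEQ, i, "T") for i in range(len(pafs))]
    total = 10000
    from midas_mhc.genotyping import VariantCluster
    return [VariantCluster(sequence=s, count=int(p * total), paf=p)
            for s, p in zip(seqs, pafs)]


def test_paf_threshold_keeps_only_sufficient_clusters():
    called = call_alleles(_clusters([0.60, 0.30, 0.012]),
                          GenotypingConfig(paf_threshold=0.015))
    assert len(called) == 2


def test_max_alleles_cap_keeps_top_by_paf():
    pafs = [0.018] * 51
    called = call_alleles(_clusters(pafs), GenotypingConfig(max_alleles=50))
    assert len(called) == 50


def test_no_cluster_above_threshold_errors():
    with pytest.raises(ValueError, match="no alleles called"):
        call_alleles(_clusters([0.01, 0.005]), GenotypingConfig(paf_threshold=0.015))


def test_reference_matching_and_novel_id_minting(small_catalog):
    ref_seq = next(iter(small_catalog.alleles.values()))
    novel = _variant(ref_seq, 1, "T") if ref_seq[1] != "T" else _variant(ref_seq, 1, "C")
    cfg = GenotypingConfig(reference=small_catalog)
    registry = {}
    called = call_alleles(_clusters([0.6, 0.4], seqs=[ref_seq, novel]), cfg, registry)
    ids = [aid for aid, _, _ in called]
    assert ids[0] in small_catalog.allele_ids
    # novel id continues the ac### numbering after the reference catalog
    assert ids[1] not in small_catalog.allele_ids
    assert ids[1].startswith("ac")
    # same novel sequence in a second individual keeps its id
    again = call_alleles(_clusters([1.0], seqs=[novel]), cfg, registry)
    assert again[0][0] == ids[1]


def test_duplicate_amplicons_give_identical_genotypes(small_catalog):
    cfg = SimulationConfig(n_alleles=30, n_populations=2,
                           n_individuals_per_population=2,
                           pool_size_range=(8, 8), depth_mean=1500,
                           depth_range=(1500, 1500), depth_sigma=1e-6,
                           sub_error_rate=0.002, indel_error_rate=0.0,
                           scenario="none", min_true_paf=0.05, seed=21)
    truth = simulate_populations(small_catalog, cfg)
    g = Genotyper(GenotypingConfig(reference=small_catalog))
    reads1 = simulate_reads(truth, cfg)
    cfg2 = SimulationConfig(**{**cfg.__dict__, "seed": 22})
    reads2 = simulate_reads(truth, cfg2)
    for ind in reads1:
        a = {aid for aid, _, _ in g.genotype_individual(reads1[ind])}
        b = {aid for aid, _, _ in g.genotype_individual(reads2[ind])}
        assert a == b


def test_lowering_threshold_never_removes_called_alleles():
    pafs = [0.4, 0.25, 0.1, 0.05, 0.02, 0.012, 0.008]
    clusters = _clusters(pafs)
    previous: set[str] = set()
    for thr in (0.05, 0.03, 0.015, 0.01, 0.005):
        called = {aid for aid, _, _ in
                  call_alleles(clusters, GenotypingConfig(paf_threshold=thr))}
        assert previous <= called
        previous = called


def test_filter_coding_removes_artifacts_keeps_inframe_deletion():
    cfg = SimulationConfig(n_alleles=10, plant_stop_allele=True,
                           plant_nonclassical=True, seed=31)
    cat = simulate_allele_pool(cfg)
    # add an in-frame 3-bp deletion of a clean allele
    base = cat.alleles["ac002"]
    cat.alleles["del3"] = base[:6] + base[9:]
    cat.classical["del3"] = True
    cat.translations["del3"] = cat.translations["ac002"][:2] + cat.translations["ac002"][3:]
    cat.aligned_translations["del3"] = cat.translations["del3"]
    filtered, _ = filter_coding(cat, non_classical_ids=["nonclassical01"])
    assert "art_frameshift" not in filtered.allele_ids
    assert "nonclassical01" not in filtered.allele_ids
    assert "del3" in filtered.allele_ids
    assert len(filtered) == 11


def test_filter_coding_errors_when_individual_loses_all_alleles(toy_samples):
    import pandas as pd
    from midas_mhc.io import AlleleCatalog, GenotypeTable

    good = "ATG" + "GCA" * 46
    bad = good[:50] + good[51:]  # frameshift
    cat = AlleleCatalog(alleles={"g1": good, "b1": bad})
    m = pd.DataFrame([[1, 1], [0, 1], [1, 0]], index=["i1", "i2", "i3"],
                     columns=["g1", "b1"])
    gt = GenotypeTable(matrix=m, samples=toy_samples)
    with pytest.raises(ValueError, match="i2"):
        filter_coding(cat, gt)
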