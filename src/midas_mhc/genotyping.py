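"""Allele calling from merged amplicon reads.

The caller mirrors a frequency-threshold amplicon genotyping workflow:
reads of one individual are dereplicated, low-count variants are absorbed
into higher-count parents when their abundance is compatible with
sequencing error (a binomial error model over the read length), and the
surviving clusters are thresholded on per-amplicon frequency (PAF) and
capped at a maximum number of alleles.  Called sequences are matched to a
reference catalog by exact sequence; novel sequences receive consecutive
``ac###`` identifiers.

The absorption rule is deliberately simple and fully specified: variant v
is absorbed into a more abundant parent p at edit distance d when
``count(v) <= count(p) * P(errors >= d)`` with P from
Binomial(read length, substitution + indel rate).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .io import AlleleCatalog, GenotypeTable, validate_sample_table

__all__ = [
    "GenotypingConfig",
    "VariantCluster",
    "denoise_reads",
    "call_alleles",
    "filter_coding",
    "Genotyper",
]


@dataclass
class GenotypingConfig:
    paf_threshold: float = 0.015
    max_alleles: int = 50
    sub_error_rate: float = 0.01
    indel_error_rate: float = 1e-5
    reference: AlleleCatalog | None = None
    expected_length: int | None = None   # reads outside +/-3 are still clustered
    max_absorb_distance: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.paf_threshold < 1:
            raise ValueError("paf_threshold must be in (0, 1)")
        if self.max_alleles < 1:
            raise ValueError("max_alleles must be >= 1")


@dataclass
class VariantCluster:
    sequence: str
    count: int
    paf: float
    members: list[tuple[str, int, int]] = field(default_factory=list)  # (seq, count, dist)


def _error_prob(d: int, length: int, rate: float) -> float:
    """P(at least d sequencing errors on one read) under Binomial(length, rate)."""
    if d <= 0:
        return 1.0
    return float(stats.binom.sf(d - 1, length, rate))


def denoise_reads(reads: Sequence[str], config: GenotypingConfig | None = None
                  ) -> list[VariantCluster]:
    """Dereplicate and error-cluster one individual's reads.

    Returns clusters sorted by descending PAF (ties broken by sequence so
    the output is independent of read order).
    """
    config = config or GenotypingConfig()
    if len(reads) == 0:
        raise ValueError("empty read set")
    counts = Counter(r.upper() for r in reads)
    total = sum(counts.values())
    # descending count, lexicographic tie-break: order-independent
    variants = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rate = config.sub_error_rate + config.indel_error_rate
    clusters: list[VariantCluster] = []
    for seq, cnt in variants:
        absorbed = False
        for cl in clusters:
            if cl.count <= cnt:
                continue
            res = edlib.align(seq, cl.sequence, mode="NW", task="distance",
                              k=config.max_absorb_distance)
            d = res["editDistance"]
            if d < 0:
                continue
            if cnt <= cl.count * _error_prob(d, len(cl.sequence), rate):
                cl.members.append((seq, cnt, d))
                absorbed = True
                break
        if not absorbed:
            clusters.append(VariantCluster(sequence=seq, count=cnt, paf=0.0,
                                           members=[(seq, cnt, 0)]))
    for cl in clusters:
        cl.count = sum(m[1] for m in cl.members)
        cl.paf = cl.count / total
    clusters.sort(key=lambda c: (-c.paf, c.sequence))
    return clusters


def call_alleles(
    clusters: Sequence[VariantCluster],
    config: GenotypingConfig | None = None,
    novel_registry: dict[str, str] | None = None,
) -> list[tuple[str, str, float]]:
    """Threshold clusters on PAF and name the surviving alleles.

    Returns ``(allele_id, sequence, paf)`` triples.  Sequences matching the
    reference catalog exactly keep the reference id; novel sequences are
    assigned consecutive ``ac###`` ids (``novel_registry`` maps sequence ->
    id and is updated in place so ids stay stable across individuals).
    """
    config = config or GenotypingConfig()
    kept = [c for c in clusters if c.paf >= config.paf_threshold]
    if not kept:
        raise ValueError("no alleles called: no cluster reaches the PAF threshold")
    kept.sort(key=lambda c: (-c.paf, c.sequence))
    kept = kept[: config.max_alleles]
    ref_by_seq: dict[str, str] = {}
    existing_ids: set[str] = set()
    if config.reference is not None:
        ref_by_seq = {s: a for a, s in config.reference.alleles.items()}
        existing_ids = set(config.reference.allele_ids)
    if novel_registry is None:
        novel_registry = {}
    existing_ids |= set(novel_registry.values())

    def next_id() -> str:
        n = 1
        while f"ac{n:03d}" in existing_ids:
            n += 1
        return f"ac{n:03d}"

    out = []
    for c in kept:
        if c.sequence in ref_by_seq:
            aid = ref_by_seq[c.sequence]
        elif c.sequence in novel_registry:
            aid = novel_registry[c.sequence]
        else:
            aid = next_id()
            novel_registry[c.sequence] = aid
            existing_ids.add(aid)
        out.append((aid, c.sequence, c.paf))
    return out


def filter_coding(
    catalog: AlleleCatalog,
    genotypes: GenotypeTable | None = None,
    non_classical_ids: Iterable[str] = (),
    reference_length: int | None = None,
) -> tuple[AlleleCatalog, GenotypeTable | None]:
    """Drop non-classical and non-coding alleles; keep in-frame deletions.

    An allele is removed when (a) its id is on the non-classical exclusion
    list or its catalog flag is False, (b) its ungapped length differs from
    the full-length fragment by a non-multiple of 3 (frameshift), or (c) its
    translation contains an internal stop.  Errors if any individual would
    be left without alleles.
    """
    non_classical = set(non_classical_ids)
    if reference_length is None:
        reference_length = max(len(s) for s in catalog.alleles.values())
    drop: list[str] = []
    for a, s in catalog.alleles.items():
        if a in non_classical or not catalog.classical.get(a, True):
            drop.append(a)
        elif (reference_length - len(s)) % 3 != 0:
            drop.append(a)
        elif "*" in catalog.translations[a]:
            drop.append(a)
    keep = [a for a in catalog.allele_ids if a not in set(drop)]
    filtered = catalog.subset(keep)
    if genotypes is None:
        return filtered, None
    present = [a for a in genotypes.allele_ids if a in set(drop)]
    if present:
        losing = genotypes.matrix[present].sum(axis=1)
        remaining = genotypes.matrix.sum(axis=1) - losing
        orphans = list(remaining[remaining == 0].index)
        if orphans:
            raise ValueError(
                f"coding filter would leave individuals without alleles: {orphans}"
            )
    return filtered, genotypes.drop_alleles(drop)


class Genotyper:
    """Cohort-level allele calling with a shared novel-allele registry."""

    def __init__(self, config: GenotypingConfig | None = None):
        self.config = config or GenotypingConfig()
        self.novel_registry: dict[str, str] = {}

    def genotype_individual(self, reads: Sequence[str]) -> list[tuple[str, str, float]]:
        clusters = denoise_reads(reads, self.config)
        return call_alleles(clusters, self.config, self.novel_registry)

    def genotype_cohort(
        self,
        reads_by_individual: Mapping[str, Sequence[str]],
        samples: pd.DataFrame,
    ) -> tuple[AlleleCatalog, GenotypeTable]:
        """Genotype every individual; returns the called catalog and table."""
        samples = validate_sample_table(samples)
        calls: dict[str, list[str]] = {}
        seqs: dict[str, str] = {}
        if self.config.reference is not None:
            ref = self.config.reference
        else:
            ref = None
        for ind, reads in reads_by_individual.items():
            called = self.genotype_individual(reads)
            calls[ind] = [aid for aid, _, _ in called]
            for aid, seq, _ in called:
                seqs[aid] = seq
        allele_ids = sorted(seqs)
        classical = {a: True for a in allele_ids}
        if ref is not None:
            for a in allele_ids:
                if a in ref.classical:
                    classical[a] = ref.classical[a]
        catalog = AlleleCatalog(
            alleles={a: seqs[a] for a in allele_ids},
            frame_offset=ref.frame_offset if ref is not None else 0,
            classical=classical,
        )
        matrix = pd.DataFrame(0, index=list(calls), columns=allele_ids)
        for ind, aids in calls.items():
            matrix.loc[ind, aids] = 1
        genotypes = GenotypeTable(matrix=matrix, samples=samples)
        return catalog, genotypes
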