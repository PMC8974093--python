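"""Synthetic allele pools, genotypes and error-bearing amplicon reads.

The generator emulates the statistical structure the analysis assumes: a
pool of ~150 unique, stop-free 47-codon exon-2 alleles derived from one
ancestral haplotype; 14 populations in six lakes x four habitat classes;
4-14 alleles per individual; per-amplicon read depths spanning roughly
1.7k-61k; Bernoulli per-base substitution / indel sequencing errors; and an
explicit co-ancestry versus convergence scenario for a focal population
pair, which fixes whether shared amino-acid states share a codon lineage
(modulo recorded synonymous changes) or carry independently drawn codons.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import AlleleCatalog, GenotypeTable, validate_sample_table

__all__ = [
    "SimulationConfig",
    "ScenarioTruth",
    "simulate_allele_pool",
    "simulate_populations",
    "simulate_reads",
    "write_reads_fastq",
    "synonymous_shuffle",
    "codon_resample",
]

_NT = "TCAG"
_ALL_CODONS = ["".join(c) for c in itertools.product(_NT, repeat=3)]
_AA_OF = {c: str(Seq(c).translate()) for c in _ALL_CODONS}
_SENSE = [c for c in _ALL_CODONS if _AA_OF[c] != "*"]
_SYN_OF = {c: [d for d in _SENSE if _AA_OF[d] == _AA_OF[c] and d != c] for c in _SENSE}
_CODONS_OF_AA: dict[str, list[str]] = {}
for _c in _SENSE:
    _CODONS_OF_AA.setdefault(_AA_OF[_c], []).append(_c)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the published survey scale."""

    n_alleles: int = 150
    fragment_codons: int = 47
    # per-allele substitution probability at a variable site; 0.165 puts the
    # mean pairwise nucleotide p-distance near the ~0.2 seen in the survey
    site_sub_prob: float = 0.165
    prop_variable_sites: float = 0.68  # fraction of nt sites allowed to vary
    n_populations: int = 14
    n_individuals_per_population: int = 20
    alleles_per_individual_mean: float = 7.5
    alleles_per_individual_range: tuple[int, int] = (4, 14)
    pool_size_range: tuple[int, int] = (22, 55)
    depth_mean: float = 14441.0
    depth_range: tuple[int, int] = (1713, 61269)
    depth_sigma: float = 0.6           # lognormal shape of per-amplicon depth
    read_proportion_concentration: float = 10.0  # Dirichlet around equal within-individual use
    min_true_paf: float = 0.0          # resample proportions until all alleles exceed this
    sub_error_rate: float = 0.005
    indel_error_rate: float = 1e-5
    scenario: str = "co_ancestry"      # 'co_ancestry' | 'convergence' | 'none'
    codon_locked_pool: bool = False    # one fixed codon per amino-acid state per position
    convergent_positions: tuple[int, ...] | None = None  # 1-based codons redrawn under convergence (None: all)
    p_syn: float = 0.1                 # per-codon synonymous-change prob. per lineage
    plant_stop_allele: bool = False
    plant_nonclassical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_sub_prob", "prop_variable_sites", "p_syn",
                     "sub_error_rate", "indel_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.scenario not in ("co_ancestry", "convergence", "none"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.depth_range[0] < 1:
            raise ValueError("read depth must be >= 1")
        if self.fragment_codons < 2:
            raise ValueError("fragment_codons must be >= 2")


@dataclass
class ScenarioTruth:
    """Ground truth of one simulated survey."""

    samples: pd.DataFrame                      # validated sample table
    pools: dict[str, list[str]]                # population -> allele ids
    pop_sequences: dict[str, dict[str, str]]   # population -> allele id -> nt sequence
    genotypes: GenotypeTable
    provenance: pd.DataFrame                   # (population, allele_id, codon, event)
    scenario_pair: tuple[str, str] | None
    config: SimulationConfig


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _random_sense_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE) for _ in range(n))


def _has_internal_stop(seq: str) -> bool:
    return "*" in str(Seq(seq[: len(seq) // 3 * 3]).translate())


def simulate_allele_pool(config: SimulationConfig) -> AlleleCatalog:
    """Draw a catalog of unique stop-free alleles around one ancestral sequence.

    Default mode: a fixed set of variable nucleotide sites is chosen once
    and each allele substitutes each variable site with probability
    ``site_sub_prob`` (drawn until stop-free and unique).

    ``codon_locked_pool`` mode works at the codon level: each variable codon
    position gets a fixed menu of amino-acid states, each encoded by one
    fixed codon, and alleles pick states from the menus.  In that mode two
    alleles sharing an amino acid at a position always share its codon --
    the ground-truth premise of the co-ancestry scenario, where codon
    differences at conserved residues must come only from recorded
    synonymous events.

    Optional planted artifacts for filter testing: a frameshifted allele
    (1-bp deletion) and a non-classical allele flagged by id.
    """
    rng = _rng(config, 0)
    L = 3 * config.fragment_codons
    if config.codon_locked_pool:
        n_var = max(1, int(round(config.prop_variable_sites * config.fragment_codons)))
        if config.n_alleles > 1 and 4 ** n_var < config.n_alleles:
            raise ValueError(
                f"cannot draw {config.n_alleles} unique alleles from {n_var} variable codons"
            )
        anc_codons = [str(c) for c in _random_sense_codons(config.fragment_codons, rng)]
        anc_codons = [anc_codons[i] + anc_codons[i + 1] + anc_codons[i + 2]
                      for i in range(0, L, 3)]
        var_codons = np.sort(rng.choice(config.fragment_codons, size=n_var, replace=False))
        # per variable codon: 1-3 alternative amino-acid states, each a fixed
        # single-nucleotide nonsynonymous neighbour of the ancestral codon
        menus: dict[int, list[str]] = {}
        for c in var_codons:
            anc = anc_codons[c]
            by_aa: dict[str, list[str]] = {}
            for pos in range(3):
                for nt in _NT:
                    if nt == anc[pos]:
                        continue
                    mut = anc[:pos] + nt + anc[pos + 1 :]
                    aa = _AA_OF[mut]
                    if aa != "*" and aa != _AA_OF[anc]:
                        by_aa.setdefault(aa, []).append(mut)
            alt_aas = sorted(by_aa)
            k_alt = min(int(rng.integers(1, 4)), len(alt_aas))
            chosen = rng.choice(alt_aas, size=k_alt, replace=False)
            menus[int(c)] = [anc] + [str(rng.choice(by_aa[aa])) for aa in chosen]
        alleles = {"ac001": "".join(anc_codons)}
        tries = 0
        while len(alleles) < config.n_alleles:
            tries += 1
            if tries > 1000 * config.n_alleles:
                raise ValueError(
                    "infeasible configuration: cannot generate unique stop-free alleles"
                )
            codons = list(anc_codons)
            for c, menu in menus.items():
                if rng.random() < config.site_sub_prob:
                    codons[c] = menu[int(rng.integers(1, len(menu)))]
            seq = "".join(codons)
            if seq in alleles.values():
                continue
            alleles[f"ac{len(alleles) + 1:03d}"] = seq
        return _finish_catalog(alleles, config, rng, L)

    n_var = int(round(config.prop_variable_sites * L))
    if config.n_alleles > 1 and 4 ** max(n_var, 1) < config.n_alleles:
        raise ValueError(
            f"cannot draw {config.n_alleles} unique alleles from {n_var} variable sites"
        )
    ancestral = _random_sense_codons(config.fragment_codons, rng)
    var_sites = np.sort(rng.choice(L, size=n_var, replace=False))
    alleles = {"ac001": ancestral}
    tries = 0
    while len(alleles) < config.n_alleles:
        tries += 1
        if tries > 1000 * config.n_alleles:
            raise ValueError("infeasible configuration: cannot generate unique stop-free alleles")
        chars = list(ancestral)
        for s in var_sites:
            if rng.random() < config.site_sub_prob:
                chars[s] = rng.choice([b for b in _NT if b != ancestral[s]])
        seq = "".join(chars)
        if _has_internal_stop(seq) or seq in alleles.values():
            continue
        alleles[f"ac{len(alleles) + 1:03d}"] = seq
    return _finish_catalog(alleles, config, rng, L)


def _finish_catalog(alleles: dict[str, str], config: SimulationConfig,
                    rng: np.random.Generator, L: int) -> AlleleCatalog:
    ancestral = alleles["ac001"]
    classical = {a: True for a in alleles}
    if config.plant_stop_allele:
        # 1-bp deletion induces a frameshift (and usually premature stops)
        alleles["art_frameshift"] = ancestral[: L // 2] + ancestral[L // 2 + 1 :]
        classical["art_frameshift"] = True
    if config.plant_nonclassical:
        # a divergent but coding sequence, excluded by id downstream
        while True:
            chars = list(ancestral)
            for s in rng.choice(L, size=max(3, L // 20), replace=False):
                chars[s] = rng.choice([b for b in _NT if b != ancestral[s]])
            seq = "".join(chars)
            if not _has_internal_stop(seq) and seq not in alleles.values():
                break
        alleles["nonclassical01"] = seq
        classical["nonclassical01"] = False
    return AlleleCatalog(alleles=alleles, frame_offset=0, classical=classical)


def synonymous_shuffle(seq: str, p_syn: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Replace each codon with a different synonymous codon with prob. ``p_syn``.

    Returns the new sequence and the 0-based codon indices that changed.
    Single-codon amino acids (Met, Trp) cannot change.
    """
    codons = [seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3)]
    changed = []
    for i, c in enumerate(codons):
        alts = _SYN_OF.get(c, [])
        if alts and rng.random() < p_syn:
            codons[i] = rng.choice(alts)
            changed.append(i)
    return "".join(codons), changed


def empirical_codon_usage(seqs, pseudocount: float = 0.0) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon frequencies observed in ``seqs`` (full length)."""
    counts: dict[str, dict[str, float]] = {
        aa: {c: pseudocount for c in codons} for aa, codons in _CODONS_OF_AA.items()
    }
    for s in seqs:
        for i in range(len(s) // 3):
            c = s[3 * i : 3 * i + 3]
            aa = _AA_OF.get(c)
            if aa and aa != "*":
                counts[aa][c] += 1.0
    usage = {}
    for aa, cc in counts.items():
        tot = sum(cc.values())
        if tot > 0:
            usage[aa] = {c: v / tot for c, v in cc.items()}
    return usage


def codon_resample(seq: str, usage: Mapping[str, Mapping[str, float]],
                   rng: np.random.Generator) -> tuple[str, list[int]]:
    """Re-draw every codon independently from the usage table of its amino acid.

    Preserves the amino-acid sequence exactly; models convergent evolution
    (identical residues with independent codon histories).
    """
    codons = [seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3)]
    changed = []
    for i, c in enumerate(codons):
        aa = _AA_OF[c]
        table = usage[aa]
        opts = list(table)
        probs = np.array([table[o] for o in opts])
        new = opts[rng.choice(len(opts), p=probs / probs.sum())]
        if new != c:
            changed.append(i)
        codons[i] = new
    return "".join(codons), changed


def _synthetic_design(config: SimulationConfig) -> pd.DataFrame:
    """Population design table: lakes and habitats cycled over populations."""
    lakes = [f"lake{l + 1:02d}" for l in range((config.n_populations + 2) // 3)][:6]
    habitats = ["shallow_benthic", "limnetic", "deep_benthic", "rocky"]
    rows = []
    for p in range(config.n_populations):
        lake = lakes[p % len(lakes)]
        habitat = habitats[(p // len(lakes)) % len(habitats)]
        lake_type = "tectonic" if (p % len(lakes)) < 2 else "crater"
        rows.append((f"pop{p + 1:02d}", lake, lake_type, habitat,
                     config.n_individuals_per_population))
    return pd.DataFrame(rows, columns=["population", "lake", "lake_type", "habitat", "n"])


def simulate_populations(catalog: AlleleCatalog, config: SimulationConfig) -> ScenarioTruth:
    """Assign allele pools and genotypes to populations, with scenario provenance.

    Pools are nested samples of the catalog (lake pool -> population pool) so
    that populations in a lake share more alleles.  Under ``co_ancestry`` the
    two focal populations (the first two sharing a habitat across lakes, or
    simply the first two) carry the same ancestral alleles with independent
    per-lineage synonymous changes (prob. ``p_syn`` per codon); under
    ``convergence`` the second population's codons are re-drawn from the
    catalog's empirical codon usage, keeping amino acids identical.
    """
    classical_ids = [a for a in catalog.allele_ids
                     if catalog.classical[a] and "*" not in catalog.translations[a]]
    design = _synthetic_design(config)
    rng = _rng(config, 1)

    # nested pools: a lake-level pool, population pools drawn inside it
    pools: dict[str, list[str]] = {}
    lake_pools: dict[str, list[str]] = {}
    lo, hi = config.pool_size_range
    for lake in design["lake"].unique():
        size = min(len(classical_ids), max(hi, lo) + 10)
        lake_pools[lake] = list(rng.choice(classical_ids, size=size, replace=False))
    for _, row in design.iterrows():
        size = min(int(rng.integers(lo, hi + 1)), len(lake_pools[row["lake"]]))
        pools[row["population"]] = list(
            rng.choice(lake_pools[row["lake"]], size=size, replace=False)
        )

    # scenario: focal pair = first two populations sharing a habitat across
    # lakes (fall back to the first two populations)
    scenario_pair: tuple[str, str] | None = None
    if config.scenario != "none" and len(design) >= 2:
        for h, grp in design.groupby("habitat", sort=False):
            if grp["lake"].nunique() >= 2:
                sub = grp.drop_duplicates("lake")
                scenario_pair = tuple(sub["population"].iloc[:2])
                break
        if scenario_pair is None:
            scenario_pair = tuple(design["population"].iloc[:2])

    pop_sequences: dict[str, dict[str, str]] = {
        pop: {a: catalog.alleles[a] for a in pool} for pop, pool in pools.items()
    }
    prov_rows: list[tuple[str, str, int, str]] = []
    if scenario_pair is not None:
        pa, pb = scenario_pair
        # the focal pair draws from one shared ancestral pool
        shared = sorted(pools[pa])
        pools[pb] = shared[:]
        if config.scenario == "co_ancestry":
            srng = _rng(config, 2)
            for pop in (pa, pb):
                seqs = {}
                for a in shared:
                    new, changed = synonymous_shuffle(catalog.alleles[a], config.p_syn, srng)
                    seqs[a] = new
                    prov_rows += [(pop, a, c, "synonymous") for c in changed]
                pop_sequences[pop] = seqs
        else:
            # convergence: both populations draw codons independently at the
            # convergent positions (all codons when unspecified); elsewhere
            # the lineages accumulate ordinary synonymous turnover
            usage = empirical_codon_usage(catalog.alleles.values())
            srng = _rng(config, 2)
            if config.convergent_positions is None:
                conv_pos = set(range(config.fragment_codons))
            else:
                conv_pos = {p - 1 for p in config.convergent_positions}
            for pop in (pa, pb):
                seqs = {}
                for a in shared:
                    redrawn, r_changed = codon_resample(catalog.alleles[a], usage, srng)
                    shuffled, s_changed = synonymous_shuffle(
                        catalog.alleles[a], config.p_syn, srng
                    )
                    codons = []
                    for i in range(config.fragment_codons):
                        src = redrawn if i in conv_pos else shuffled
                        codons.append(src[3 * i : 3 * i + 3])
                    seqs[a] = "".join(codons)
                    prov_rows += [(pop, a, c, "redrawn") for c in r_changed
                                  if c in conv_pos]
                    prov_rows += [(pop, a, c, "synonymous") for c in s_changed
                                  if c not in conv_pos]
                pop_sequences[pop] = seqs

    # genotypes: per-population allele frequencies, individuals draw without
    # replacement
    grng = _rng(config, 3)
    sample_rows = []
    geno_rows = []
    kmin, kmax = config.alleles_per_individual_range
    for _, row in design.iterrows():
        pop = row["population"]
        pool = pools[pop]
        freqs = grng.dirichlet(np.full(len(pool), 1.0))
        for i in range(int(row["n"])):
            ind = f"{pop}_i{i + 1:03d}"
            k = int(np.clip(grng.poisson(config.alleles_per_individual_mean),
                            kmin, min(kmax, len(pool))))
            chosen = grng.choice(pool, size=k, replace=False, p=freqs)
            sample_rows.append((ind, pop, row["lake"], row["lake_type"], row["habitat"]))
            geno_rows += [(ind, a) for a in chosen]
    samples = validate_sample_table(pd.DataFrame(
        sample_rows, columns=["individual_id", "population", "lake", "lake_type", "habitat"]
    ))
    long = pd.DataFrame(geno_rows, columns=["individual_id", "allele_id"])
    matrix = pd.crosstab(long["individual_id"], long["allele_id"]).clip(upper=1)
    matrix = matrix.loc[[r[0] for r in sample_rows]]
    matrix.index.name = None
    matrix.columns.name = None
    genotypes = GenotypeTable(matrix=matrix, samples=samples)
    provenance = pd.DataFrame(prov_rows, columns=["population", "allele_id", "codon", "event"])
    return ScenarioTruth(
        samples=samples, pools=pools, pop_sequences=pop_sequences,
        genotypes=genotypes, provenance=provenance,
        scenario_pair=scenario_pair, config=config,
    )


# ---------------------------------------------------------------------------
# reads


def _mutate_reads(seq: str, count: int, config: SimulationConfig,
                  rng: np.random.Generator) -> list[str]:
    if count == 0:
        return []
    arr = np.tile(np.frombuffer(seq.encode(), dtype="S1"), (count, 1)).copy()
    L = arr.shape[1]
    if config.sub_error_rate > 0:
        mask = rng.random((count, L)) < config.sub_error_rate
        n_mut = int(mask.sum())
        if n_mut:
            # substitute with one of the three other bases
            bases = np.frombuffer(b"ACGT", dtype="S1")
            orig = arr[mask]
            repl = bases[rng.integers(0, 4, size=n_mut)]
            clash = repl == orig
            while clash.any():
                repl[clash] = bases[rng.integers(0, 4, size=int(clash.sum()))]
                clash = repl == orig
            arr[mask] = repl
    reads = [r.tobytes().decode() for r in arr]
    if config.indel_error_rate > 0:
        n_events = rng.binomial(L, config.indel_error_rate, size=count)
        for i in np.nonzero(n_events)[0]:
            r = list(reads[i])
            for _ in range(int(n_events[i])):
                pos = int(rng.integers(0, len(r)))
                if rng.random() < 0.5 and len(r) > 1:
                    del r[pos]
                else:
                    r.insert(pos, str(rng.choice(list("ACGT"))))
            reads[i] = "".join(r)
    return reads


def simulate_reads(truth: ScenarioTruth, config: SimulationConfig | None = None,
                   ) -> dict[str, list[str]]:
    """Per-individual merged amplicon reads with sequencing errors.

    Depth per amplicon follows a clipped lognormal around ``depth_mean``;
    within an individual, reads split over its alleles with symmetric
    Dirichlet proportions around equality.  Returns individual -> list of
    read sequences (shuffled).
    """
    config = config or truth.config
    if truth.genotypes.matrix.shape[0] == 0:
        raise ValueError("no individuals in truth genotypes")
    rng = _rng(config, 4)
    mu = np.log(config.depth_mean) - 0.5 * config.depth_sigma**2
    pop_of = dict(zip(truth.samples["individual_id"], truth.samples["population"]))
    reads: dict[str, list[str]] = {}
    for ind in truth.genotypes.individuals:
        alleles = truth.genotypes.alleles_of(ind)
        depth = int(np.clip(rng.lognormal(mu, config.depth_sigma),
                            config.depth_range[0], config.depth_range[1]))
        if depth < 1:
            raise ValueError("zero read depth")
        props = rng.dirichlet(np.full(len(alleles),
                                      config.read_proportion_concentration))
        if config.min_true_paf > 0:
            for _ in range(1000):
                if props.min() >= config.min_true_paf:
                    break
                props = rng.dirichlet(np.full(len(alleles),
                                              config.read_proportion_concentration))
            else:
                props = np.clip(props, config.min_true_paf, None)
                props = props / props.sum()
        counts = rng.multinomial(depth, props)
        seqs = truth.pop_sequences[pop_of[ind]]
        ind_reads: list[str] = []
        for a, c in zip(alleles, counts):
            ind_reads += _mutate_reads(seqs[a], int(c), config, rng)
        order = rng.permutation(len(ind_reads))
        reads[ind] = [ind_reads[i] for i in order]
    return reads


def write_reads_fastq(reads: Mapping[str, list[str]], out_dir: str | Path,
                      quality_char: str = "?") -> list[Path]:
    """One FASTQ (Phred+33, constant Q30 by default) per individual."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ind, seqs in reads.items():
        path = out_dir / f"{ind}.fastq"
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@{ind}_r{i + 1}\n{s}\n+\n{quality_char * len(s)}\n")
        paths.append(path)
    return paths
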