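"""Simulate a survey-scale data set: 150-allele pool, 14 populations in six
lakes, per-individual genotypes, and error-bearing amplicon reads for two
populations (kept small so the driver stays quick).

Writes results/simulated/: allele catalog FASTA, sample metadata and true
genotype table; the per-individual FASTQ files (large) go to scratch/reads.
"""

from pathlib import Path

from midas_mhc.io import write_allele_fasta, write_genotypes
from midas_mhc.synthdata import (
    SimulationConfig,
    simulate_allele_pool,
    simulate_populations,
    simulate_reads,
    write_reads_fastq,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
READS_OUT = Path(__file__).resolve().parents[1] / "scratch" / "reads"
SEED = 20260926

config = SimulationConfig(n_alleles=150, scenario="none", depth_mean=1500,
                          depth_range=(800, 4000), sub_error_rate=0.002,
                          seed=SEED)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = simulate_allele_pool(config)
    truth = simulate_populations(catalog, config)
    write_allele_fasta(catalog, OUT / "alleles.fasta")
    write_genotypes(truth.genotypes, OUT / "true_genotypes.csv", OUT / "metadata.csv")

    pops = sorted(truth.pools)[:2]
    subset = truth.samples[truth.samples["population"].isin(pops)]
    sub_truth = type(truth)(
        samples=subset,
        pools=truth.pools,
        pop_sequences=truth.pop_sequences,
        genotypes=truth.genotypes.subset_individuals(subset["individual_id"]),
        provenance=truth.provenance,
        scenario_pair=truth.scenario_pair,
        config=config,
    )
    reads = simulate_reads(sub_truth, config)
    paths = write_reads_fastq(reads, READS_OUT)
    n_reads = sum(len(r) for r in reads.values())
    print(f"simulated {len(catalog)} alleles, "
          f"{truth.genotypes.matrix.shape[0]} individuals in "
          f"{truth.samples['population'].nunique()} populations")
    print(f"mean alleles/individual: "
          f"{truth.genotypes.matrix.sum(axis=1).mean():.2f}")
    print(f"wrote {len(paths)} FASTQ files ({n_reads} reads) for populations {pops}")


if __name__ == "__main__":
    main()
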