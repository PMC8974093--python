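# midas-mhc

Amplicon immunogenetics of the Midas cichlid (*Amphilophus* spp.) radiation:
a tested, reusable pipeline for MHC class IIB exon-2 diversity and
population-divergence analyses, together with a seeded synthetic-data
generator that emulates the survey's structure end to end.

The Nicaraguan great lakes and their young crater lakes hold repeated,
partly sympatric radiations of Midas cichlids whose benthic, limnetic and
rocky-shore ecomorphs face different parasite communities. The major
histocompatibility complex class IIB genes — whose exon 2 encodes most of
the antigen-binding groove — are a natural place to look for habitat-driven
divergent selection. This package implements the analysis chain such a
survey needs, for population geneticists and immunogeneticists working from
merged amplicon reads or pre-called genotype tables:

1. **Allele calling** (`midas_mhc.genotyping`) — per-amplicon dereplication,
   absorption of error variants under a binomial error model, a per-amplicon
   frequency (PAF) threshold (default 1.5%), a cap of 50 alleles per
   individual, exact reference matching and `ac###` naming of novel alleles,
   and coding filters (non-classical alleles and frameshifts out, in-frame
   deletions kept).
2. **Sequence diversity** (`midas_mhc.diversity`) — mean pairwise nucleotide
   p-distance (π), amino-acid p-distance, and dN/dS by the Nei–Gojobori
   method with Jukes–Cantor correction, d = −(3/4)·ln(1 − 4p/3); bootstrap
   SEs over sites; the gene-wide codon Z-test
   Z = (dN − dS)/SE(dN − dS) with the SE bootstrapped over codons; and the
   same indices per individual over its own allele set.
3. **Positively selected sites** (`midas_mhc.selection`,
   `midas_mhc.published`) — site lists from external codon-model scans
   (CodeML, MEME/BUSTED, MrBayes) combined by a ≥2-method consensus, and
   reduction of alleles to their PSS residues.
4. **Supertypes** (`midas_mhc.supertyping`) — PSS-reduced sequences encoded
   with the five Sandberg z-descriptors per residue, K-means over principal
   components with a BIC "goodfit" choice of K, DAPC-style discriminant
   assignment with cross-validated PC count, and a consensus over 5 × 10
   seeded runs.
5. **Co-ancestry vs convergence** (`midas_mhc.convergence`) — for population
   pairs sharing a habitat, the proportion of identical amino acids at PSS
   that are encoded by the *same* codon, tested against Monte-Carlo nulls
   for convergent evolution (identity Σfᵢ² from codon usage) and co-ancestry
   (identity (1 − p_syn) + p_syn·Σfᵢ², with p_syn estimated from
   amino-acid-conserved non-PSS sites).
6. **Population divergence** (`midas_mhc.divergence`) — quasi-Poisson and
   linear models of per-individual diversity with Tukey post-hocs; a
   multivariate allele-pool test (sum of per-allele binomial-GLM deviances,
   permutation p-values, Westfall–Young step-down per-allele contributions,
   Benjamini–Hochberg pairwise comparisons); and nonmetric MDS of
   individuals on Jaccard dissimilarities.
7. **Synthetic data** (`midas_mhc.synthdata`) — seeded generation of allele
   pools (~150 alleles of 47 codons), 14 populations in six lakes × four
   habitat classes, 4–14 alleles per individual, lognormal read depths with
   substitution/indel errors, and explicit co-ancestry / convergence
   scenarios with codon-level ground truth.

## Worked example

The `analysis/` drivers run the whole chain on a simulated survey
(150 alleles, 14 populations, 280 individuals). After
`python analysis/01_simulate_survey.py` and
`python analysis/02_call_genotypes.py`:

```
simulated 150 alleles, 280 individuals in 14 populations
mean alleles/individual: 7.77
exact-genotype recovery: 40/40 (100.0%)
```

i.e. the PAF genotyper recovers every simulated genotype exactly from reads
carrying a 0.2% per-base error rate. `python analysis/04_selection_supertypes.py`
combines the published selection scans and clusters the simulated pool:

```
consensus PSS (>=2 of 3 methods): [1, 3, 12, 13, 22, 28, 35, 36, 42, 44, 45, 46]
supported by all methods: [1, 3, 13, 22, 35, 42, 45, 46]
```

— twelve consensus antigen-binding positions, eight unanimous, exactly the
arithmetic of the published per-method site lists.
`python analysis/05_convergence_test.py` generates population pairs under
both evolutionary scenarios and runs the codon-usage test:

```
generating scenario: co_ancestry (50 simulations)
  observed identity: 82.3% (ancestry null 81.4%, convergence null 43.6%)
  convergence rejected at 0.05: 1.00
  correct scenario preferred:   1.00
generating scenario: convergence (50 simulations)
  observed identity: 50.1% (ancestry null 82.0%, convergence null 47.2%)
  ancestry rejected at 0.05:    1.00
  correct scenario preferred:   1.00
```

Shared ancestry leaves shared codons behind identical amino acids (~82%
identity, matching its null); convergent evolution drops codon identity to
the codon-usage expectation (~50%), and the test tells the scenarios apart
in every simulation here.

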