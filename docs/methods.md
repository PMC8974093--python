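# Methods

This note records the models, conventions and numerical choices behind
`midas_mhc`, and what the synthetic-data tests do and do not establish.

## Data model

The unit of analysis is a 142-bp fragment of MHC class IIB exon 2:
47 codons plus one trailing base, which is ignored at translation
(`frame_offset = 0`; the loader verifies that this frame translates every
classical allele without internal stops and errors otherwise, so a wrong
frame cannot pass silently). Alleles are unique nucleotide variants of this
fragment; one known allele carries a 3-bp in-frame deletion and is
represented with a gap codon in aligned form (translated as `-` at that
position). Individuals carry 4–14 alleles (multi-locus amplicon without
locus assignment), stored as a binary individuals × alleles matrix joined
to a population / lake / habitat design table.

## Allele calling

Published amplicon-genotyping tools leave their error-clustering heuristics
partly unspecified; this package implements a fully specified simplified
rule so results are reproducible from the code alone. Reads of one
amplicon are dereplicated exactly; a variant `v` is absorbed into a more
abundant parent `p` at edit distance `d` (edlib, Needleman–Wunsch) when

    count(v) <= count(p) * P(X >= d),  X ~ Binomial(L, e_sub + e_indel),

i.e. when its abundance is compatible with sequencing error off the parent.
Surviving clusters are thresholded at a per-amplicon frequency (PAF) of
1.5% by default and capped at 50 alleles per individual — the two decisive
published parameters — with PAF ties at the cap broken lexicographically so
output never depends on read order. Called sequences are matched to a
reference catalog by exact identity; novel sequences get consecutive
`ac###` identifiers shared across a cohort. Coding filters then remove
alleles on the non-classical exclusion list (the discriminating-primer
logic that identifies non-classical loci is upstream of this artifact, so
identification is by ID), alleles whose ungapped length differs from the
full fragment by a non-multiple of 3, and alleles translating with internal
stops; in-frame deletions are kept. Error modes: an individual losing all
alleles to the filters, or no cluster reaching the PAF threshold, is an
error naming the individual, never silent.

The error-absorption rule is deliberately conservative with realistic
depths (≥~600 reads) and error rates (≤1%); with error-free reads it
reduces to exact dereplication, which is what the recovery property tests.

## Distances and the codon Z-test

p-distances are mean pairwise mismatch proportions over comparable sites;
deletion handling is pairwise by default, with complete and partial
(≥95% site coverage) modes available. Standard errors bootstrap alignment
sites (default 9999 replicates, seeded). A gamma-corrected form
d = a((1−p)^(−1/a) − 1) (a = 0.39 available) is provided, but the defaults
are plain p-distances: applying a rate-heterogeneity correction to a
p-distance mixes conventions, and the published point values are matched by
the plain form.

Nei–Gojobori counts use the classic conventions: each codon contributes
3 sites split by the fraction of the three possible changes per position
that are synonymous, with changes to stop codons counted as nonsynonymous
(so s + n = 3 exactly); differences between codons average synonymous /
nonsynonymous steps over all minimal substitution paths with equal weight,
excluding paths through stop codons (falling back to all paths when every
path is blocked). Per pair, S and N are averaged between the two sequences,
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected
(d = −(3/4)ln(1 − 4p/3); p ≥ 3/4 is an error naming the pair), and the
reported dN, dS are means over all pairs. A 64 × 64 lookup table built once
by path enumeration makes this exact and fast; a brute-force enumeration
oracle in the test suite verifies the table on random codon pairs.

The codon Z-test uses Z = (dN − dS)/SE(dN − dS) with the SE from a
bootstrap over codon sites (not nucleotide sites — the codon is the
resampling unit because S/N site counts are codon-level quantities), one
tailed for dN > dS via the normal approximation, under partial deletion.
A bootstrap with zero variance is an error unless dN = dS exactly (an
alignment with no differences), where Z = 0 by definition.

Per-individual indices (π, aa p-dist, dN, dS over the individual's own
alleles) are computed from catalog-wide pairwise matrices calculated once.
Individuals with a single allele get missing values, not zeros — a distance
needs a pair, and coding it 0 would bias group means downward.

## PSS consensus and supertypes

Site-level selection scans are consumed, not fitted: per-method site lists
(CodeML M2a/M8, MEME shared with the unconstrained BUSTED fit, MrBayes
Ny98) are combined by counting, keeping positions flagged by at least two
methods (codon 41, which carries the deletion, can be excluded before
counting). For the published lists this yields 12 positions, 8 unanimous.

Alleles reduced to their PSS residues are encoded with the five Sandberg
(1998) z-scales per residue (lipophilicity, steric bulk/polarisability,
polarity, two electronic-property scales); gap residues are imputed with
the column mean (neutral imputation) with a warning. One clustering run:
center/scale, PCA, K-means (10 inits) for K in 2..20 on the PCs carrying
99.9% of variance, with

    BIC(K) = n·d·ln(WSS/(n·d)) + K·d·ln(n)

(WSS = within-cluster sum of squares, d = retained PCs; lower is better)
and K chosen by the "goodfit" elbow rule — the smallest K achieving ≥90% of
the maximal BIC improvement over K = 1; the published source does not print
its rule, so this formalisation is our convention. A discriminant step
(LDA) is trained on the K-means labels with its retained-PC count chosen by
held-out assignment success over stratified 90/10 splits, and its
assignments are the run's labels. The consensus over 5 × 10 seeded runs
builds the co-assignment matrix, clusters 1 − co-assignment by average
linkage, and cuts at the modal K across runs (smallest mode on ties, with a
warning); per-allele support is the mean co-assignment with the final
co-members. The consensus is invariant to cluster relabelling within runs
by construction, which a test verifies.

## Co-ancestry versus convergence

For a population pair, every (allele of A, allele of B, PSS position)
triple with identical amino acids is an *event*; the statistic is the
proportion of events with identical codons. Nulls, 1000 Monte-Carlo
replicates each:

* **Convergence**: both codons drawn independently per event from the
  pooled per-amino-acid codon usage of the full sequences of both
  populations (pseudo-count 0.5 per codon avoids zero frequencies);
  expected identity per event Σfᵢ².
* **Co-ancestry**: an event stays identical unless a synonymous change hit
  the pair's joint history; identity probability
  (1 − p_syn) + p_syn·Σfᵢ².

The co-ancestry null is the package's main interpretive choice — the
original scripts are not published — and p_syn is estimated from the same
pair's amino-acid-conserved non-PSS sites by method of moments: the
observed codon-difference fraction d satisfies d = p_syn(1 − Σfᵢ²) under
the model, so p_syn = d/(1 − Σfᵢ²) (event-weighted Σfᵢ²). Estimating
p_syn as the raw d instead biases the null mean upward by ~p_syn·Σfᵢ² and
demonstrably miscalibrates the test, so the consistent estimator is used.
Significance per scenario: an exact two-sided binomial test of the observed
count against the null's mean proportion, plus the two-sided Monte-Carlo
empirical p (bounded in [1/(R+1), 1]). The "preferred scenario" is the one
with the larger empirical p.

Two caveats the simulations make explicit. First, events are not
independent when pools overlap (one lineage's synonymous change feeds every
pair containing that allele), so with many-allele pools the proportion
tests are anti-conservative; the calibration study therefore uses
single-allele pools, where events are exactly independent, and the
scenario-preference study uses 3-allele pools. Second, a convergence
scenario in which *every* codon is redrawn makes the data-estimated
ancestry null collapse onto the convergence null (p_syn saturates), so the
generator redraws codons only at designated convergent positions (the PSS
in all property studies) and applies ordinary synonymous turnover
elsewhere — matching the biological claim under test, convergence at the
antigen-binding sites against an ancestral background.

## Divergence statistics

Counts of alleles and supertypes per individual are over-dispersed, so the
count models are Poisson GLMs with a quasi-likelihood dispersion (Pearson
χ²/df of the full model) and sequential scaled-deviance χ² tests;
continuous indices use OLS with sequential (type-I) F tests; Tukey HSD
supplies pairwise contrasts. Factors with a single level are errors.

The multivariate pool test fits one binomial GLM per allele (batched IRLS
with a 1e-9 ridge; closed-form cell means when the design is a single
factor or a complete crossing) and sums per-allele deviance drops for each
sequential term — an additive likelihood-ratio statistic that is zero when
group presence patterns are identical. P-values come from 999 permutations
of individuals' presence profiles: free permutation for the first term,
permutation within the levels of the first reduced-model factor for later
terms. This is an approximation to resampling residual structure under the
reduced model; the proprietary resampling of the original multivariate
package is not reimplemented. 999 resamples put the smallest attainable
p at 0.001. Per-allele contributions get Westfall–Young step-down maxT
adjusted p-values from the same permutations; pairwise group tests are
Benjamini–Hochberg corrected. Alleles present in all or no individuals are
dropped with a warning (they carry no deviance).

NMDS uses Jaccard dissimilarities on presence/absence and nonmetric stress
(Kruskal stress-1) minimisation over ≥30 random starts (scikit-learn MDS,
metric=False), 1000 iterations maximum, returning the best start with
centred coordinates; 6 dimensions for all-lake analyses and 4–5 within
single lakes are the defaults.

## Synthetic data

The generator emulates the survey's stated conditions: ~150 unique
stop-free alleles of 47 codons derived from one ancestral sequence (default
per-variable-site substitution probability 0.165, chosen so mean pairwise π
lands near the observed ~0.20; ~68% of sites variable, matching 97/142);
14 populations in six lakes × four habitat classes with nested lake →
population allele pools (22–55 alleles each); 4–14 alleles per individual
(clipped Poisson, mean 7.5); lognormal per-amplicon depths (mean 14,441,
clipped to 1,713–61,269); within-individual allele read proportions from a
symmetric Dirichlet (concentration 10) around equality; and Bernoulli
per-base substitution (default 0.005) and indel (10⁻⁵) errors with constant
Q30 qualities — the survey reports no quantitative error model, so these
defaults are conventions, not measurements. Chimeras are not modelled.
A `codon_locked_pool` mode builds alleles from per-position menus of
single-nucleotide nonsynonymous neighbours (one fixed codon per amino-acid
state), which (a) guarantees the co-ancestry ground truth that shared
residues share a codon lineage up to recorded synonymous events, and
(b) yields pure nonsynonymous between-allele divergence for
positive-selection power tests. All outputs are bit-reproducible from one
integer seed.

What passing synthetic tests do *not* show: real amplicon data carry PCR
chimeras, index hopping, depth-dependent error profiles and locus-specific
amplification bias that the generator omits; the genotyper's published
thresholds are validated here only against the generator's error model.
The sequence-level published values (97/142 variable sites, 146 unique
translations, π = 0.20, dN = 0.24, dS = 0.21, Z = 0.8, 115 PSS-reduced
sequences, 13 supertypes) are checked by tests that require the deposited
allele alignment at `data/study_alleles.fasta`; those tests fail with
download instructions when the file is absent, since the sequences are
archived externally and not redistributed here.

## Problem sizes used by the test and acceptance runs

Recovery: 500 simulated individuals, 30-allele catalog, depth 600–2000,
true PAFs ≥3%. Oracle comparison: 1000 random ≤3-codon pairs. Convergence
calibration: 500 co-ancestry pairs (type-I), 150 pairs per scenario
(preference), 1000 MC replicates each. Multivariate: 200 null and 100
planted-shift data sets (2 × 40 individuals, 25 alleles), 199 permutations.
Z-test bootstraps: 9999 replicates on real data, 500–2000 in simulation
checks. These sizes were chosen to keep each study's Monte-Carlo error
well inside the asserted margins.
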