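# Methods

## The simulator

### Model and time scale

Genealogies are drawn from the n-deme structured coalescent with migration,
parameterised as coalescent gene-flow software reports it: per-deme
Θ_i = 4N_i μ per locus and a matrix M of mutation-scaled migration rates
m/μ, rows indexing the receiving deme. Time is measured in mutational units
(one unit = 1/μ generations at the per-locus mutation rate), which fixes the
three event rates consistently:

* coalescence of any pair within deme i at rate 2/Θ_i (k lineages:
  k(k−1)/Θ_i);
* backward migration of a lineage currently in deme i to source deme j at
  rate M[i][j] — the mutation-scaled immigration rate into i from j, which is
  the correct backward rate under the row = receiving convention;
* mutations on a branch as Poisson(branch length × 1).

Under this scale E[T₂] = Θ/2 for two lineages in one deme, and
E[S] = Θ·a₁ for n lineages (a₁ = Σ_{i<n} 1/i), which the test suite verifies
by Monte Carlo, against closed forms, and against msprime as an independent
coalescent implementation. Mutations follow infinite sites inside a
fixed-length locus (90 bp by default); positional collisions are re-drawn,
a negligible correction at Θ_site ≈ 6×10⁻⁴. Diploids are formed by random
within-deme pairing of haplotypes (no inbreeding model); missingness is
i.i.d. Bernoulli per cell, emulating RAD dropout without modelling its
restriction-site bias.

### Exact two-lineage expectations

`expected_pair_times` solves the absorbing Markov chain of two lineages over
deme-pair configurations exactly. Two consequences are used throughout:

* **Within-deme diversity.** E[π per locus] = 2·E[T_w]. With d connected
  demes the species genealogy is deeper than any single deme's
  (for a symmetric island model E[T_w] is d times the panmictic value), so
  the per-deme coalescent parameter consistent with an *observed*
  within-population diversity of 0.0006/site is roughly three times smaller
  than 0.0006×90 per locus in the three-colony default. The default model is
  calibrated by exact time rescaling (Θ → cΘ, M → M/c), which scales all
  coalescence times by c and leaves every F_ST invariant.
* **F_ST expectation.** The ratio-of-sums Weir–Cockerham estimator over many
  loci converges to (T_b − T_w)/T_b computed from the chain (for a symmetric
  2-deme model, 1/(1 + 2ΘM)). Note this is *not* the textbook island-model
  identity F_ST = 1/(1 + 4Nm·(d/(d−1))²): that expression describes
  identity-by-descent relative to the whole d-deme universe including
  self-deme weighting, and the two differ by about a factor of two in the
  denominator at d = 2. The island-model recovery test therefore checks the
  estimator against the exact coalescence-time form, which the simulator
  reproduces within Monte-Carlo error.

### Default three-colony model

Demes Tern (17 diploids), Midway (11) and Torishima (19); 90-bp loci;
within-population diversity calibrated to 0.0006/site. Migration rates were
chosen against the exact chain so expected pairwise Weir–Cockerham F_ST is
≈0.006 between the two Hawaiian demes and ≈0.045 between Japan and either
Hawaiian deme, with fully symmetric mutation-scaled rates. The within-Hawaii
value is deliberately *below* the resolution of a 99-permutation null at
these sample sizes: the observed non-significance of the within-Hawaii
comparison implies its true differentiation is at null level, and a
point-estimate of ~0.02 from real data of this size is dominated by sampling
noise of the estimator, not by a population parameter.

### What the generator does not emulate

* **No intra-locus recombination** (deliberate): two SNPs on one locus share
  a single genealogy, so within-locus r² is elevated over the unlinked
  baseline but carries *no distance trend*. The r²-vs-distance decay seen in
  real RAD data requires historical recombination; passing LD tests here
  demonstrate the estimator and the smoother, not the decay's biological
  origin.
* No sequencing error, no restriction-site allele dropout bias (missingness
  is i.i.d.), no selection. Passing tests therefore show estimator
  correctness under a clean neutral model, not robustness to those artefacts.

Morphometric tables are drawn from a (population × sex) cell-means normal
model. Default cell means come from the published grand means and location /
sex contrasts (tarsus −11.9 mm Hawaii−Japan on a 98.5 mm grand mean, culmen
+3.2, bill width −0.8, wing chord +9.1; sex contrasts 3.2 and 1.3 mm for
culmen and bill width); residual SDs (19.5 / 8.5 / 3.0 / 1.3 mm for wing,
tarsus, culmen, width) were back-computed from the published F statistics at
the published cell sizes, so simulated power matches the study's. Per-trait
cell sizes reproduce the unequal usable sample sizes (32–34) caused by
museum preparation.

## Estimator conventions

* **Missing data** is a single sentinel (−1). All allele-frequency-based
  statistics are pairwise-complete (frequencies from non-missing chromosomes
  per SNP); nothing is listwise-deleted except per-trait rows in the ANOVA.
* **Polarity.** Reference/alternate labelling is arbitrary; every statistic
  is tested for invariance under allele relabelling.
* **Filtering order** is subsample → completeness → heterozygosity/MAF →
  one-SNP-per-locus. MAF is pooled over retained individuals; the
  heterozygosity filter uses observed heterozygosity; thresholds are strict
  inequalities (MAF > 0.05, het < 0.75); one-SNP-per-locus keeps the lowest
  offset (deterministic, matching the usual first-SNP writer behaviour).
  Which individuals the original study drew for its subsampled data sets is
  unknowable, so subsampling is seeded-uniform only.
* **Watterson's n.** With ragged per-SNP call rates, a₁ uses the median
  non-missing chromosome count across SNPs.
* **W-C F_ST**: the 1984 θ̂ with heterozygote terms, ratio-of-sums
  combination, negative per-SNP values retained. Permutation p-values use
  (1+x)/(1+N) so p is never 0. The default permutation pool is *all*
  individuals (the published procedure: pairwise nulls draw both group sizes
  from the pooled sample, so third-population structure widens the null and
  the test is conservative for weakly differentiated pairs); the classical
  pair-only exchangeability null, centred at zero, is available as
  `pool="pair"`.
* **Ordination**: missing genotypes imputed to the per-SNP mean, columns
  centred but not variance-scaled (0/1/2 coding), PCA by SVD, then
  discriminant axes from the generalised eigenproblem S_b v = λ S_w v on the
  retained PC scores; eigenvalues are between/within ratios. A tiny ridge
  (10⁻¹⁰) on S_w guards perfectly separated groups.
* **Assignment**: Hardy–Weinberg genotype likelihoods with leave-one-out
  allele frequencies for the individual's own population and frequencies
  floored at 1/(2n+1); replicates bootstrap individuals within populations.
* **Two-locus EM**: the likelihood in D can be bimodal and the
  linkage-equilibrium point is an unstable fixed point, so EM runs from
  coupling-leaning, neutral and repulsion-leaning starts; because EM
  preserves the one-locus margins, the two boundary points of the admissible
  D interval are also evaluated directly (EM approaches a boundary MLE only
  sublinearly) and the highest-likelihood solution wins. A composite
  (genotypic-correlation) r² that needs no phase model is provided as an
  option. LOESS span defaults to 0.75 (unstated in the motivating analysis;
  configurable), with pointwise SE from the weighted local fit.
* **Nm conventions.** "literal" (Θ×M = 4Nm) is the default because the
  published 0.02–4.5 birds-per-generation range is only consistent with the
  plain product; the diploid Θ×M/4 variant is always printed alongside.
  Directional cross-data-set averages pool the two Hawaiian demes and use
  nonsymmetric-model entries only.
* **ANOVA**: Type II sums of squares (each main effect adjusted for the
  other, interaction against the full-model residual), the convention of the
  R ecosystem the original analysis used and the sensible default for
  unbalanced museum data. Location sign is mean(Hawaii) − mean(Japan). An
  all-equal response is reported as degenerate (F = 0) rather than 0/0.
* **Kinship**: KING-robust (between-family) estimator, chosen because it
  stays unbiased under exactly the population structure the pipeline
  measures; pairs sharing <100 SNPs are flagged low-confidence. At a few
  hundred shared SNPs the estimator's sampling noise spans the 2nd-degree
  cut-off, so screening real data should use the full SNP matrix, not a
  thinned one.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one global seed via `numpy.random.SeedSequence` in a
fixed stage order, so runs are byte-identical and stages independently
reproducible. The manifest records the package version, all seeds and every
convention listed above.

## Problem sizes

The test suite and acceptance script run simulations sized for a laptop
core: 2,500-locus three-colony data sets (~700 SNPs, versus 9,760 loci /
3,455 SNPs in the motivating study), 5,000 single-deme loci for
diversity-recovery checks, 2,500 island-model loci for the F_ST expectation,
10⁴ replicates for waiting-time moments. These sizes put Monte-Carlo error
comfortably inside the stated tolerances (10–20% for stochastic recoveries)
while keeping the full suite under a few minutes.

## Known limitations

* The simulator is a forward stand-in for Bayesian structured-coalescent
  inference, not a re-implementation of it; no priors or MCMC diagnostics
  exist here.
* Between-locus LD is out of scope (RAD loci are unanchored).
* N_e from θ inherits the downward bias of RAD diversity estimates
  (allele dropout at restriction sites), which is documented but not
  corrected.
* Which F_ST variant other software stacks print (hierfstat vs Stacks
  flavours) differs in detail; exactly one estimator (W-C 1984 θ̂) is
  implemented and labelled.
* π "over polymorphic loci only" averages per SNP, not per polymorphic
  locus; with multi-SNP loci the two differ slightly.
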