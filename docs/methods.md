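# Methods

This note documents the statistical models, the defaults, and the numerical
conventions the package implements, including the design choices made where
more than one reasonable convention exists.

## Study design the package assumes

Conspecific bees netted at one site form a putative subpopulation; females
are workers (or queens) from colonies headed by a single queen mated to a
single drone (monogyny/monoandry), so sampled females within a colony are
full sisters with relatedness 3/4. Males arise either from unfertilized
eggs (haploid) or, under single-locus complementary sex determination
(csd), from fertilized eggs homozygous at the csd locus (sterile diploid
males) — which is why diploid-male frequency is an inbreeding signal.

## Synthetic-data generator

The generator produces `GenotypeDataset`s with a parallel `SimTruth` so
every downstream stage can be validated against known ground truth.

* **Site differentiation by drift.** Base allele frequencies per locus are
  Dirichlet(concentration, default 1.0). Each site drifts independently for
  `t` generations of multinomial resampling of `2·Ne` gene copies with
  `Ne = 1000` fixed, `t` solved from the requested F_ST via the expected
  fixation index `1 − (1 − 1/(2Ne))^t` (t rounds to the nearest integer
  generation; target 0 means no drift and bitwise-identical site vectors).
  Drift, rather than an island-model migration rate, is used because it is
  the mechanism of the classical power-simulation design, and the same
  routine backs `power_sim`. The realized F_ST reported with the
  frequencies is the ratio of the summed among-site variance of allele
  frequencies to the summed `p̄(1−p̄)`, computed from the generated vectors.
* **Colonies.** Queen = two gene copies per locus from the site
  frequencies, drone = one; each sampled worker receives the drone allele
  plus one uniformly chosen queen allele per locus. Workers per colony are
  zero-truncated Poisson (mean parameter 1.5 by default; a mean parameter
  of 0 degenerates to exactly one worker, which models post-dedup data).
  The csd locus (default 10 equifrequent alleles) is transmitted the same
  way; a sampled male is a fertilized diploid male with probability equal
  to the csd-homozygosity probability given his parents, otherwise a
  haploid son of the queen.
* **Observation model.** Independently per allele copy: mistyping with
  probability ε replaces the copy with a frequency-weighted draw from its
  site's pool (class-I error; allelic dropout is not separately modeled
  because downstream stages assume a single error rate); a hidden null
  allele per locus at configured frequency makes null homozygotes read as
  missing and null heterozygotes as visible-allele homozygotes (the
  standard single-null model); finally whole-locus failure blanks the call.
  All noise rates default to 0 — noise is an explicit scenario choice, and
  the conventional 5% error figure enters as the *assumed* error rate of
  the sibship model rather than as a data-generation baseline.
* **Body size.** Width = per-(species, site) mean (default 4.5 mm) +
  colony effect (Normal, sd 0.25 mm, shared by sisters) + residual
  (Normal, sd 0.35 mm), truncated at zero. Site means are configuration,
  not constants, so clines of any size and direction can be planted.
* **Determinism.** All stage RNGs are spawned from `SimConfig.seed` via
  named `SeedSequence` substreams; a run is bit-reproducible.

What the generator does **not** emulate: spatial foraging structure,
polyandry/polygyny, temporal colony demography, locus-specific error
profiles, and any mechanistic link from the inbreeding coefficient to csd
homozygosity (queen–drone csd matching is random given the site
frequencies). Passing recovery tests on this generator therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every failure mode of real microsatellite data.

## Quality control

Order: per-species missingness filter (loci with ≥ 20% missing calls
first, then individuals with ≥ 20% missing over the retained loci — loci
first because individual failure rates depend on the panel) → null-allele
screen → sibship inference → one-sister-per-colony dedup → LD pruning →
HWE report. Thresholds are inclusive at the printed boundaries (exactly
20%, exactly 0.25 ⇒ dropped).

* **Null alleles.** The heterozygote-deficit estimator
  r = (He − Ho)/(He + Ho) with Nei's unbiased He; negative values
  (heterozygote excess) are reported as computed. Strata are species pooled
  across sites by default (per-site estimation is available by passing a
  stratum), since pooling is the conservative choice when site structure is
  weak.
* **HWE.** Monte-Carlo exact test: the statistic is the Levene conditional
  probability of the genotype array given the allele counts; the null is
  random re-pairing of the observed allele copies; the p-value carries the
  +1 correction and never returns 0. Monomorphic loci return 1. The exact
  conditional test is discrete, hence mildly conservative for few alleles
  or small samples; calibration approaches the nominal level as allele
  counts spread.
* **LD.** Permutation G-test on the joint genotype table of each locus
  pair (one locus's genotypes shuffled across individuals); pairs with
  fewer than five jointly typed individuals are recorded untested.
  Connected components of significantly linked pairs (raw p < 0.05, no
  multiplicity correction, matching the conventional screen) collapse to
  one retained locus: least missingness, ties broken lexicographically.
* **Dedup.** One uniformly chosen sister per inferred family, seeded;
  males are untouched.

## Sibship inference and colony density

The family likelihood integrates the members' genotypes over one queen
(diploid, Hardy–Weinberg proportions at the supplied frequencies) and one
drone (haploid): per locus, member factor `0.5·(A[q1,d] + A[q2,d])` where
`A[a,d]` is the probability of the member's observed call given maternal
allele a and paternal allele d under the mistyping model
`P(obs o | true t) = (1−ε)·[o=t] + ε·p_o`. Per-locus member factors
multiply within a family and contract against the parental prior
`p⊗p⊗p`; a family of one reduces exactly to the unconditional genotype
probability, so the partition log-likelihood of all-singletons equals the
unrelated-individuals likelihood.

The search is deterministic agglomerative ML: start from singletons,
repeatedly apply the admissible merge with the largest positive gain in
total partition log-likelihood, stop when none remains. A merge is
admissible when the best cross-pair full-sib posterior (uniform prior over
{full-sib, unrelated}) reaches the threshold, default 0.95. This
deliberately replaces the stochastic MCMC pedigree search of the
conventional GUI program: it is reproducible and testable at desk scale,
and on error-free polymorphic data it provably reaches the exhaustive-ML
partition (verified against brute force over all set partitions in the
tests). The 0.95 figure is implemented as a posterior admission cutoff;
this is an interpretation of the conventional "probability of being full
siblings" setting, which the GUI program does not define precisely.
Allele frequencies default to plug-in estimates from the same females,
computed once (not iteratively).

Density chain per species × site: `N_ns = (N_nr/N_g)·N_i` unrounded, then
`N_c = 4.5·N·n·m/(1+2m)` (= 1.5·N_ns for n = m = 1) computed from the
unrounded N_ns; both reported to one decimal (deferring rounding is
required — rounding N_ns first changes 19.6 to 19.7 in the worked ED
cell). Sites with N_g ≤ 15 are skipped (no N_ns/N_c).

## F-statistics and allelic richness

Weir–Cockerham variance components a (among populations), b (among
individuals within populations), c (within individuals) per allele with
the standard n_c correction for unequal sample sizes; multilocus
θ = Σa/Σ(a+b+c) and f = 1 − Σc/Σ(b+c) over alleles and polymorphic loci.
Only diploid females enter (the estimators assume unrelated individuals,
which the sister dedup provides); negative estimates are reported
untruncated. 95% CIs are percentile bootstrap over loci (n_boot = 1000
default) — loci are the natural resampling unit for a ratio of locus
sums; the alternative locus jackknife is not implemented. Sites with
fewer than 25 genotyped females are excluded from θ/f and per-site
richness but kept in global richness.

Allelic richness is rarefied by the exact hypergeometric expectation; the
default depths are computed from the data as twice the smallest included
site size (per-site AR) and twice the smallest species total (global AR),
never hard-coded. The mean ± SE over loci uses the simple standard error
of the per-locus values.

## Male ploidy

A male is diploid when ≥ 3 of his typed loci are heterozygous; the rule is
a hard threshold, so males typed at fewer than 3 loci can only ever be
called haploid — they are counted haploid in the percentages and flagged
`indeterminate` in the table. Percentages print to two decimals. At zero
scoring error the rule has perfect specificity (haploids cannot read
heterozygous); at error ε the false-diploid rate is the exact
Poisson-binomial tail over loci, provided in closed form.

## Power simulation

A replicate drifts subpopulation frequencies (same mechanism and Ne = 1000
convention as the generator), samples 2n gene copies per subpopulation per
locus, and tests heterogeneity. `chi2_sum` sums per-locus Pearson
statistics and degrees of freedom; `fisher_combined` computes per-locus
exact p-values — scipy's Fisher exact test for 2×2 tables, otherwise
Monte-Carlo sampling of tables with fixed margins (Patefield sampling via
`scipy.stats.random_table`; the network algorithm is out of scope) — and
combines them with the −2Σlog p chi-square rule. Power is the fraction of
replicates with p < α, with binomial Monte-Carlo standard error. When both
(Ne, t) and a target F_ST are supplied they must agree to 1e-9; otherwise
t is solved from the target at fixed Ne.

## Body size

Cells (species × site) with ≤ 15 measured workers are excluded, then an
OLS two-way ANOVA with sum-to-zero coding and Type-III partial F tests
(the convention that keeps main effects interpretable under imbalance; the
sum-of-squares type is a design choice, not an assertion about any
particular prior analysis). LS means and contrast SEs come from the
equivalent cell-means parameterization, which is exact even when cells are
missing; contrasts use the residual degrees of freedom of the full model
(no Satterthwaite). Every unordered same-species pair of retained sites
yields one contrast; the Bonferroni threshold α/#contrasts is compared
exactly and only rounded (5 decimals) for display.

## Pipeline

`pipeline.run` executes the ladder in the order above with the defaults
0.20 / 0.25 / ε 0.05 / posterior 0.95 / min-pop 25 / N_g ≤ 15 skip /
> 15 workers / α 0.05, derives every stage seed deterministically from the
master seed, writes each stage's table to its own file, and keeps a
provenance log (without timestamps, so identical seeds give byte-identical
bundles). The density stage also accepts externally supplied
(N_i, N_g, N_nr) count tables, which allows completing the chain for
strata whose sibship reconstruction was done elsewhere.

## Problem sizes in the test suite

The suite validates calibration claims at deliberately modest Monte-Carlo
sizes chosen to keep the whole run in the minutes range: e.g. 1000 null
loci for HWE size, 120 locus pairs for LD size, 20 replicates of the
20-colony sibship benchmark, 40 panmictic replicates for CI coverage, and
500 drift replicates for power. Tolerances follow the binomial standard
errors these sizes imply.

## Known limitations

* The sibship search is greedy; pathological frequency configurations
  could in principle trap it in a local optimum that the admission gate
  cannot undo (no split/reassign moves).
* The mistyping model is class-I error only; allelic dropout and
  stuttering are not distinguished.
* The Fisher route's Monte-Carlo p-values are discrete (granularity
  1/(B+1)), making the combined test slightly conservative.
* F-statistics assume diploid, unrelated, non-inbred samples within
  sites; running them on data that skipped the sister dedup biases θ
  upward (demonstrated in the tests).
* GenePop export encodes haploid males as homozygotes plus a JSON sidecar
  manifest; third-party GenePop consumers will see them as diploid
  homozygotes unless they read the manifest.
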