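# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Pseudo-haploid data model

Every analysis assumes pseudo-haploid calls: at each SNP an individual
contributes one allele, sampled uniformly from their two chromosomes (one on
the male X). Calls are stored as REF/ALT/MISSING; the EIGENSTRAT text
dialect writes REF as digit 2, ALT as 0 and MISSING as 9. The heterozygous
digit 1 cannot occur in pseudo-haploid data, so it is an error under the
default `strict` reading and remapped to MISSING under `lenient`.
Coordinates are 1-based inclusive, hg19; the X pseudo-autosomal regions
default to chrX:60,001–2,699,520 and 154,931,044–155,260,560 and are removed
before any X-specific analysis.

QC thresholds (all configurable, defaults in `paleokin.config`): samples
need ≥ 20,000 called SNPs; SNPs need minor-allele frequency ≥ 0.01 among
called samples (all-missing SNPs are dropped with a warning — their
frequency is undefined); LD pruning uses r² ≥ 0.4 in 200-SNP windows with a
25-SNP step. Within a window, pairs are scanned left to right and the SNP
with the lower call rate is dropped (ties drop the right-hand SNP); r² is
the squared Pearson correlation of the haploid 0/1 calls over jointly called
samples, and pairs with fewer than 20 joint observations are treated as
uncorrelated. This greedy rule is deterministic and independent of sample
order.

## Kinship

For a pair with mismatch rate x over n jointly called autosomal SNPs,

    r = 1 − 2(x − b/2)/b ,

an affine, strictly decreasing function of x with r(b) = 0 and r(b/2) = 1.
The baseline b is the median mismatch over pairs with ≥ 100K overlap
(self-estimated per dataset because it absorbs population heterozygosity
and panel composition; the published central-European Neolithic value
0.2593 is kept available as a config constant). Bootstrap CIs resample SNPs
with replacement (percentile method, default 1,000 replicates); because the
discordance vector is 0/1, resampling is drawn exactly as
Binomial(n, x)/n without materialising index arrays.

Degree bins sit at the midpoints of the expected r values — identical
r ≥ 0.75, first 0.375–0.75, second 0.1875–0.375, unrelated below — since
the source scheme for these cutoffs is not printed anywhere; midpoints
reproduce its intent. "More than two possible degrees" is operationalised
as the 95% CI of r intersecting ≥ 3 bins; such pairs, and pairs with
< 2,500 overlapping SNPs, are left unassigned.

## Two-source ancestry and sex bias

Supervised ancestry with two fixed sources reduces to a one-dimensional
problem: with per-SNP ALT frequencies f_WHG and f_AN, the probability that
a sampled allele is ALT for an individual with WHG fraction q is
q·f_WHG + (1−q)·f_AN, and the log-likelihood over SNPs is concave in q. We
maximise it by bounded scalar optimisation (tolerance 1e-6). This
deliberately replaces a supervised ADMIXTURE run: with K = 2 fixed sources
the two approaches estimate the same quantity, and the closed-form
likelihood keeps the estimator transparent and fast enough for thousands of
down-sampling replicates. Source frequencies estimated from reference
panels get a pseudocount of 0.5 per allele class and are clipped to
[0.001, 0.999] to keep the likelihood off the log(0) boundary. If the two
source frequencies coincide at every used SNP the likelihood is flat; q is
reported as 0.5 with a non-identifiability flag.

R_X/A estimates q on all called X SNPs and, per replicate (default 1,000),
on an equally sized autosomal subset drawn without replacement; the
reported ratio divides q_X by the mean replicate q_A (the aggregation is
not pinned down externally, so the mean is used and replicate-level ratios
are retained). Individuals with < 1,000 called X SNPs are excluded. Tests:
exact right-tailed binomial on the count of individuals with R_X/A < 1
(ties at exactly 1 count as "not below"), and a paired Wilcoxon signed-rank
per replicate (exact null for n ≤ 25 without ties, otherwise the
tie-corrected normal approximation with continuity correction; zero
differences dropped; an all-zero difference vector reports p = 1), with the
median p over replicates as the summary.

The Q statistic uses a haploid adaptation of the Weir–Cockerham (1984)
ANOVA estimator: per SNP with group sizes n_i and frequencies p_i,
MSP = Σ n_i (p_i − p̄)², MSG = Σ n_i p_i (1−p_i)/(n−2), and
n_c = n − (n₁²+n₂²)/n; the weighted multi-SNP estimate is
Σ(MSP − MSG) / Σ(MSP + (n_c−1)·MSG). SNPs lacking a call in either group or
monomorphic overall contribute nothing. Q = ln(1−2Fst_A)/ln(1−2Fst_X) is
undefined for Fst ≥ 0.5 or Fst_X = 0 (errors).

## HLA statistics

Frequencies count two alleles per typed individual, per locus; individuals
untyped at a locus are excluded from that locus only. One representative
per first-degree cluster is kept (most typed loci, ties to the smallest
sample id). Fisher 2×2 tables are built on allele counts (this-allele vs
all-others), matching frequency-scale reporting; the two-sided p sums the
probabilities of margin-fixed tables no more probable than the observed
one.

Multiple testing uses the two-stage Benjamini–Hochberg procedure: stage 1
runs the BH step-up at α′ = α/(1+α) and estimates the number of true nulls
as m₀ = m − r₁; stage 2 is BH with m₀ in place of m, i.e. the adjusted
value for the i-th order statistic is min_{j≥i} p_(j)·m₀/j, clipped to
[0, 1]. The procedure is authored here so the adjusted values have this
exact definition; tests cross-check the rejection set against statsmodels'
`fdr_tsbh`. By default all alleles of all six loci form one family per
group comparison; a per-locus family is available. An allele is "significant"
only when adjusted p ≤ 0.05 *and* |Δfreq| ≥ 0.1.

The resampling comparison redraws both groups with replacement (100×) at
the smaller group's size in individuals, recomputes frequencies, and
compares the per-allele frequency distributions with a two-sided
Mann–Whitney U (average ranks, tie-corrected normal approximation — the
resampled frequencies tie heavily), TSBH-adjusted. Shannon diversity
resamples n alleles (the smallest population's 2×typed-individuals count)
weighted by each population's frequencies, 100 times, and compares the H′
distributions by Kruskal–Wallis plus Dunn's pairwise z tests on pooled
ranks with tie correction; Dunn p-values are TSBH-adjusted for internal
consistency (no external prescription exists for this step). Dunn's test is
implemented in-package (pooled-rank z with tie correction) as no installed
dependency provides it. The "smallest population size" is counted in
individuals for the frequency resampling and in alleles (2n) for Shannon,
mirroring how each procedure consumes the data.

Two-locus haplotype frequencies use the gametic-phase EM for unphased
multi-allelic genotypes: only double heterozygotes are phase-ambiguous, the
E-step splits them between the two configurations in proportion to the
current haplotype frequency products (multiplicity 2 for distinct
haplotypes), the M-step re-estimates from expected counts. Initialisation
at linkage-equilibrium product frequencies; convergence when the largest
frequency change drops below 1e-8 (cap 1,000 iterations); the observed-data
log-likelihood is asserted non-decreasing at every step. The algorithm is
deterministic.

## Local ancestry

A_i averages the per-SNP WHG probability over both haplotypes of every
individual (haplotypes → individual mean → across-individual mean, which
equals pooling all 2N haplotypes but keeps per-individual values reusable
for the carrier tests). Z_i = (A_i − μ)/σ with μ, σ taken genome-wide over
SNPs and σ the population SD (denominator N) — the score is descriptive,
not inferential. A constant track (σ numerically 0) is an error. Region
enrichment compares the mean A_i inside the region (default: extended MHC,
5-Mb flanks) with the genome-wide mean. Carrier tests define carriers by
presence of ≥ 1 allele copy, exclude individuals untyped at the locus, skip
alleles leaving fewer than two individuals in either class, use the exact
Mann–Whitney null when the pooled values are tie-free and small (≤ 40) and
the asymptotic tie-corrected form otherwise, and adjust with Holm–Šidák
across the tested allele set.

## Synthetic-data generator

What it emulates, and how:

* **Sources.** Balding–Nichols drift: ancestral frequency
  p ~ Uniform(0.05, 0.95) per SNP; each source draws from
  Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance F·p(1−p)). Defaults
  F_WHG = 0.15, F_AN = 0.10 — enough differentiation for supervised
  estimation, comparable to strongly drifted Holocene populations.
* **Admixture pulse.** One pulse G = 22 generations ago with male
  contribution c_m and female contribution c_f of WHG ancestry; stationary
  WHG fractions (c_m+c_f)/2 on autosomes and (c_m+2c_f)/3 on the X.
  Default c_m = c_f = 0.35, matching the late-farmer autosomal WHG scale.
* **Tracts.** A stationary renewal process at rate G per Morgan whose
  segments draw ancestry i.i.d. from the stationary law — exactly the
  two-state Markov chain with relaxation rate G. Renewal segments average
  100/G ≈ 4.5 cM at G = 22; ancestry-constant runs are longer by the factor
  1/(1−α) (or 1/α), which the tests account for. The X uses rate 2G/3
  (recombination only in females). This is *not* an explicit
  per-generation pedigree: tract-length variance beyond the exponential
  approximation, interference, and sex-specific maps are not modelled.
* **Panel.** 50,000 autosomal SNPs split over 22 chromosomes of 130 Mb and
  5,000 X SNPs (the scale of the real X panel after filtering), uniform
  1 cM/Mb map, evenly spaced positions.
* **Observation.** One random haplotype per site per individual, then
  independent missingness (default 10%). No aDNA damage or genotyping
  error — missingness is the only observation noise, so error-driven
  mismatch inflation in kinship is out of scope.
* **Relatives.** Gene dropping with Poisson crossovers (1/Morgan, no
  interference): parent–offspring, grandparent–grandchild chains, and
  re-observed duplicates. Fathers pass their X without recombination and
  not to sons.
* **HLA.** Each MHC haplotype draws a DRB1–DQB1 haplotype from the pool of
  its true MHC-majority ancestry (WHG pool enriched for
  DRB1\*08:01–DQB1\*04:02); HLA-A comes from a shared ancestry-neutral
  pool. Pool contents are synthetic — loosely shaped like Neolithic tables
  but with no claim of historical accuracy.

Consequently, green tests show that the *statistics* behave as designed
under their own model assumptions (unbiasedness, calibration, error
control); they cannot certify robustness to reference bias, damage,
contamination, or non-exponential tract structure in real data.

## Problem sizes and stochastic calibrations

Calibration experiments use sizes chosen to keep Monte Carlo error well
below the effect being checked:

* Q: 50 replicate Wright–Fisher splits, 500 individuals per sex, 50
  generations, 5,000 loci per compartment, 100 sampled haploid genomes per
  population (per-replicate SD of Q ≈ 0.04, so the mean carries SE ≈ 0.006).
* R_X/A: the across-individual mean of a *single* 40-individual cohort has
  SD ≈ 0.055, almost entirely the true tract-level sampling variance of X
  ancestry (the estimate correlates 0.96 with the cohort's true ratio).
  The calibration therefore averages the cohort mean over 8 independent
  cohorts (SE ≈ 0.02), which measures estimator bias rather than one
  cohort's draw; per-cohort conditions (40 individuals, 50,000/5,000 SNPs,
  1,000 down-sampling replicates) are unchanged.
* EM recovery likewise averages over 10 independent n = 90 tables, since a
  single multinomial draw puts the planted haplotype frequency at SD ≈ 0.03.

## Seeding and determinism

One master seed per run; every analysis derives an independent NumPy
substream keyed by a short name (CRC-32 of the name as a spawn key), so
adding or reordering analyses does not perturb other streams. Identical
config + seed yields byte-identical outputs; the pipeline records a SHA-256
hash of the configuration in every report.

## Known limitations

* The degree-bin cutoffs are a documented stand-in for an unpublished
  scheme; borderline second/third-degree pairs depend on them.
* The haploid Fst estimator assumes two groups; no multi-population form.
* The ancestry estimator treats SNPs as independent given q; with tract
  LD the nominal likelihood curvature overstates per-individual precision
  (only ratios and cohort means are interpreted here).
* `estimate_ancestry` requires externally supplied or reference-estimated
  source frequencies; misspecified sources bias q toward 0.5.
* The EM reports a single mode; for pathological genotype configurations
  with multiple likelihood modes it returns the one reached from the
  linkage-equilibrium start.
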