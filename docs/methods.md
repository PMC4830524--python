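# Methods

This note documents the statistical procedures implemented in `pdhs`, the
design choices made where the method left room, and what the synthetic-data
generator does and does not emulate.

## Coordinates and set semantics

BED intervals and gene TSS are 0-based half-open; VCF positions are 1-based,
so a SNP at VCF position `p` occupies 0-based position `p − 1`. Chromosome
names are matched by exact string equality (an explicit alias map,
`rename_chroms`, is available; nothing is normalised silently). All inputs
must share one coordinate system — the package performs no lift-over.

The subtractive screen retains a SNP iff some DHS interval on the same
chromosome contains its 0-based position, then removes SNPs present in the
comparator strain. The default identity key is `(chrom, pos, alt)`
(allele-aware, the conservative reading of "present in the comparator");
position-only matching is available as `match_mode="position"`. Overlapping
DHS intervals are used as-is — merging would not change membership and would
lose provenance. An optional second DHS track (`high_stringency_dhs`)
intersects before subtraction.

## Regulatory domains

Every gene receives a basal domain: 5 kb upstream and 1 kb downstream of the
TSS by default, strand-aware, regardless of neighbours, clipped to the
chromosome, and always containing the TSS base itself even if a side width
is zero. The extended domain grows in each direction until the nearest other
gene's basal-domain edge on that side (strand ignored; the edge considered
on the left is the maximal basal *end* among genes with TSS ≤ the gene's
own, symmetric on the right — with strand-asymmetric basal windows a
farther gene's basal edge can be the nearest obstruction), capped at 1 Mb
measured from the TSS, and clipped to the chromosome. The gene's own basal
domain is never truncated: the extended domain is the union of the basal
window and the extension interval. Genes with identical TSS bound each other
on both sides, each keeping its full basal window. The 1 Mb cap is measured
from the TSS, not from the basal edge. A region (or a SNP, treated as a
width-1 region) is associated with every gene whose extended domain it
overlaps; basal-only assignment is a flag. Curated per-gene domains are not
supported.

## Expression screens

**Normalisation.** Median-array normalisation on the log2 scale: the
reference is the sample whose median expression is the median of all
per-sample medians (lower of the two middle samples when even); every sample
is shifted additively so its median equals the reference's. The operation is
idempotent.

**Variance filter.** The log-intensity-variation filter keeps genes whose
expression varies more than the array-typical gene: per gene,
`T = (n − 1) · s_i² / s_med²` with `s_i²` the gene's sample variance and
`s_med²` the median of all gene variances, referred to the upper tail of
χ²(n − 1); genes with p < 0.05 are retained. The original screening tool
names this filter without printing its formula; the variance-ratio-to-median
chi-square above is the reconstruction used here and is the package's
defined behaviour.

**Cox screen.** Per-gene univariate Cox proportional hazards against DMFS:
safeguarded Newton iteration on the partial likelihood (step-halving, at
most 50 iterations, convergence when the update drops below 1e−9 on the
standardised-covariate scale), Efron tie handling by default with Breslow
selectable. |β| is capped at 15 on the standardised scale; reaching the cap
sets a monotone-likelihood flag (complete separation — the MLE is infinite
and the reported value is the cap). The default p-value is the two-sided
Wald test; a likelihood-ratio p is available behind `p_kind="lr"`. Sign
convention: higher expression with earlier events gives β > 0, HR > 1.

**Spearman screen.** ρ is the Pearson correlation of mid-ranks (average
ranks at ties). The p-value is exact by full enumeration when n ≤ 9 and
neither vector has ties, otherwise the t approximation
`t = ρ·√((n−2)/(1−ρ²))` on n − 2 degrees of freedom.

**Calling rule.** Genes are called at raw two-sided p < 0.05 with no
multiple-testing correction — deliberately low-stringency, matching the
screen's subtractive philosophy; a Benjamini–Hochberg column is attached for
information only. Screens operate on gene-level matrices; a max-variance
probe collapse utility handles duplicated gene ids.

## Signatures and survival evaluation

Signature weights are log2(HR) (DMFS mode), the Spearman coefficient
(correlation mode), or the signed expression fold change filtered at
|FC| > 10 (fold-change mode). A sample's score is the weighted mean of
(by default z-scored, ddof = 1) expression over the signature genes present
in the cohort; missing genes are dropped and reported as coverage, never
imputed. Standardised scoring makes the score invariant to per-gene affine
rescaling of expression.

Samples are stratified at empirical quantile cut points (tertiles by
default, median split optional); cut points are actual data values (lower
interpolation) and samples exactly on a cut point go to the lower group.
Survival separation is tested with the k-group log-rank statistic
(hypergeometric variance at each distinct event time, χ² with k − 1 df),
and per-group Kaplan–Meier curves are returned. The stratified evaluation's
headline statistic — also the permutation comparison metric — is the
log-rank chi-square, which is monotone in the displayed p-values but
immune to floating-point underflow ties. The downstream scoring cannot
distinguish a signature from its global sign flip (group relabelling), and
the log-rank statistic is invariant to it.

Discovery/test reweighting (`split_and_reweight`) splits a cohort in half
(stratified by event indicator, deterministic in the seed), refits per-gene
univariate Cox on the discovery half and emits fresh log2(HR) weights;
evaluation on the held-out half is the caller's composition.

## Permutation nulls

Three schemes: `random_genes` keeps the observed weight multiset and assigns
it to a uniform random gene subset of equal size (without replacement) from
the gene universe; `random_weights` keeps the genes and draws i.i.d. normal
weights with mean 0 and the observed weights' SD (unit SD optional);
`random_both` combines the two. The gene universe defaults to all genes of
the validation expression matrix. Empirical significance uses the
+1-corrected estimator `(1 + #{null ≥ observed}) / (1 + n_perm)`, which is
never zero and never anti-conservative; 1,000 permutations is the default.
Fisher's combined probability test (`X = −2·Σ ln pᵢ` against χ²(2k)) and a
2×2 Pearson chi-square with optional Yates correction round out the
statistics toolkit.

## The synthetic-data generator

The generator emulates the statistical structure of the real study: a small
multi-chromosome genome with uniformly spaced genes; DHS intervals covering
< 2% of the genome with one DHS guaranteed inside every gene's basal domain;
Poisson-uniform background SNPs per strain, a configurable fraction shared
with the comparator; and one to three target-only SNPs planted inside a
basal-domain DHS of every causal gene, so the subtractive screen and both
assignment modes recover every causal gene by construction.

Cohorts are generated from a latent gene-by-sample standard-normal field.
Two deliberate structural choices:

* **Causal co-expression.** The causal genes share a per-sample latent
  factor with variance fraction `causal_corr = 0.1`, sign-aligned with each
  gene's effect direction. This encodes the screen's biological premise that
  susceptibility genes act as a coordinated program rather than twenty
  independent coins. It is also a statistical necessity: with fully
  independent causal genes, the unmodelled remainder of the linear predictor
  acts as a strong frailty that attenuates every marginal Cox fit, putting a
  ceiling of roughly 60% on per-gene recovery at |β| ≤ 0.6 and n = 150
  regardless of censoring — no marginal screen could then recover a planted
  program of this effect size. At r = 0.1 the per-gene recovery of the DMFS
  screen is ~99% under the reference conditions.
* **Variance heterogeneity.** Causal genes, and 45% of non-causal genes,
  have their expression SD doubled (variance ×4). Causal genes must be
  variable — the screen's premise is that functional polymorphism drives
  expression variation, and the variance filter would otherwise delete the
  planted truth. The variable fraction is kept just under one half so that
  the median gene variance, the filter's reference point, stays anchored in
  the non-variable majority and the filter separates the two populations
  cleanly.

The per-sample linear predictor is `L = Σ β_g ε_g` over the causal genes'
latent (unit-variance) values, with |β| drawn uniformly from `beta_range`
and random signs. Metastasis counts are negative binomial with mean
`5·exp(L)` and dispersion 2; DMFS times are exponential with hazard
`0.1·exp(L)` (a Weibull shape parameter is exposed); censoring is
independent uniform on (0, c) with c solved by bisection so the expected
censoring fraction matches the 0.3 target — between the two tumour cohorts'
observed censoring levels. Expression values add a per-gene baseline
(N(8, 1)) and per-sample shifts (N(0, 0.2)) so the normalisation step has
real work to do. All randomness flows from a single seed through
stage-tagged child generators; bundles are bit-reproducible, and expression
TSVs are written at 6 significant digits (round-trip is exact for the
integer-coordinate genomic files and to 1e-5 relative for expression).

What the generator does **not** emulate: linkage disequilibrium and haplotype
structure, array probe effects, batch structure, hormone-receptor biology,
or realistic chromosome counts and SNP densities. Passing tests therefore
demonstrate the correctness and calibration of the machinery — exact set
semantics, correct survival statistics, nominal type-I error, recovery of
plantable signal — not the field performance of the screen on real cohorts.

## Reference study conditions and problem sizes

The reference synthetic study uses 5 chromosomes × 10 Mb, 2,000 genes,
3,000 background DHS of 150 bp, background SNP rate 0.002/bp, shared
fraction 0.5, 20 causal genes with |β| ∈ [0.3, 0.6], 150 tumour samples and
500 validation samples. Oracle sweeps in the test suite run 1,000 random
instances each with sizes drawn small enough to keep the brute-force
comparisons comfortable; calibration checks pool 50 cohort seeds (screens)
and 200 outer seeds × 99 permutations (empirical-p uniformity). The
permutation default in the pipeline and acceptance script is 1,000.

## Known limitations

* The Cox screen is marginal by design; it inherits the usual attenuation
  of marginal hazard estimates under omitted covariates, and the reported
  HRs should be read as screening weights, not causal effect sizes.
* The exact-permutation Spearman p is only used at n ≤ 9 without ties;
  heavily tied count data at small n fall back to the t approximation.
* Monotone-likelihood Cox fits report the capped coefficient with a flag;
  downstream weighting treats them like any other hit.
* The quantile stratification sends boundary ties to the lower group, so
  group sizes can differ by the number of tied boundary samples.
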