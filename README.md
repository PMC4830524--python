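# pdhs — a subtractive polymorphic-DHS screen for metastasis-susceptibility genes

Inherited polymorphism, not just somatic mutation, shapes whether a tumour
metastasises. Most of that inherited signal is regulatory: strain- or
patient-specific variants sitting in open chromatin that tune the expression
of nearby genes. `pdhs` implements an integrated *subtractive* screen that
walks from raw variant calls to validated prognostic gene signatures:

1. **Subtractive SNP filter.** Restrict the low-metastasis strain's SNPs to
   DNase-hypersensitive sites (DHS), then subtract every variant shared with
   the high-metastasis host strain. What survives — the polymorphic-DHS
   (pDHS) SNP set — is enriched for variants that could causally alter
   cis-regulation.
2. **Regulatory-domain gene assignment.** Each gene gets a basal domain
   around its TSS (5 kb upstream / 1 kb downstream, strand-aware) extended
   toward its neighbours' basal domains up to 1 Mb from the TSS; a pDHS SNP
   is assigned to every gene whose domain covers it.
3. **Expression screens.** Tumour-cohort expression is median-array
   normalised, filtered for genes whose log-intensity variation exceeds the
   array-typical gene (chi-square test on the variance ratio to the median
   gene variance), then screened gene-by-gene: univariate Cox proportional
   hazards against distant-metastasis-free survival (DMFS), and Spearman
   rank correlation against metastasis counts, both called at raw p < 0.05.
4. **Weighted signatures.** Screen hits become signatures with weight
   log2(hazard ratio) (DMFS mode) or the Spearman coefficient (correlation
   mode); a fold-change mode (|FC| > 10) covers treatment contrasts. A
   cohort sample's score is the weighted mean of z-scored expression over
   the signature genes; samples are cut into score tertiles and survival
   separation is tested by the k-group log-rank test.
5. **Permutation nulls.** Signature significance is referenced against three
   nulls — random genes with the observed weights, random Gaussian weights
   on the observed genes, and both at once — with the +1-corrected empirical
   p = (1 + #{null ≥ observed}) / (1 + n_perm).

A first-class synthetic-data module generates a complete study (genome,
DHS, two strain VCFs, a tumour cohort with counts and censored survival, an
independent validation cohort) with *planted* causal genes, so the whole
pipeline is testable end to end with no external downloads.

## Worked example

```python
import pdhs

study = pdhs.generate_study(pdhs.GeneratorConfig(seed=1))

# 1-2: subtract, then map surviving SNPs to genes
snps, summary = pdhs.run_subtractive_screen(study.target, study.comparator, study.dhs)
print(summary)
domains = pdhs.build_regulatory_domains(study.genes, sizes=study.sizes)
_, pdhs_genes = pdhs.assign_regions_to_genes(snps, domains)

# 3: normalise, variance-filter, screen against DMFS
expr = pdhs.normalize_to_median_array(study.mouse_expr)
variable, _ = pdhs.log_intensity_variation_filter(expr)
candidates = sorted(set(pdhs_genes) & set(variable))
hits = pdhs.screen_genes(expr, study.mouse_pheno, candidates, "dmfs")

# 4-5: signature, validation, permutation null
sig = pdhs.build_weighted_signature(hits.passing, "dmfs")
ev = pdhs.evaluate_signature(sig, study.human_expr, study.human_pheno)
perm = pdhs.permutation_test(
    sig, study.human_expr, study.human_pheno,
    pdhs.PermutationConfig(scheme="random_genes", n_perm=1000, seed=1),
)
```

This prints / produces:

```
SubtractionSummary(n_input_snps=100120, n_in_dhs=1518, n_shared_removed=739, n_retained=779)
pdhs_genes: 817 of 2000 genes
candidates: 378, DMFS hits: 35 (all 20 planted causal genes among them)
log-rank chi2 = 590.3, df = 2, p = 6.7e-129, tertile sizes [167, 166, 167]
permutation empirical p = 0.000999  (0 of 1000 random gene sets score higher)
```

Of 100,120 strain-specific SNPs only 779 fall in open chromatin and are
absent from the comparator strain; they implicate 817 genes, 378 of which
also vary in expression. The DMFS screen keeps 35 of those — including
every planted causal gene — and the resulting signature splits the
independent 500-sample validation cohort into tertiles with dramatically
different survival, far beyond anything 1,000 random gene sets achieve.

The same workflow is available from the shell:

```bash
pdhs simulate --seed 1 --out fixtures/
pdhs subtract --target fixtures/target.vcf --comparator fixtures/comparator.vcf \
              --dhs fixtures/dhs.bed --out pdhs.tsv --summary summary.json
pdhs run --config pipeline.yaml        # the full screen, one YAML config
```

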