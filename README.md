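# chipewas

Epigenome-wide association meta-analysis of clonal hematopoiesis of
indeterminate potential (CHIP), as a reusable, tested pipeline.

CHIP — somatic driver mutations (variant allele frequency ≥ 2%) in
myeloid-malignancy genes such as *DNMT3A*, *TET2* and *ASXL1* carried in
blood without hematologic malignancy — reshapes the blood DNA methylome and
raises cardiovascular disease risk. This package implements the full
analysis chain used to characterize those changes, for epigenetic
epidemiologists working with cohort methylation data:

- **Cohort EWAS** (`chipewas.ewas`): per-CpG least squares of methylation
  beta values on CHIP carrier status plus covariates,
  `β̂ = (XᵀX)⁻¹Xᵀy`, with optional cluster-robust (family) standard
  errors; genomic-control inflation `λ = median(χ²₁)/0.455` with
  `χ²/λ` deflation applied when λ > 1.5.
- **Stratified + cross-race meta-analysis** (`chipewas.meta`):
  fixed-effects inverse-variance weighting `TE = Σwᵢβᵢ/Σwᵢ`,
  `w = 1/se²`, with Cochran's Q / I², Bonferroni thresholds
  (0.05/400,000 ≈ 1×10⁻⁷), BH-FDR, and the descriptive summaries:
  direction of effect, overlap concordance, cis/trans (1 Mb) driver-gene
  classification, VAF-sensitivity re-identification.
- **Cis-eQTM** (`chipewas.eqtm`): residualized expression ~ residualized
  methylation for all CpG–transcript pairs within 1 Mb of the TSS.
- **Engineered-cell validation** (`chipewas.evoc`): strand-collapsed mC
  fractions from six-base-chemistry read counts, Welch-screened KO-vs-control
  shifts, and the one-sided exact binomial quadrant test of sign concordance
  with EWAS effects.
- **Two-sample Mendelian randomization** (`chipewas.mr`): cis-mQTL
  instruments (p < 2×10⁻¹¹, LD-pruned greedily at r² < 0.01), Wald ratio
  `β_Y/β_X` for single instruments, fixed-effect IVW
  `β_MR = Σβ_Xβ_Y/se_Y² / Σβ_X²/se_Y²` otherwise, heterogeneity and
  MR-Egger intercept screens with exclusion at p < 0.05, BH-FDR per outcome.
- **Trait-set enrichment** (`chipewas.enrich`): Fisher exact tests of CpG
  sets against trait catalogs with a Bonferroni scan threshold α/k.
- **Synthetic data** (`chipewas.simulate`): generates every input above
  with known ground truth — driver-specific direction skew, confounding,
  family clustering, mQTL→methylation→outcome causal chains with optional
  pleiotropy, and replicate KO count data.

## Worked example

```python
import chipewas as cw
from chipewas.io import summary_stats_frame

meth, pheno, truth = cw.simulate_cohort(
    n_samples=2000, n_cpgs=1500,
    chip_prevalence={"DNMT3A": 0.08, "TET2": 0.08},
    effect_size=0.05, causal_fraction=0.2, noise_sd=0.04,
    direction_skew={"DNMT3A": 1.0, "TET2": 0.10}, rng_seed=777,
)
records, summary = cw.run_ewas(
    meth, pheno, exposure="DNMT3A",
    covariate_columns=["age", "sex", "cf_gran", "cf_lymph"],
)
print(f"lambda = {summary.lambda_gc:.3f}, cases = {summary.n_cases}")
table = summary_stats_frame(records).rename(columns={"beta": "te"})
print(cw.direction_summary(table, 1.25e-7))
```

prints

```
lambda = 1.720, cases = 146
{'n_sig': 300, 'n_negative': 300, 'n_positive': 0,
 'percent_negative': 100, 'percent_positive': 0}
```

All 300 epigenome-wide-significant CpGs for the *DNMT3A* exposure show
decreased methylation — exactly the generating skew (100% negative),
mirroring the hypomethylating effect of *DNMT3A* loss of function. λ is
well above 1 because a fifth of the probes are truly associated, not
because of bias; since λ > 1.5 the records returned have already been
genomic-control corrected (`summary.gc_applied` is `True`).

A command-line shell mirrors the library
(`chipewas simulate | ewas | meta | eqtm | evoc-validate | mr | enrich`);
run `chipewas --help`.

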