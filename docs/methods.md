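# Methods

## Scope and model overview

`chipewas` analyzes differential DNA methylation associated with clonal
hematopoiesis of indeterminate potential (CHIP) and follows the methylation
signal downstream to expression, engineered-cell validation and causal
inference. Methylation is represented throughout as beta values in [0, 1]
(fraction of methylated signal per CpG); CHIP status is a binary exposure
defined by a somatic driver mutation at VAF ≥ 2%, optionally restricted to
a single driver gene (*DNMT3A*, *TET2*, *ASXL1*).

## Cohort EWAS

Each CpG is fit by ordinary least squares of methylation on
[intercept, CHIP status, covariates]. The solver is vectorised across
probes: the projection `(XᵀX)⁻¹Xᵀ` is formed once per design, so a
10,000-probe cohort fits in seconds. P-values are two-sided from the t
distribution with residual degrees of freedom.

**Relatedness.** Family structure is handled with a CR1 cluster-robust
sandwich standard error (cluster = family) with a t reference on
(n_clusters − 1) df, rather than a REML mixed model. This preserves the
fixed-effect estimate and corrects its standard error for intra-family
correlation at a fraction of the cost; it does not borrow strength across
families the way a random-intercept model would, so it is slightly
conservative under strong clustering. The single-probe path is verified
against `statsmodels` OLS with clustered covariance in the tests.

**Exposure definitions.** For a driver-gene exposure, carriers of *other*
drivers are excluded from the controls to avoid contaminating the control
group with a different methylation signature. Runs with fewer than 2 cases
are refused. A VAF floor (`min_vaf=0.10`) re-runs the analysis excluding
small clones, the sensitivity design.

**Genomic control.** λ is the median association χ²₁ statistic divided by
the median of the χ²₁ distribution. The divisor defaults to the exact
median 0.454936… (often quoted rounded as 0.456) so that a p-value vector
with median exactly 0.5 gives λ = 1 identically. When λ exceeds the
correction threshold (default 1.5), every probe's χ² is divided by λ —
equivalently SE × √λ, betas untouched — and p-values are recomputed from
the χ²₁ tail. The correction is monotone (never decreases a p-value for
λ > 1) and recentres the recomputed λ at 1.

## Meta-analysis

Fixed-effects inverse-variance weighting only: `TE = Σwβ/Σw`, `w = 1/se²`,
`se_TE = 1/√Σw`, z and two-sided normal p. Heterogeneity is Cochran's
`Q = Σw(β − TE)²` on k − 1 df with `I² = max(0, (Q − df)/Q)`. Probes are
restricted to the intersection present in every contributing cohort before
combination, and the per-study direction string follows a canonical
ordering: studies sorted by (stratum, cohort id).

The cross-race estimate is two-stage by default — IVW of the two
stratum-level IVW results — with a one-stage pooling of all cohort results
available via `two_stage=False`. With fixed-effects weighting the two are
algebraically identical for complete probes; the flag mainly changes the
direction-string granularity and how incomplete probes drop out.

Significance uses strict inequality p < α/m. Multiplicity defaults:
epigenome-wide α/m = 0.05/400,000 = 1.25×10⁻⁷; BH step-up FDR q < 0.05 as
the lenient tier. Percentages in the descriptive summaries (direction of
effect, overlap concordance, re-identification) are rounded half away from
zero to the nearest integer; cis/trans fractions are reported unrounded.
A CpG is *proximal* to a driver gene iff it is on the same chromosome and
within 1 Mb of the gene body (distance 0 inside [start, end], else gap to
the nearer edge; boundary inclusive — remote requires distance strictly
greater than the window).

## Cis-eQTM

Expression and methylation are each residualized on the supplied covariate
matrix (which must include or span an intercept); principal components are
consumed as precomputed columns, not computed internally, since in
practice they come from the cohort processing pipelines. The association
is then a simple regression of expression residual on methylation residual
with a t-based two-sided p on n − 2 df (the t, rather than normal,
reference is the package's choice and matters only at small n). Cis pairs
are CpG–TSS distances ≤ 1 Mb on the same chromosome, boundary inclusive;
pair enumeration is deterministic (chromosome, position, gene id).

## Engineered-cell validation

Per CpG, forward and reverse strand counts are summed first, then the mC
fraction `reads_mc / (reads_mc + reads_c)` is computed per replicate
(reads calling A/T/G are excluded from the denominator; a zero denominator
yields a missing value and the site drops out). The KO effect is the
difference in mean fraction between KO and control replicates, screened
with a two-sided Welch (unequal-variance) t-test at p < 0.05. Sites
passing the screen enter the quadrant test: the count of sites with
`delta · TE > 0` against Binomial(n, ½), one-sided upper tail by default
("enrichment"); a two-sided option exists. Ties (delta or TE exactly 0)
are excluded from the count, not split. The null probability stays at ½ —
no correction for a background sign skew — so a genome-wide directional
shift in the KO would inflate the test; interpret accordingly.

## Mendelian randomization

Instruments per exposure CpG are cis-mQTLs (within 1 Mb, association
p ≤ 2×10⁻¹¹) pruned greedily: candidates sorted by ascending p (ties:
larger |β_X|, then snp id), accepted iff r² < 0.01 against every accepted
SNP. r² is the squared Pearson correlation of diploid dosages from the LD
reference, or looked up from a precomputed pairwise table; SNPs absent
from the LD source are dropped. Harmonization flips the outcome beta when
the stated effect alleles disagree and drops unresolvable mismatches.

Estimation: Wald ratio `β_Y/β_X` with first-order delta SE `se_Y/|β_X|`
for a single instrument; fixed-effect IVW otherwise (the precision-weighted
mean of per-instrument Wald ratios with weights `β_X²/se_Y²`). Exposure
uncertainty is ignored (NO Measurement Error assumption), standard for
strong instruments at p < 2×10⁻¹¹. Diagnostics: Cochran's Q over Wald
ratios (≥ 2 IVs) and the MR-Egger intercept (≥ 3 IVs; instruments oriented
so β_X > 0, weights 1/se_Y², t reference on n − 2 df). Records failing
either screen at p < 0.05 are *excluded*, not corrected. BH-FDR is pooled
within each outcome by default (a global pooling option exists); the
significant set is q < 0.05.

## Enrichment

Two-sided Fisher exact test on the 2×2 membership table of query ×
catalog within a declared universe. The universe defaults to the probes
tested in the meta-analysis. Odds ratios use the Haldane–Anscombe 0.5
correction when a cell is zero (p-values remain exact and uncorrected);
a perfectly nested maximal overlap is flagged with an infinite OR. Catalog
scans use a Bonferroni threshold α/k over the k traits.

## Synthetic-data generator

The generator defines the package's study conditions; all recovery and
calibration results are relative to it.

**Cohorts.** Driver carriers are mutually exclusive with prevalences
defaulting to DNMT3A 3%, TET2 1.5%, ASXL1 1% (≈ 5.5% any-CHIP, matching
an elderly cohort). Carriers are age-biased to create genuine confounding;
covariate loadings on methylation (age, sex, granulocyte and lymphocyte
fractions) are small and global. A causal fraction of CpGs (default 5%)
per driver receives a signed effect of |δ| = 0.05 beta units, with the
fraction of negative signs set by the direction skew (DNMT3A 1.0,
TET2 0.10, ASXL1 0.76 — the directional asymmetries expected from the
drivers' opposing effects on global methylation). Methylation is formed on
the logit scale — baseline logit plus (effects + confounding + family
intercept + noise) scaled by the local logistic slope b(1−b) — and
squashed with the logistic function, so values never leave [0, 1] while
the realized beta-scale case-control difference stays ≈ δ to first order.
Baselines are drawn symmetric about 0.5 (Uniform(0.35, 0.65)) so the
second-order squashing bias averages out across causal probes. VAF is a
two-part mixture: a configurable fraction of carriers (default ½) above
10%, the rest in [2%, 10%), exercising the sensitivity filter. What this
does *not* emulate: probe-wise heteroscedasticity and spatial correlation
of real arrays, cell-composition shifts caused by CHIP itself, batch
structure. Passing tests therefore certify the statistics, not robustness
to those artifacts.

**mQTL/MR chains.** Lead instruments are independent Binomial(2, MAF)
dosages over an LD reference (default 500 samples); optional shadow SNPs
are haplotype copies with small flip probability, giving within-block
r² ≫ 0.01 for pruning tests. mQTL effects are Uniform(0.1, 0.3) with
random sign and z-scores in [8, 15], so all designated instruments pass
the 2×10⁻¹¹ ceiling. Outcome statistics follow
β_Y = θβ_X + α + N(0, se_Y) with se stored exactly — the standard
two-sample generating model, which makes Wald/IVW/Egger identities exact
in the noiseless limit.

**KO counts.** Per CpG, strand, replicate and condition: mC reads
Binomial(depth, fraction), C reads the remainder, plus a small Poisson
count of other-base reads that must never affect the fraction. Control
fractions default to Uniform(0.25, 0.75); the KO shift is |Δ| = 0.2 with
sign matched to a supplied EWAS effect table for a configurable fraction
of sites.

## Numerical choices and degenerate inputs

- P-values are floored at the smallest positive double rather than 0.
- A perfect per-CpG fit (zero residual variance) raises a degenerate-design
  error instead of reporting se = 0.
- Rank-deficient designs raise a collinearity error naming the dependent
  columns.
- Welch test on two zero-variance groups reports p = 1 when means are
  equal and NaN otherwise; NaN screens fail, so such sites drop out.
- BED input is 0-based half-open on disk and 1-based inclusive internally;
  the conversion is a bijection and round-trips exactly.
- BH-FDR is the exact step-up (min over j ≥ i of m·p(j)/j), capped at 1.

## Problem sizes in the test and acceptance runs

The suite and the acceptance script use desk-scale problems chosen to keep
Monte-Carlo error well inside the asserted tolerances: null calibration on
one 500-sample × 10,000-probe cohort; 200 null replicates of the quadrant
pipeline (40 CpGs, depth 50, 4 replicates); 500 Monte-Carlo repetitions per
θ ∈ {0, 0.3, 0.5} for MR recovery with 5 instruments; and a 2,000-sample ×
1,500-probe cohort for direction-skew recovery. Headline study counts that
depend on the real controlled-access cohorts are exercised as worked
examples on their printed numerators and denominators instead.

## Known limitations

- OLS + cluster-robust SEs approximate, not reproduce, mixed-model
  inference under relatedness.
- Fixed-effects meta only; between-study heterogeneity is reported (Q, I²)
  but never modeled.
- MR assumes uncorrelated instruments after pruning and ignores exposure
  estimation error; no robust estimators (weighted median, MR-PRESSO) are
  provided — invalid-instrument sets are excluded, not rescued.
- The Fisher enrichment universe is user-declared; a mis-specified
  universe biases odds ratios.
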