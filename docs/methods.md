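# Methods

This note documents the statistical models implemented in `mamt`, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Summary-statistic harmonization

Tables are keyed by (chromosome, position, effect allele, other
allele); duplicate keys keep the record with the smaller standard error
(the better-powered measurement).  Harmonization against a reference
orientation handles four cases: exact allele match (kept), swapped
alleles (β sign flipped, EAF complemented), strand-flipped alleles
(complemented then resolved as above), and everything else (dropped and
counted).  A/T and C/G pairs are strand-unresolvable from alleles alone
and are **dropped by default**; `ambiguous_policy="freq"` keeps them
when the allele frequency is decisive relative to the reference
(difference margin 0.2).  Dropping is the safe default for
meta-analysis, where a silently mis-oriented variant corrupts the
pooled effect.

Coordinates are 1-based; exclusion regions are half-open
`[start, end)`, which intentionally diverges from 0-based BED and is
documented on the reader.  The HLA default exclusion is
chr6:25–35 Mb (hg19), configurable, because published analyses rarely
state exact bounds; the extended MHC's outsized, heterogeneous effects
violate the homogeneous-covariance assumption of the multi-trait
combiner and are excluded from that stage only.

## Pairwise diagnostics and fixed-effect pooling

λ_meta compares squared paired effect differences to their sampling
variance: Tᵢ = (bᵢ₁ − bᵢ₂)²/(σᵢ₁² + σᵢ₂²), λ = median(T)/median(χ²₁).
The χ²₁ median is hard-coded as 0.4549364231 (from the quantile
function, not typed from memory at lower precision).  Under
independent homogeneous studies T ~ χ²₁ so λ ≈ 1; shared samples
correlate the errors and shrink the numerator (λ < 1); effect
heterogeneity inflates it (λ > 1).

IVW pooling uses weights 1/se²; Cochran's Q is computed per variant
with df = contributing studies − 1.  Nested-study subtraction inverts
the IVW update exactly (w_R = w_L − w_S), raising when residual weight
is non-positive — the signature of a study that is not actually
nested.  Overlap decorrelation premultiplies the per-variant z vector
by the inverse Cholesky factor of the study-level z correlation
(estimable from null variants); SEs are kept and betas rescaled so
β/se equals the transformed z, which preserves downstream pooling.

Loci are assigned greedily: the most significant unassigned variant
becomes a sentinel and absorbs hits within ±1 Mb (distance mode) or
with r² > 0.2 to it (LD mode).  P-value ties break on (chromosome,
position) for determinism; windows never cross chromosomes.  Sentinel
χ²(1df) p-values are computed with `scipy`'s survival function and a
log-space variant (p = 2Φ(−|z|) through the normal log-survival
function) that stays finite far beyond the |z| ≈ 37.6 underflow of the
linear scale.  A Bonferroni heterogeneity flag at 0.05/(number of loci)
marks sentinels with significant Q.

## Genetic correlation and multi-trait combination

Cross-trait LD-score regression regresses z₁z₂ on √(N₁N₂)·ℓ/M with a
free intercept (which absorbs sample overlap) and 1/ℓ
heteroskedasticity weights, single-step — no iterative reweighting.
rg = ĝcov/√(ĥ₁²ĥ₂²); the standard error comes from a delete-one block
jackknife over 200 contiguous blocks (default).  This deliberately
implements the regression estimator itself rather than reproducing any
external software's option set; the desk-scale simulations in the test
suite (rg = 0.5, h² = 0.3, M = 20 000, N = 50 000) recover rg within
±0.1.

Auxiliary traits enter the multi-trait stage only if their rg p-value
against the target passes Benjamini–Hochberg at FDR 0.05, evaluated on
the best-powered reference ancestry (EUR by default).

The multi-trait combiner works on z-scores.  Σ (sampling covariance,
unit diagonal) is the correlation of z over null-looking variants
(max |z| < 2 across traits by default); Ω (genetic covariance) is the
empirical second moment of z minus Σ, projected to the PSD cone by
eigenvalue clipping — both deterministic moment estimates.  The target
estimate is β̂ₜ = wᵀΛ⁻¹ẑ/(wᵀΛ⁻¹w), w = ωₜ/ω_tt,
Λ = Ω − ωₜωₜᵀ/ω_tt + Σ, with effective SE 1/√(wᵀΛ⁻¹w).  Three exact
properties pin the implementation down: a single trait returns its
input; diagonal Ω with Σ = I borrows nothing; exchangeable traits with
Σ = I give z_out = Σzᵢ/√T.  Exactly duplicated traits make Σ singular;
the estimate is still returned (with a warning) and the combiner
raises only when Λ cannot be inverted.

## Replicability mixture model

Per variant j across K studies, latent R_j ~ Bernoulli(π).  If
R_j = 1, the studies share μ_j ~ N(0, τ²) and β̂_jk ~ N(μ_j, s²_jk);
if R_j = 0, μ_j = 0 and each study is independently an outlier with
probability λ_o, inflating its variance by α > 1.  The replicable
marginal N(0, D + τ²11ᵀ) is evaluated in closed form via
Sherman–Morrison; missing entries simply drop out of the per-variant
product.  EM updates are exact (π from mean PPR; τ² from the posterior
second moment of μ; λ_o and α from outlier posteriors) so the
log-likelihood is non-decreasing — asserted in tests.  Because the
likelihood is multimodal, five restarts with seeded jitter around the
default initialization (π = 0.1, τ² = 90th percentile of
max(β̂² − s², 0), λ_o = 0.01, α = 5) are run and the best kept.
Convergence: relative log-likelihood change < 1e-6, max 2000
iterations.

Ancestry adjustment regresses the per-variant study effects on
[1, ancestry PC scores] by WLS (weights 1/se²) and feeds the residuals
to the mixture.  PCs come from the column-centered study×variant
allele-frequency matrix with a deterministic sign convention
(largest-magnitude loading positive); the default is
m = min(2, studies − 2).  Residual variances are passed through
unchanged — the regression degrees of freedom are not charged to them —
a simplification that slightly overstates residual noise when study
counts are small.

PPR > 0.90 (strict) is the replicability call.  Note that PPR is *not*
globally monotone in signal scale: multiplying an inconsistent
variant's effects by c > 1 can strengthen the outlier explanation
faster than the shared-effect one.  Monotonicity holds, and is tested,
for consistent signals (equal z across studies).

## Cell-type enrichment

Expression is TPM-rescaled so each cell type sums to 10⁶ after removing
genes unexpressed everywhere; specificity is the row-normalized share,
and each cell type's specific set is its top ⌈0.05·G⌉ genes with ties
broken by (score descending, gene id ascending) — exact set sizes,
fully deterministic.

The enrichment regression is GLS of Y = squared TWAS Z-scores on the
indicator matrix X: γ̂ = (XᵀP⁻¹X)⁻¹XᵀP⁻¹Y, Var(γ̂) = σ̂²(XᵀP⁻¹X)⁻¹
with σ̂² from the P-weighted residuals on G − rank(X) df, and
per-coefficient two-sided t-tests at 0.05.  Design choices: an
intercept column is included, so γ_c measures excess mean Z² over
baseline (without one, every coefficient absorbs the genome-wide mean
and the test answers a different question); P is shrunk as
(1 − δ)P + δI with δ = 0.05 before inversion because finite bootstrap
estimates of P need not be positive definite; genes absent from the
expression reference get all-zero rows (baseline only).  With P = I
the fit reduces to OLS exactly (tested).

For the correlation of squared statistics, the bivariate-normal closed
form Corr(Z₁², Z₂²) = ρ² is the default fast path; a seeded Monte-Carlo
sampler (correlation of squared draws over B ≥ 1000 pairs) verifies it.
A third mode averaging products of the *unsquared* draws is retained
for comparison only — that average estimates ρ itself, not the
squared-statistic correlation, and is not used.

TWAS post-processing filters genes at p < 2.5×10⁻⁶ (Bonferroni for
~20 000 genes) and builds loci iteratively: most significant remaining
gene defines gene body ± 1 Mb, overlapping significant genes join,
repeat.  A locus is novel iff its window contains no known GWAS
sentinel.

## PRS construction and evaluation

Cohort QC applies, in order: variant missingness > 1%, individual
missingness > 1%, MAF < 5%, HWE χ²(1df) p < 1e-6 on hard calls,
heterozygosity outliers (inbreeding coefficient beyond ±3 SD — the
conventional reading of "high or low heterozygosity"), and greedy
relatedness pruning at genomic relationship > 0.125 (the member with
more missingness is dropped).  Note the GRM estimate has sampling SD
≈ 1/√M, so relatedness pruning at 0.125 needs on the order of
thousands of variants to be meaningful.

Clumping is greedy with PLINK-equivalent defaults (p1 = p2 = 1,
r² = 0.1, 250 kb); absent LD pairs count as r² = 0 with a warning.
Thirteen p-value thresholds (5e-8 … 1) produce nested weight sets.
Scores are additive in dosage; missing dosages impute as 2·EAF.

EHR case definitions: Def1 ≥ 1 SLE ICD count; Def6 ≥ 2 counts and no
systemic sclerosis/dermatomyositis codes; Def12 ≥ 4 counts, an ANA
titer ≥ 1:160, and no exclusion codes (missing ANA ⇒ control,
counted).  Lab binarization: ANA positive at titer ≥ 1:80; anti-dsDNA
positive at ≥ 60 IU/mL or positive status; unparseable values are
missing and excluded from stratified analyses.

Evaluation: logistic regression via `statsmodels` (Newton, tol 1e-8)
with Nagelkerke R²; the liability transformation uses the
case-control ascertainment-corrected form — with t = Φ⁻¹(1−K),
z = φ(t), m = z/K, C = K²(1−K)²/(z²P(1−P)),
θ = m(P−K)/(1−K)·(m(P−K)/(1−K) − t):
R²_liab = C·R²/(1 + C·θ·R²), which reduces to the plain K(1−K)/z²
rescaling at P = K.  The **observed-scale (linear) R²** is what this
transformation is derived for and what the recovery test feeds it;
Nagelkerke R² is reported alongside, untransformed, because pushing a
likelihood-ratio pseudo-R² through a linear-scale transformation has
no such guarantee.  AUC is the Mann–Whitney statistic (ties half);
DeLong's test uses structural components over cases and controls, with
the one-sided alternative "the PRS-augmented model has greater AUC";
identical score vectors return p = 1 by convention.  Bootstrap CIs are
percentile with 1000 seeded replicates.  Quintiles are cut on the
analysis sample with ties broken by individual id; odds ratios against
the bottom quintile carry Woolf CIs with the Haldane–Anscombe 0.5
correction (flagged) on zero cells; "middle quintile" means the third.
Youden's point maximizes sensitivity + specificity − 1, lowest
threshold on ties.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); one master
seed fans out to named substreams so adding a generator never perturbs
existing draws, and reruns are bit-identical.

- **LD** is block-diagonal AR(1) (D_ij = ρ^|i−j|), with LD scores
  ℓ_j = Σᵢ D²_ij.  Real LD is neither stationary nor block-diagonal;
  the panel exists to give clumping, LD-aware loci, and LD-score
  regression non-trivial structure, not to mimic a genome map.
- **Summary statistics** combine sparse causal effects (shared across
  ancestries, correlated across traits), a polygenic background whose
  z-variance tracks N·ℓ·h²/M (so LDSC-style regressions are
  well-posed), Balding–Nichols allele-frequency drift between
  ancestries (default F_ST 0.1 — enough for ancestry PCs to carry real
  signal), optional study-overlap noise correlation, and optional
  single-study spurious effects.  Effect estimates are drawn at the
  asymptotic normal approximation; there is no genotype-level sampling,
  no imputation error, and no confounding stratification in the effects
  themselves.
- **Replicability datasets** draw directly from the mixture model with
  per-study SEs uniform on 0.001–0.004 — the precision of per-study
  effects at biobank-scale effective sample sizes, which is the regime
  where variants entering a replicability screen live and where the
  mixture's components are well separated (mean PPR of replicable
  variants > 0.9).  With noisier effects the components blur and PPR
  for weak true effects is intrinsically intermediate — a property of
  the model, not a failure of the fit.
- **Cohorts** follow a liability-threshold model: a standardized
  genotype score explains a set fraction of unit liability; cases
  exceed Φ⁻¹(1−K).  Ascertained designs accumulate cases chunk-wise so
  memory stays flat at rare K.  ANA/anti-dsDNA are generated at stated
  sensitivity/specificity against true case status, ICD counts from
  case-dependent Poisson rates.  Real labs and EHR codes are
  correlated with severity and with each other in ways this does not
  model.

Passing tests on these generators therefore demonstrates correctness
of the estimators under their own assumptions and calibrated behaviour
under clean nulls — not robustness to real-data pathologies
(stratification, cryptic relatedness across cohorts, imputation
artefacts, phenotyping noise beyond the modelled error rates).

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
each check is statistically decisive yet the whole battery completes in
a few minutes on one CPU: 10⁵ variants for median-based calibration
(λ sampling SD ≈ 0.005), 5000 variants × 8 studies for mixture
recovery, 2000 replicates for enrichment type-I error (binomial SE
≈ 0.005), 100 random instances for clumping-oracle equivalence, and a
50 000-sample ascertained cohort for liability-R² recovery
(tolerance ±0.03 ≈ 3 empirical SDs).

## Known limitations

- The LDSC implementation is single-step weighted; it matches the
  estimator, not the reference software's iterative weighting or its
  standard errors in edge regimes (tiny h², very short panels).
- The multi-trait combiner assumes one shared Ω across variants
  (homogeneous-covariance); the HLA exclusion exists precisely because
  that assumption fails there.  No maxFDR-style diagnostic is
  provided.
- Ancestry adjustment does not propagate regression uncertainty into
  the residual variances.
- `decorrelate_overlap` requires the overlap correlation as input; it
  does not estimate it from null variants itself.
- EHR phenotyping takes the ICD code list as configuration; no code
  list ships with the package.
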