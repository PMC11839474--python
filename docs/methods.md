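# Methods

This note documents the statistical models implemented in `mirqtl`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Expression QC

**Abundance filter.** Features are kept when RPM ≥ 1 in ≥ 50% of samples,
both thresholds inclusive. The threshold is deliberately liberal: bulk
tissue dilutes cell-type-restricted miRNAs, and a stricter cut would
discard genuinely expressed species.

**Multi-precursor dedup.** A mature miRNA quantified against several
precursors keeps the row with the largest total count; ties go to the
lexicographically smallest precursor id (logged), so the result is
deterministic.

**Normalization.** TMM scale factors with the standard trims (30% on M,
5% on A; reference = sample whose 75th count percentile is closest to the
mean). We use the *unweighted* trimmed mean of M-values rather than the
precision-weighted variant: the weights depend on library size, which
breaks the exact invariance of a sample's normalized values under uniform
rescaling of its counts, a property we consider part of the normalization
contract. Factors agree with `edgeR::calcNormFactors(..., doWeighting =
FALSE)` to < 1e-6 (cross-checked in the test suite via Rscript). The log
transform is log2(CPM + 0.5), i.e. a prior of 0.5 on the CPM scale, again
for exact scale invariance; at typical miRNA abundances (CPM ≫ 1) this is
indistinguishable from a prior-count formulation.

**Outlier removal.** Batch-metric mode drops samples > 5 SD from their
batch mean on any metric, iterating to stability, and refuses to shrink a
batch below 3 samples. PCA mode drops samples > 4 SD from the mean of
either of the first two expression PCs in a single pass (an
iterate-until-stable flag exists for proteomic-style matrices), then
recomputes PCs once for reporting. Whether PCs should be recomputed after
removal is genuinely open; we report post-removal PCs but do not re-screen
on them by default.

**Surrogate variables.** Known covariates are regressed out and the SVs
are the top left singular vectors of the residual matrix, scaled to unit
variance. This "PCA on residuals" is deterministic and orthogonal to the
known-covariate space by construction; since the original SV call is made
with a randomly generated variable of interest, it behaves as an
unsupervised factor estimate, which residual SVD matches. Default n_sv =
15, as in the study design this emulates.

## cis-QTL scan

Windows are the union of per-precursor intervals padded ±500 kb, merged,
so a SNP in the shared padding of two precursors of one miRNA is tested
once. The scan is OLS of normalized expression on dosage plus covariates;
by Frisch–Waugh–Lovell both sides are residualized on the covariates once
and per-SNP statistics follow from the simple regression, with exact
two-sided t tests on n − p − 1 degrees of freedom (not the normal
approximation). Covariate columns are dropped for exact collinearity (QR
with pivoting) and for variance inflation beyond a configurable bound
(default VIF ≤ 500, mirroring the platform/genetic-PC multicollinearity
the design tolerates); drops are warned in order.

**Storey q-values.** π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95 is
smoothed with a least-squares natural cubic spline (interior knots at the
λ tertiles, ~3 effective df) and evaluated at λ = 0.95, clipped to
(1/m, 1]. q-values are the usual running minimum of π0·m·p(j)/j. Below
100 p-values the π0 estimate is too unstable, so π0 = 1 (plain BH) with a
warning.

**Variance explained.** Expression is first residualized on non-genetic
covariates and SVs; the reported fraction is Var(β̂·dosage)/Var(outcome)
from a fit on SNP + genetic PCs.

## LD operations

r² is the squared Pearson correlation of dosage vectors (composite LD, no
phasing). Clumping greedily takes the smallest-p remaining SNP as index
and absorbs SNPs with r² ≥ 0.5 AND distance ≤ 250 kb (the PLINK semantics
of the cited option pair; the equivalent retention phrasing is an OR);
ties on p break to the smaller position. Conditional analysis re-tests
index SNPs with the growing independent set as covariates, adds the
best-ranked significant one per round, and stops when at most one remains
significant; the significance threshold defaults to the same unadjusted-p
cutoff that defined the q < 0.01 set for the run. Only index SNPs are
re-tested, not clump members.

## Colocalization

Wakefield log-ABF per SNP: lABF = ½log(1−r) + z²r/2 with r = W/(V+W),
prior effect SD √W = 0.15 phenotype-SD units for quantitative traits and
0.2 on the log-odds scale for case-control GWAS. Hypothesis sums run in
log space (log-sum-exp); H3 uses the identity ΣᵢΣⱼ≠ᵢ = S₁S₂ − S₁₂
computed as a stable log-difference, clamped at zero mass with a warning
if cancellation goes negative (and exactly zero for a 1-SNP locus).
Priors p1 = p2 = 1e-4, p12 = 1e-5 (the field's standard defaults). The
vectorized implementation is tested against brute-force enumeration of
all causal-SNP configurations at 1e-10. Multiple-causal-variant (credible
set) hybrids are out of scope; this is the single-variant branch used
when no credible sets are found.

## SMR and HEIDI

SMR at the exposure's top SNP: b̂ₓᵧ = b̂ᵤᵧ/b̂ᵤₓ, T = z₁²z₂²/(z₁²+z₂²)
referred to χ²(1), delta-method SE. The top SNP must pass an instrument
threshold (default p < 5e-8, relaxable to the run's cis-significance
threshold since SMR is applied to already-significant loci).

HEIDI selects up to 20 SNPs with exposure p < 1.57e-3 and r² with the top
SNP in [0.05, 0.9] (the published defaults of the method), forms
dᵢ = b̂ₓᵧ(i) − b̂ₓᵧ(top), and computes the covariance of d by the delta
method treating the exposure and outcome studies as independent. The
statistic Σ(dᵢ/sd(dᵢ))² is a correlated chi-square sum; its p-value uses
a two-moment (Satterthwaite) match on the eigenvalues of the correlation
matrix of d. This approximation is mildly anticonservative in the far
tail but adequate at the 0.05 decision boundary: measured type-I error
under single-shared-causal simulations with strong instruments (top
exposure z ≈ 11) is ≈ 0.04–0.08 over 300 replicates. Weak instruments
inflate it further — a known property of the test, which is why the
instrument gate matters. Fewer than 3 eligible SNPs yields a missing
HEIDI p with a reason code, and a missing HEIDI p can never support a
mediation verdict.

## miRWAS

**Heritability gate.** Single-variance-component REML on the cis GRM
(standardized dosages), optimized on h² ∈ [0, 1) in the eigenbasis of the
centered kernel with σ² profiled out; the LRT against h² = 0 uses the
½χ²(0) + ½χ²(1) boundary mixture. miRNAs pass at p < 0.01.

**Weight models.** top1 (marginal beta of the most significant cis SNP),
lasso and elastic net (mixing 0.5) on standardized dosages, penalty
chosen on a 20-point geometric grid from the null-penalty down by 1e-3,
scored by 5-fold out-of-fold R²; the model with the best cv R² wins, ties
to top1. No model with positive cv R² excludes the miRNA. blup/bslmm are
deliberately omitted: the tested mechanism is the selection rule, not the
menu breadth, and both require machinery (REML BLUP solvers / MCMC) out
of proportion to their contribution here.

**Association.** z = wᵀz_GWAS/√(wᵀRw) with R from the same panel used for
training (a single-panel stand-in for an external LD reference,
configurable); non-positive quadratic forms are ridge-repaired (+1e-3)
with a warning. FDR across miRNAs per trait is Benjamini–Hochberg.

**Causal screen.** A (miRNA, trait) pair is flagged causal iff
FDR < 0.05 ∧ PP.H4 > 0.5 ∧ SMR p < 0.05 ∧ HEIDI p ≥ 0.05, strict
inequalities as written; any missing component fails with a reason code.

## Enrichment, sharing, positions

CMH common OR over MAF strata (0–0.1), [0.1–0.2), [0.2–0.5] via the
Mantel–Haenszel estimator with Robins–Breslow–Greenland CIs and the CMH
chi-squared without continuity correction (statsmodels `StratifiedTable`
underneath); complete separation returns a +∞ sentinel with a warning.
Cross-study sharing reconstructs the 2×2 eMiR table (shared / a-only /
b-only / neither) and applies the chi-squared test *with* Yates
correction — the corrected statistics reproduce both published values
(4.33 → "4.3", 9.05 → "9.1") where the uncorrected ones (5.0, 9.7) do
not. π₁ = 1 − π0 on the replication p-values of discovery top hits,
requiring ≥ 50 values. Positional statistics classify index QTLs as
within / upstream / downstream / ambiguous in the miRNA gene's
transcriptional orientation (a genomic-left flag exists), use the exact
two-sided binomial (minimum-likelihood rule; the exact test reproduces
the published 1.32e-10 where a normal approximation does not), and
Spearman with average ranks for |TSS distance| vs p.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes,
at the study's scale where that scale matters (n = 604 donors; hundreds
of miRNAs; 15 SVs):

- **Genotypes** — haplotypes in LD blocks via a shared-uniform copula:
  each haplotype copies a block-level uniform with probability √r and
  draws fresh otherwise, so two block-mates have haplotypic correlation
  ≈ r on the binary scale directly (a thresholded-Gaussian latent r would
  understate binary correlation through the tetrachoric gap and miss the
  intended LD strength). Block frequencies are jittered ±0.02 so LD stays
  near-target while the MAF spectrum varies. Dosage = two independent
  haplotypes. Not emulated: coalescent-accurate LD decay, recombination
  hotspots, population structure or relatedness.
- **Counts** — log2-CPM mean = baseline + Σβ·dosage + batch offsets
  (SD 0.3) + 3 hidden factors (loading SD 0.3, a stand-in for cell-type
  composition) + N(0, 0.5²); counts drawn negative-binomial with
  Var = μ + μ²·φ (default φ = 0.05; pipeline studies use 0.01) at
  library sizes 3–6 M. A planted variance fraction is defined against
  the variance the scan actually sees — log-scale noise plus the
  expected counting noise — because covariates and SVs absorb batch and
  factor structure; β is solved from that target, so realized fractions
  center on the plant. Not emulated: isomiR structure, mapping artifacts,
  GC or length bias.
- **GWAS** — z ~ N(Rλ, R) with non-centrality λ = b·√(2f(1−f)·n_GWAS) at
  the causal SNP; the mediated scenario sets b = β_QTL·β_mediation at the
  miRNA's causal SNP (signs propagate), linkage places the trait's causal
  variant on a distinct correlated SNP, pleiotropy re-uses the SNP with
  an independent effect. Not emulated: sample overlap between studies,
  polygenic background outside the locus.
- **Annotations** — per-SNP interval membership with a stratum-constant
  odds ratio against a MAF-stratified base rate; intervals are single-base
  so membership is exact.

Passing tests on these data demonstrate that the estimators recover what
was planted under the assumed model — they do not certify performance on
real small-RNA data, where LD, expression structure and confounding are
richer than the generator's.

## Problem sizes in the shipped tests and acceptance script

Replicate-level suites use desk-scale loci chosen to exercise the logic,
not the full genome: 60-SNP panels (10-SNP blocks, r = 0.8) for the
end-to-end screen (100 replicates per scenario), 30-SNP equicorrelated
loci for HEIDI calibration (300 replicates), 400 features × 4,000 SNPs
for the power/FDR study (200 planted pairs at 4% variance, n = 604), and
100k independent SNPs for the enrichment recovery. The planted-4% band
check deserves a caveat: at n = 604 the sampling SD of an estimated R²
around 0.04 is ≈ 0.015, so ~18% of single-locus estimates fall outside
[0.02, 0.06] for *any* unbiased estimator; the suite therefore asserts
the median inside the band plus a coverage floor consistent with that
noise, rather than an unattainable per-replicate guarantee.

## Known limitations

- Single-causal-variant coloc only; loci with multiple causal variants
  dilute PP.H4.
- HEIDI's Satterthwaite tail and delta-method covariance are
  approximations; borderline p ≈ 0.05 verdicts should not be
  over-interpreted.
- The LD reference for miRWAS defaults to the training panel; external
  reference panels are supported only by supplying a different panel.
- The conditional-analysis significance threshold is a configuration
  choice (default: the run's cis-significance cutoff); the source design
  leaves it unstated.
- rsID-keyed and position-keyed matching are both supported for
  cross-study lookups, but no precedence rule is applied when the two
  keys disagree; callers choose one.
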