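# Methods

This note documents the statistical models, the simulator, the numerical
choices, and the limits of what the test suite demonstrates.

## The animal model

All evaluation components share the single-trait animal model

    y = Xb + Zu + e,   u ~ N(0, K sigma_a2),   e ~ N(0, I sigma_e2)

where `y` are trait records, `b` fixed effects (sex, measurement-date batch,
age as a covariate, plus an intercept), and `u` additive genetic values with
covariance proportional to a relationship matrix `K`. `K` may be the
pedigree numerator relationship matrix **A**, the marker-based **G**, or the
single-step hybrid **H**; heritability is h² = σ²ₐ/(σ²ₐ+σ²ₑ).

For a 0/1 trait the package also reports the observed-scale heritability
σ²ₐ/(Φ(1−Φ)) with Φ the incidence. This quantity is only meaningful when
σ²ₐ was estimated on the same 0/1 scale; if a liability-scale variance is
plugged in the ratio can exceed 1, and the function warns rather than
truncating. (A published component table for a coat-length trait is
internally consistent with the continuous ratio but not with the
observed-scale formula at its stated incidence; both computations are
available so users can see the discrepancy themselves.) The
logistic-GLMM treatment of binary traits is deliberately out of scope: the
binary trait is fitted as a linear model on the 0/1 scale.

## Relationship matrices

* **A** is built by the tabular method; inbreeding coefficients are computed
  independently by the Meuwissen–Luo ancestor-traversal algorithm and the
  two diagonals are cross-checked at 1e-10 on every build.
* **A⁻¹** uses Henderson's sparse rules with Mendelian-sampling variances
  dᵢ = ½ − ¼(F_s + F_d) (¾ − ¼F for one known parent, 1 for founders).
* **G** (VanRaden method 1) centers dosages by twice the observed allele
  frequency of the counted minor allele and scales by 2Σpᵢ(1−pᵢ).
  Frequencies come from the genotyped set itself; no base-population
  frequencies are assumed (none are generally available in a conservation
  program), and an override is possible by passing a pre-built matrix.
* **G_centered** is the column-centered cross-product divided by the SNP
  count — the kinship standardization used by mixed-model association
  software; its rows sum to zero.
* **H⁻¹** follows the standard single-step construction with blend weights
  0.95/0.05 (parameters `tau_g`, `tau_a`). No additional rescaling of G to
  A₂₂ is applied beyond the blend — users of preGSf90-style pipelines should
  note its optional tuning steps are not replicated. A fixed ridge of 1e-8
  is added to G's diagonal before any inversion inside the blend and is
  recorded in the result metadata.

Everything is dense: the target scale (≤ a few thousand animals) makes
sparse mixed-model machinery unnecessary, and dense code is directly
checkable against brute-force oracles (the suite compares A to a recursive
reference implementation, A⁻¹ to dense inversion, and H⁻¹ to the inverse of
an explicitly assembled joint H).

## REML

With a single random effect the restricted likelihood is profiled to one
dimension: eigendecompose `K` restricted to phenotyped animals once, rotate
`y` and `X`, and the covariance becomes diagonal in the variance ratio
γ = σ²ₐ/σ²ₑ. The ratio is optimized on log γ ∈ [−12, 12] by a 49-point grid
followed by bounded Brent refinement (xatol 1e-10); σ²ₑ then has a closed
form. This is exact for this model class and cannot diverge, unlike general
AI-REML iterations; the grid-then-refine search makes the optimum global up
to grid resolution (verified against a dense 100×100 component grid in the
tests). Fits with the ratio pinned at a search bound, or ĥ² within 1e-6 of
0 or 1, are flagged `boundary`.

The standard error of ĥ² is obtained from the curvature of the profiled
restricted log-likelihood at the optimum (a central difference in h²),
which coincides asymptotically with the average-information SE; boundary
fits report NaN.

Identifiability guard: if the eigenvalue spread of `K` on the phenotyped
subset is below 1e-8 the model cannot separate σ²ₐ from σ²ₑ and the fit is
refused rather than returning an arbitrary split.

## Prediction and cross-validation

Adjusted phenotypes y_c are OLS residuals of y on the fixed-effect design
(y_c = y − X(X′X)⁻¹X′y); the prediction model then fits only an overall
mean, so fixed effects never re-enter. The four methods differ only in the
relationship inverse entering Henderson's equations: A⁻¹ over all animals
(PBLUP), A₂₂⁻¹ (PBLUP-G) or G⁻¹ (GBLUP) over genotyped animals, and H⁻¹
(ssGBLUP) over all animals. G and A₂₂ receive a 1e-8 ridge before dense
inversion. Every solve asserts a relative MME residual below 1e-8.

Cross-validation partitions the phenotyped in-scope animals into five
seeded folds; each fold's phenotypes are masked (the animals stay in the
relationship structure) and its accuracy is Pearson's r between adjusted
phenotype and EBV divided by √h², so the five accuracies exist for the
empirical SE = sd/√5. The h² in the denominator is the full-data REML
estimate by default (a training-only estimate can be supplied). Accuracy is
computed within folds; a pooled variant is available as a flag. "Repeated"
fivefold is interpreted as each fold serving once as validation, with an
`n_repeats` option for independent repartitions.

For *cross-method* comparisons the package evaluates all methods on a
common validation scope (the genotyped-and-phenotyped animals, via
`subset_ids`): methods whose scopes differ (ssGBLUP sees all phenotypes,
GBLUP only genotyped ones) are otherwise not comparable fold-for-fold.

## GWAS

Per SNP the model adds a dosage covariate to the fixed effects and uses the
centered GRM as `K`. The kinship is eigendecomposed once and all SNP columns
are rotated in one matrix product; the variance ratio is re-optimized by
REML for every SNP (`per_snp`, the exact treatment) or taken from the
covariate-only null model (`null_once`, EMMAX-style — faster, with slightly
different p-values; the two agree closely in the tests). The reported
statistic is the Wald χ²₁ = (β̂/se)². Monomorphic SNPs are skipped with a
logged reason; missing dosages are mean-imputed for the regression while
MAF is reported pre-imputation. No leave-one-chromosome-out correction is
applied — the single-GRM usage matches the evaluation pipeline this package
mirrors, and proximal contamination is a known consequence.

λ_gc divides the median back-converted χ² by 0.4549. Thresholds are α/N
(genome-wide) and 1/N (suggestive); a lenient −log₁₀p cutoff (default 4) is
carried as a parameter because underpowered traits are commonly reported at
that level.

## The simulator

`simpop` emulates a small closed breeding program:

* **Pedigree** — founders with alternating sexes; each generation draws
  sires and dams uniformly from all earlier generations and produces full-sib
  litters (`offspring_per_mating`). Defaults: 28 founders + 5 generations ×
  35 matings × 2 pups = 378 animals, the phenotyped-cohort size of the
  motivating setting; deeper/larger pedigrees are plain config changes.
* **Genotypes** — gene dropping: founder haplotypes Bernoulli at per-SNP
  frequencies uniform in (0.05, 0.5]; one recombinant gamete per parent with
  Poisson crossovers (1 Morgan/chromosome by default, configurable);
  38 autosomes of 60 Mb. The youngest `genotyped_fraction` (default 0.62,
  ≈ 234/378) carry the released panel, with missingness at 2%; the complete
  matrix is available as ground truth.
* **Breeding values** — recursive parent-average plus Mendelian-sampling
  deviation with variance ½(1 − (F_s+F_d)/2)·σ²ₐ(polygenic), so A-matrix
  expectations hold exactly; optionally a fraction of σ²ₐ is carried by QTL
  sampled from the simulated markers, with effects scaled to the target
  variance at founder allele frequencies.
* **Phenotypes** — intercept + sex effect + Normal date-batch effects
  (5 batches) + age slope (age uniform 1–10 y) + u + Normal residual.
  Default components σ²ₐ = 4.430, σ²ₑ = 5.323 (a body-height-like scale,
  h² ≈ 0.45).
* **Binary trait** — the continuous liability thresholded at its empirical
  (1 − incidence) quantile (default incidence 0.593), matching the target
  count to within one animal without Normality assumptions.

A deliberate consequence of the exact polygenic construction: with no QTL,
marker genotypes are independent of breeding values given the pedigree, so
genomic methods cannot beat pedigree methods on such data. Tests that make
claims about genomic-prediction ordering (ssGBLUP ≥ GBLUP ≥ PBLUP-G)
therefore simulate a marker-determined trait (`n_qtl` large,
`qtl_variance_fraction = 1`); tests of REML recovery and A-matrix algebra
use the pure polygenic architecture where A is exactly right.

What passing tests do **not** show about real data: the simulator has no
selection, non-random mating, population structure, genotyping batch
effects, allele-frequency drift between reference panels, or realistic
linkage-disequilibrium decay (LD comes only from a 1 Morgan map at desk-scale
marker densities). Calibration results (type-I error, λ_gc) are statements
about correctly specified models on data generated by this process.

## Problem sizes and numerical defaults

The default suite runs populations of a few hundred animals and panels of
1.5–2.5 thousand SNPs; replicate counts are 10–20 for parameter-recovery and
ordering experiments and 2,000 SNPs for calibration checks — sizes chosen so
the whole suite completes in well under a minute of CPU per heavy test while
keeping Monte-Carlo error a small fraction of the tested tolerances.
Key tolerances: MME residual 1e-8; A diagonal cross-check 1e-10; REML ratio
search xatol 1e-10 on the log scale; G/A₂₂ inversion ridge 1e-8; HWE exact
test compared to an independent enumeration oracle at rel. 1e-9.

## Known limitations

* No metafounders, unknown-parent groups, or APY-style sparse inverses.
* No multi-trait models, maternal or permanent-environment effects.
* Binary traits are linear-model-on-0/1 only (no threshold/logit GLMM).
* Beagle-style haplotype imputation is replaced by mean-dosage imputation,
  which preserves allele frequencies but not LD.
* PLINK dialect only (no VCF/PGEN); gene annotation requires a user table.
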