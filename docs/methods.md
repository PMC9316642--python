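# Methods

## The two-stage trajectory heritability model

Each subject's repeat-measured trait is assumed linear in age over the
observation window,

    y_ij = beta0_i + beta1_i (age_ij - abar_i) + eps_ij,
    eps_ij ~ N(0, sigma_i^2 / w_j),

where `abar_i` is the subject's mean observed age, `beta0_i` the level at
`abar_i`, `beta1_i` the annual change rate, and `w_j` a visit-specific
weight. Centring at `abar_i` makes the two estimates orthogonal under equal
weights, so `beta0` is a subject mean rather than a baseline value — over a
14-year window the mean is the better-determined summary, and the model
deliberately targets it.

**Visit weights.** Repeat-measured physiological traits are heteroscedastic
across visits (instrument drift, protocol changes, ageing of the sample), so
each visit's residual variance is estimated by OLS of the trait on age, sex
and height among subjects observed at that visit, with the unbiased divisor
`n_j - p - 1`, and its inverse is the weight. All observations contribute to
weight estimation, including subjects later excluded by the minimum-visit
filter: the weight is a property of the visit, not of the analysis sample,
and more observations stabilise it. A visit with fewer complete observations
than regression parameters + 2 is excluded with a warning; an exactly zero
residual variance (constant trait) is degenerate and raises. For ratio
traits the height adjustment is debatable; the pipeline applies the same
covariates to every trait by default and exposes `weight_covariates` to drop
any of them.

**Subject filter.** Subjects need at least 3 observed visits (two parameters
plus one residual degree of freedom); subjects whose observed ages are all
equal have a singular design and are dropped with a warning.

**Inverse normal transform.** Estimated `beta0` and `beta1` are separately
mapped to normal scores: rank r of n (average ranks for ties) goes to
`Phi^-1((r - 3/8) / (n + 1/4))`. The Blom offset 3/8 is the community
default for GRM-based heritability analyses. The transform is applied to
each variable independently, and *within* the analysed sample — after
subgroup splitting — because ranks are only meaningful relative to the
sample actually fitted.

## Genetic relationship matrix

The GRM is the allele-frequency-standardised estimator of realized
relatedness: for samples j ≠ k,

    A_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

and on the diagonal the variance-corrected form
`1 + (1/M_j) * sum_i (x^2 - (1 + 2p) x + 2 p^2) / (2p(1-p))`. Allele
frequencies are estimated in-sample from non-missing dosages. Missing
genotypes are excluded pairwise with per-pair SNP counts `M_jk` recorded
(mean imputation is available as a speed switch and slightly shrinks
affected pairs toward zero). Two consequences of these choices that tests
rely on:

- in-sample centring forces the mean off-diagonal to exactly −1/(n−1) for
  any sample, not 0;
- the diagonal replacement means A is not guaranteed positive semidefinite;
  all REML code therefore verifies positive definiteness of V = Σθ_k A_k
  through its Cholesky factorisation and treats failures as infeasible
  steps.

QC before the GRM is a configurable MAF / missing-rate filter (defaults
0.01 / 0.05); Hardy–Weinberg filtering is not applied by default. Principal
components are eigenvectors of the GRM itself scaled by the square root of
their eigenvalues, with the sign convention that each component's
largest-magnitude loading is positive.

## REML variance components

All three models are maximised by the same dense engine: V = Σ_k θ_k A_k,
average-information Newton steps

    AI_kl = 1/2 y'P A_k P A_l P y,    score_k = 1/2 (y'P A_k P y - tr(P A_k)),

with step-halving (up to 30 halvings) whenever a proposed step leaves the
feasible region (Cholesky failure) or decreases the restricted likelihood,
and an EM-flavoured fallback step when no fraction of the AI direction
ascends. Accepted iterations therefore never decrease logL. Convergence
requires |ΔlogL| < tol AND max relative parameter change < 10·tol
(default tol 1e-6, max 100 iterations); non-convergence is flagged on the
result and warned, never silent.

Constraints: variance components are floored at 1e-8 × phenotypic variance;
covariance components are clipped inside the positive-semidefinite cone of
their 2×2 block (|σ01| ≤ 0.999·√(σ0²σ1²)). The bivariate model is
parameterised in covariances, not correlations, so the likelihood stays
smooth as ρ → ±1; ρ_g and ρ_e are derived afterwards.

Initialisation: univariate and G×E fits split the phenotypic variance
equally across components; the bivariate fit starts from halved phenotypic
(co)variances. Fixed effects default to intercept, sex, mean age and mean
height; principal components are *not* in the REML design by default (they
are GWAS covariates) but `pcs_in_reml` adds them.

**Tests and standard errors.** A variance component null (σ_g² = 0,
σ_gxe² = 0) lies on the boundary of the parameter space, so its LRT p-value
is the 50:50 mixture `0.5 P(χ²₁ > Λ)` (p = 1 at Λ = 0). The genetic
covariance is interior, so ρ_g = 0 is tested by plain χ²₁ against the
constrained refit with σ_g01 dropped. SEs of h², ρ_g, ρ_e and h²_GxS come
from the inverse AI matrix by the first-order delta method; both Λ and the
SE are reported so Wald-style checks are possible too. A near-singular AI
matrix (condition number > 1e10 — e.g. A = I, where σ_g² and σ_e² are not
separately identifiable) sets `ai_singular` and NaN SEs rather than
fabricating precision.

**G×E model.** K equals the GRM within exposure groups and zero across
(diagonal kept), so σ_gxe² is the variance of a genetic effect that is
drawn independently per exposure group. The exposure main effect must be a
fixed effect; samples with missing exposure are dropped; a constant
exposure makes K = A and raises.

**Derived quantities.** From the bivariate fit: genetic covariance
`sqrt(σ_g0² σ_g1²) ρ_g` and the conditional change-rate variance
`σ_g1² (1 − ρ_g²)` — the genetic variance in the slope left when the
genetic effect on the level is held fixed.

## GWAS

Per-SNP OLS of the transformed trajectory parameter on dosage with
covariates (sex, mean age, mean height, PC1–PC10 by default). Covariates
are projected out once via QR and each SNP is tested in the residual space
(Frisch–Waugh), which is algebraically identical to the full per-SNP fit;
the per-SNP t test uses n − p − 1 degrees of freedom. Missing dosages are
mean-imputed per SNP by default (`complete_case` refits affected SNPs on
observed rows). Monomorphic SNPs yield NaN-statistics rows; a SNP collinear
with the covariates raises. "Age" in the GWAS design is the stage-1 mean
age, consistent with the heritability covariates. λ_GC is the median
association χ² over the exact χ²₁ median (0.4549364…). FDR is
Benjamini–Hochberg. Clumping is the standard greedy rule: smallest-p
unassigned SNP below 5×10⁻⁸ becomes an index, absorbing unassigned SNPs
within 250 kb with dosage r² ≥ 0.1 (both configurable); the procedure is a
community convention, deliberately simple.

## Synthetic cohort generator

`simdata` draws unlinked biallelic SNPs in Hardy–Weinberg proportions with
frequencies uniform on `maf_range`, then builds trajectory parameters with
unit variances:

- per-SNP effect pairs on (level, slope) are bivariate normal with
  correlation `rho_g`, scaled by the *generating* frequencies so the
  polygenic values have variances exactly `h0_sq` and `h1_sq` in
  expectation;
- residual subject effects fill the remainder with correlation `rho_e`;
- the SNP-by-smoking interaction is an independent polygenic slope
  deviation per smoking group (variance `gxe_var_frac` in each group,
  independent draws across groups). This is precisely the covariance
  structure the K-matrix estimator models — σ_gxe²·A within groups, zero
  across — and it recovers unbiasedly; a construction that adds the
  deviation only to ever-smokers leaves half the within-group pairs without
  interaction covariance and biases the estimate downward by roughly a
  third;
- smoking is assigned independently of genotype (`smoker_frac` ever,
  optional missing-status fraction);
- observed values add per-visit Gaussian noise and independent per-visit
  dropout; ages start uniformly in 40–69 with 8 biennial visits.

Defaults are calibrated to a spirometric ratio trait: per-visit measurement
SD 0.4 and slope scale `slope_sd` = 0.07 units/yr on the unit-variance
trajectory scale (between-subject SD ~7 %, measurement error ~3 %,
annual-decline SD ~0.5 %/yr). The slope scale matters: stage-1 slope
estimation error is `noise² / Σ w (age−ā)²`, about 0.19 of the slope
variance at these defaults, so two-stage estimates of h1² are attenuated by
~1/1.19 — exactly as in the real method, where reported change-rate
heritabilities likewise refer to estimated, noisy slopes. Parameter-recovery
tests account for this.

What the generator does *not* emulate: linkage disequilibrium, imputation
uncertainty, population structure (unless two populations are constructed
explicitly), genotype–exposure correlation, nonlinear trajectories,
informative dropout. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data complications.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen for a single CPU: parameter
recovery at n = 1000 subjects × 1000 SNPs over 10 seeds (mean recovery of
h0², h1², ρ_g and the interaction variance); REML-vs-grid oracle
equivalence at n = 150 over 10 seeds with a 50×50 likelihood grid; null
calibration of the boundary LRT over 200 replicates at n = 500 sharing one
GRM; the permutation-null GWAS inflation check at n = 300 × 100 000 SNPs;
delta-method coverage over 100 replicates at n = 500. Tolerances follow
sampling theory at those sizes, not the other way round.

## Known limitations

- Dense REML is O(n³) per iteration and O(n²) memory; practical to a few
  thousand samples. No sparse/low-rank path.
- The bivariate model assumes both traits observed on the same samples;
  there is no partial-overlap support.
- The conditional-variance formula assumes the bivariate fit's variances
  are positive; boundary fits (a variance at the floor) make ρ_g and the
  derived quantities unstable, which the `converged` / `ai_singular` flags
  surface but do not repair.
- GWAS is plain OLS with PC adjustment, not a mixed model; at strong
  cryptic relatedness λ will exceed 1.
- The CLI's smoking subgroups are the fixed {all, never, ever} set; other
  exposures go through the library API (`fit_gxe_greml` takes any binary
  exposure vector).
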