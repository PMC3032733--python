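# Methods

## The twin model

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and non-shared environmental (E)
sources using the differing genetic relatedness of monozygotic (MZ, identical)
and dizygotic (DZ, on average 50% genetically similar) co-twins. For a single
standardized phenotype with path coefficients (a, c, e), the expected
twin-pair covariance matrices are

    MZ: [[a²+c²+e², a²+c²  ], [a²+c²,   a²+c²+e²]]
    DZ: [[a²+c²+e², ½a²+c² ], [½a²+c²,  a²+c²+e²]]

Multivariately, lower-triangular path matrices Λ_A, Λ_C, Λ_E define component
covariances Σ_X = Λ_X Λ_Xᵀ; the within-twin block is Σ_A + Σ_C + Σ_E and the
cross-twin block Σ_A + Σ_C (MZ) or ½Σ_A + Σ_C (DZ). The triangular (Cholesky)
structure orders traits causally: the first factor triple loads on all traits,
the last only on the final trait, so the final factor's contributions are the
genetic and environmental influences on the outcome *independent* of every
covariate trait. Dividing those independent components by their sum
("re-standardization") expresses them as proportions of the covariate-free
variance, directly comparable to a univariate decomposition of a
regression-residualized score.

Assumptions inherited from the design: additivity (no dominance or epistasis
modelled), equal environments across zygosities, no assortative mating, no
sex-limitation of the variance components, random mating of measurement error
into E. Gene–environment correlation is absorbed into A.

## Estimators

- **Intraclass correlation**: one-way random-effects ANOVA form over unordered
  complete pairs, (MSB − MSW)/(MSB + MSW) with group size 2. A double-entry
  Pearson correlation is provided as a cross-check estimator; the two agree to
  O(1/n).
- **Falconer arithmetic**: A = 2(rMZ − rDZ), C = rMZ − A, E = 1 − rMZ. The
  raw arithmetic is reported without truncation; components outside [0, 1]
  are flagged, not clipped.
- **Maximum likelihood**: Gaussian full-information likelihood (FIML) over
  all available observations. Pairs are grouped by missingness pattern; each
  pattern contributes the likelihood of its observed sub-vector, so a twin
  whose co-twin skipped a measure still informs the fit. Sufficient statistics
  (count, sum, cross-product per pattern) make each likelihood evaluation
  independent of sample size. Optimization is L-BFGS-B in path-coefficient
  parameterization (which enforces non-negative variance components) from a
  fixed set of starting values; a fit is accepted only if the multi-start
  optima agree (the spread is recorded on every fit object). Multivariate
  starts come from method-of-moments component estimates (2(C_MZ − C_DZ) etc.)
  projected to the nearest PSD matrix.
- **Confidence intervals**: profile likelihood on the standardized
  proportions. Bounds solve 2·(ℓ_max − ℓ_profile(t)) = 3.841 (χ²₁ at 95%),
  located by stepping from the estimate toward each boundary and Brent root
  refinement; bounds are clipped to [0, 1] and a lower bound of exactly 0
  flags the component as non-significant (NS) at α = .05. For Cholesky
  models, profile CIs are computed for the three independent final-factor
  components via SLSQP equality-constrained re-optimization; they are off by
  default in the study runner (≈13 s per component at full cohort size) and
  enabled with `cholesky_ci=True`. Per-path CI tables beyond the independent
  components are not produced: the study's inferential claims concern the
  independent components, and the univariate module supplies per-trait CIs.
- **Sex × zygosity ANOVA**: 2×2 fixed-effects ANOVA (statsmodels, Type-II
  sums of squares) on one randomly selected member of each pair; the selection
  is seeded and the seed recorded. η² = effect SS / total corrected SS. With
  effects this small (η² ≲ .004) the SS type is immaterial.

Boundary caveat for submodel tests: dropping a truly-zero component places the
null on the parameter boundary, so the likelihood-ratio statistic follows a
½χ²₀ + ½χ²₁ mixture and nominal χ²₁ p-values are conservative.

## Preprocessing

All phenotypes are standardized to mean 0, SD 1 over pooled individual twin
observations, using the population (divide-by-n) SD convention, held fixed
throughout. Age and sex (coded 0/1) are regressed out of each measure by OLS
over pooled individuals — twins correlate perfectly for age, and same-sex
pairs for sex, so uncorrected data would inflate twin correlations.
Within-pair dependence is deliberately ignored in these regressions, as is
standard at the preprocessing stage. Covariate-corrected traits ("g-free",
"previous-achievement-free", doubly corrected) are standardized OLS residuals
over complete cases; an observation missing any covariate is missing the
corrected trait, which is why corrected traits have smaller Ns. Composites are
means of available (non-missing) subscales, then standardized — maximizing N
rather than requiring complete subscale sets. The pipeline standardizes both
before the age/sex regression and after each residualization, so every
analyzed trait enters the models with unit variance.

## The synthetic cohort generator

Phenotypes are multivariate normal — the distributional assumption already
implicit in the Gaussian ML twin model. Latent A/C/E factor scores are drawn
per trait with MZ co-twins sharing A exactly, DZ co-twins correlating 0.5 per
A factor (via x₂ = ½x₁ + √¾·innovation), C shared, E independent. Every
random stream is keyed by (group, role, factor index) through SeedSequence
spawn keys, so adding a trait or changing one measure's missingness never
perturbs other columns, and a fixed seed reproduces the cohort bit for bit.

Fixed generator choices, made once:

- **Ages** uniform on (10.4, 12.7) years: midpoint 11.55 and SD ≈ 0.66,
  matching the reference cohort's age distribution. Age effects shift means
  by `age_effect · (age − midpoint)`.
- **Sexes**: MZ pairs same-sex (fair coin); DZ pairs half same-sex, half
  opposite-sex in expectation. Analyses pool across sex and zygosity
  composition — no sex-limitation model is simulated or fitted, and
  opposite-sex DZ pairs are included everywhere.
- **Missingness** is missing-completely-at-random per trait per twin. The
  reference scenario's per-trait rates (.55, .37, .11, .26, .01) were chosen
  so complete-pair counts approximate the reference Ns (e.g. ≈1,040 of 1,900
  MZ pairs complete for teacher-rated achievement).
- **Subscales**: each requested indicator is √r·trait + √(1−r)·noise, so the
  inter-subscale correlation equals the requested reliability r and the first
  principal component explains ≈ r + (1−r)/m of the variance for m subscales
  (3 subscales at r=.83 → ≈ 88%; 6 at r=.49 → ≈ 58%).

### The reference generating structure

Per-trait (A, C, E) diagonals are fixed by the published twin correlations
through the Falconer identities rMZ = A + C, rDZ = ½A + C: (.50, .30, .20)
for teacher-rated achievement, (.56, .19, .25) for test achievement,
(.44, .23, .33) for g. Cross-trait component covariances follow the published
bivariate decompositions: if the covariate explains contributions
(k_A, k_C, k_E) of the outcome's components, the implied component covariance
is √(X_cov · k_X), rescaled so the phenotypic correlations hit .50 (g–teacher)
and .69 (g–test) exactly. Quantities the reference study does not report were
set once to field-plausible values: age-10 traits mirror their age-12
counterparts; the ach10–g covariance split copies the g–ach12 split;
teacher–test phenotypic correlations are .60 same-age and .50 cross-age, split
across A/C/E proportionally to √(X_i X_j) with the C part shrunk 10% to keep
Σ_C positive semi-definite.

One structural point: the published *residual-trait* twin correlations and
the published *Cholesky* decompositions are not mutually consistent — no
single generating model reproduces both, because a coherent model forces the
residual route and the re-standardized Cholesky route to agree (they do here,
within ±.05 at large n), whereas the published pair differs by more (e.g.
g-free teacher C of .21 by one route and .30 by the other). The generator
matches the raw-trait correlations and the Cholesky decompositions exactly;
the residual-trait correlations are then emergent and land near, but not on,
their published values. Passing tests therefore demonstrate that the
estimators recover a known coherent structure under realistic Ns and
missingness — not that real cohort data are this well behaved: real teacher
ratings are ordinal and rater-clustered, missingness is not completely at
random, and measurement reliability varies by subgroup, none of which is
emulated.

## Numerical choices

- Optimizer: L-BFGS-B, ftol 1e-12, numeric gradients; multi-start agreement
  required within 1e-6 in log-likelihood on the test grid.
- Cholesky sign convention: factor columns are flipped after fitting so
  diagonal paths are non-negative (Λ Λᵀ is invariant); the Λ_E diagonal is
  floored at 1e-8 to keep the fitted model valid when a residual variance
  estimates to zero.
- PSD handling: component matrices supplied as covariances are factored with
  an eigenvalue-clipped Cholesky tolerating eigenvalues above −1e-8.
- Degenerate inputs raise typed errors rather than emitting noise: constant
  traits (standardization), outcomes fully explained by covariates
  (residualization and re-standardization), collinear covariates, empty ANOVA
  cells, < 2 complete pairs (ICC), < 10 informative pairs per group (ML fits).
- Reported problem sizes: the study replica runs at 1,900 MZ / 3,250 DZ pairs
  (full pipeline ≈ 30 s); calibration tests use 5,000–25,000 pairs per group
  where a tolerance of ±.02–.05 on a proportion requires it; the replicate
  recovery study uses 100 cohorts at 1,039/1,785 pairs.

## Known limitations

- No dominance (ADE), sex-limitation, sibling-interaction, rater-clustering
  or selection/attrition models; no independent-pathway or common-pathway
  alternatives to the Cholesky structure.
- FIML assumes multivariate normality and MCAR/MAR missingness.
- Profile CIs for all individual Cholesky paths are not exposed, only for the
  independent components of the final trait.
- The sex × zygosity ANOVA discards one twin per pair by design (to avoid
  within-pair dependence), halving its effective sample.
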