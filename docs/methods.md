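# Methods

## Data model

The analysis substrate is a long-format table, one row per mouse per test
day: mouse id, strain, sex (F/M), test site (JAX/UNC), treatment arm
(cocaine/saline), calendar day of the 19-day protocol, total distance (cm)
in the 60-minute post-injection interval, and day-1 body weight (g). Days
are the protocol's calendar days {1, 2, 3, 5, 7, 9, 11, 12, 19}, never
re-indexed at I/O time. The CSV dialect is comma-separated UTF-8 with a
header; missing numeric fields are empty strings and distances are written
with 3 decimals, which makes write→read the identity on valid tables.
Input headers may be aliased (e.g. `animal_id`, `test_day`,
`total_distance`); the alias map is configurable because deposited files
vary in naming.

## Derived phenotypes

Difference scores are signed, later minus earlier day ("day 2–1" = D2 −
D1). The sensitization AUC integrates distance over the five cocaine
exposures by the trapezoidal rule on the exposure index with unit spacing,
(D3 + D11)/2 + D5 + D7 + D9. A plain sum is available behind
`auc_rule="sum"` because "area under the curve" is occasionally computed
that way; the trapezoid-on-index reading is the default as the most common
convention and because it is scale-consistent (constant input c gives 4c).
A derived value is missing exactly when any constituent day is missing,
and every variable carries a day-set provenance (e.g. auc ↦ {3,5,7,9,11})
that downstream correlation masking consumes.

## Synthetic cohort generator

The generator exists to give every downstream stage inputs with known
truth. Its model for mouse m of strain s on day d is

    y = μ + a_s + b_s·k(d) + u_m + δ_d + drug(d) + sex + site + ε,

with a_s ~ N(0, σ²_strain), b_s ~ N(0, σ²_slope), u_m ~ N(0, σ²_mouse),
ε ~ N(0, σ²_e), k(d) the 0-based cocaine-exposure index, and, in the
cocaine arm, drug(d) = acute + cumulative ramp on exposure days, the
conditioned shift on day 12, and the exposure-5 value plus an expression
shift on day 19. The `ramp` vector holds per-exposure increments; the
acute effect is the exposure-1 baseline, so the first increment defaults
to zero. Distances are floored at 0 after noise; the truncation count is
recorded in `TrueParameters` because heavy truncation biases moments.
Generation is fully deterministic given the seed.

Default configuration (shipped as a versioned JSON fixture): 59 strains ×
8 mice per strain per arm, grand mean 6,000 cm, σ_strain = 1,500 cm,
σ_slope = 150 cm/exposure, σ_mouse = 800 cm, σ_e = 1,000 cm, acute cocaine
effect +4,000 cm with a decelerating ramp (cumulative +0, 800, 1,400,
1,800, 2,100 cm), conditioned activation +1,000 cm, no mean expression
shift, F−M shift +500 cm, JAX−UNC shift +800 cm. These magnitudes are
chosen to be realistic for 60-minute open-field distances in a diverse
panel and to place day-level heritabilities around 0.6 and
difference-score heritabilities near their sampling floor — the
qualitative landscape a strain survey of this design produces. The
published panel's within-strain variances are not recoverable from
summary statistics, so the components are a design choice, not a fit.

What the generator does *not* emulate: strain-specific acute response
magnitudes (all strains share the acute effect, so with the default
effect size every strain is a responder), non-Gaussian and
heteroscedastic activity distributions, day-to-day autocorrelation beyond
the mouse intercept, attrition, and batch/cohort effects. Passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed variance-components model, not robustness to real-data
pathologies.

For any derived variable that is a linear combination Σ c_d D_d, the
generator's analytic between/within strain variances are

    σ²_B = (Σc)²σ²_strain + (Σ c_d κ_d)²σ²_slope,
    σ²_W = (Σc)²σ²_mouse + (Σc²)σ²_e + (Σc)²·r(1−r)·sex² [+ site term],

with κ_d the slope multiplier and r the sex ratio, giving the plug-in
expectation of the heritability estimator under balanced sampling,
(σ²_B + σ²_W/n)/(σ²_B + σ²_W); recovery tests compare the mean estimate
over replicate cohorts against it.

## Mixed model

Sex is removed first by OLS residualization on an intercept plus sex
indicator (equivalently within-sex centering; idempotent), matching the
two-stage practice of residualizing and then modeling. The residuals
enter a cell-means linear model over day × treatment × strain with a
random intercept per mouse. REML estimation profiles the restricted
likelihood over the single ratio λ = σ²_mouse/σ²_e: given λ, the whitened
per-mouse transformation ỹ = y − (λn_m/(1+λn_m))·ȳ_m reduces GLS to OLS
with closed-form β and σ²_e. Because each mouse lies in one strain ×
treatment combination, the whitened normal equations are block-diagonal
over such groups, making each objective evaluation O(N). The profile
deviance is minimized on log λ by a 33-point grid plus bounded Brent
(tolerance 1e-10 on log λ, i.e. better than 1e-8 relative on the ratio),
with the λ = 0 boundary compared explicitly; boundary estimates are
reported as exact zeros with a flag. Zero residual variance (all
responses equal within cells) is flagged degenerate rather than fitted.

Type III tests are built from the cell-means parameterization —
marginal-mean contrasts via Kronecker products of difference and
averaging operators — which makes them independent of factor coding but
requires the full factorial of cells; empty cells raise a rank-deficiency
error naming the missing cells. Denominator df are Satterthwaite: the
asymptotic covariance of (σ²_mouse, σ²_e) is twice the inverse finite-
difference Hessian of the REML deviance, the variance of each 1-df
contrast is differentiated by central differences, and multi-df terms
combine per-eigendirection dfs as ν = 2E/(E−q), E = Σ ν_i/(ν_i−2). When
the Hessian is unusable or the fit is on the boundary, residual df are
used and the row is annotated. Satterthwaite rather than Kenward-Roger
matches the df convention of the standard mixed-model ANOVA tooling in
this field; agreement is qualitative, not digit-exact.

Tukey HSD p-values use the studentized range distribution
(scipy's numerically integrated CDF), q = |Δ|/(SE_Δ/√2); at k = 2 this is
exactly the two-sided t-test, and the implementation is cross-checked in
tests against a 10⁶-draw Monte-Carlo oracle. Responder classification
takes, per strain, the cocaine−saline contrast of marginal means averaged
over days, its SE from the block covariance, Satterthwaite df, and a
Tukey adjustment over the family of all strain × treatment marginal means
(HSD names an all-pairs procedure; only within-strain pairs are
reported). A strain is a responder when the adjusted p < 0.05 with a
positive estimate; unadjusted p-values are emitted alongside since the
adjustment convention for published per-strain p-values varies. Strains
present in only one arm are reported inestimable and excluded from the
responder count. Because the all-pairs family is large, the adjusted flag
is deliberately conservative; type-I calibration is asserted on the
unadjusted contrast p-values.

The cross-site replicability ANOVA (strain, sex, site with all two-way
interactions, one row per mouse) is ordinary least squares with
sum-to-zero coding, under which drop-one-term model comparison yields
Type III F statistics with residual df; aliased terms (empty cells,
single-level factors) are dropped with a warning.

## Heritability

H² = MS_strain/(MS_strain + (n̄−1)·MS_resid) from the one-way strain
ANOVA of each derived variable, cocaine arm only, with n̄ the arithmetic
mean of per-strain counts. The estimator is strictly inside (0,1)
whenever n̄ > 1 and both mean squares are positive, increasing in
MS_strain, decreasing in MS_resid, and scale-invariant. The bootstrap SE
re-simulates from the fitted one-way random-effects model: components
σ̂²_strain = max(0, (MS_strain − MS_resid)/n₀) (n₀ the unbalanced-design
effective n; the clamp is standard practice) and σ̂²_e = MS_resid;
replicates preserve observed per-strain counts; 1,000 replicates by
default, vectorized, deterministic given the seed. The bootstrap
re-simulates the per-mouse derived variable directly (one-way model, no
day-level structure) since the estimator operates on per-mouse values;
re-simulating the full repeated-measures model is a defensible
alternative reading and would mainly matter if day-level errors were
strongly correlated. Heritability uses raw (non-residualized) values with
sexes pooled; residualization is exposed as an option but is not the
default since sex removal is described for the mixed-model ANOVA, not the
heritability computation.

## Correlations

Strain-mean Pearson correlations (cocaine arm) over per-day distances,
derived variables and day-1 body weight. A pair is masked exactly when
the two variables' day sets intersect; distinct single-day variables
never share a day and body weight has an empty day set, so both are
structurally exempt. The masked pattern over the 16-variable panel is
asserted structurally in tests against the published blank-cell pattern.
Pairwise-complete strain deletion is used (coverage differs by variable);
n is reported per pair and r requires n ≥ 3. Two-sided p-values come from
the t transform t = r√((n−2)/(1−r²)); the Bonferroni denominator is the
number of unmasked pairs actually reported (configurable in effect, since
it is derived from the variable set supplied). Cross-site replicability
correlates the two sites' strain means per derived variable across
shared strains, reporting df = n − 2.

## Problem sizes and numerical choices

Recovery and calibration studies in the test suite use 200 cohorts of 50
strains × 10 mice for estimator recovery and bootstrap calibration (the
bootstrap at the full 1,000 replicates), and 500 null cohorts of 4
strains × 4 mice per arm for type-I calibration — sizes at which the
Monte-Carlo error of the checked quantities is well below the asserted
tolerances while the whole suite stays fast. The REML grid spans
λ ∈ [1e-8, 1e8]; optimality is property-tested against a 64-point grid.
Ties and degenerate inputs: duplicate (mouse, day) rows fail strict
validation (last-row-wins otherwise); all-equal responses flag a
degenerate fit; zero-variance variables yield missing correlations with
a reason; both-mean-squares-zero yields missing H².

## Known limitations

Single random intercept only — no crossed or day-level random effects, no
repeated-measures covariance structures; Satterthwaite df are an
approximation, weakest for small panels with strong imbalance; the
Tukey-adjusted responder flag is conservative under the all-pairs family;
the generator's Gaussian, homoscedastic structure understates real-data
messiness; and the bootstrap's one-way model reading (versus re-fitting
the full mixed model) is one of two defensible interpretations of
model-based resampling for this estimator.
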