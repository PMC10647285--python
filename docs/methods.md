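# Methods

## Data model

A trial is a long-format table of (environment, genotype, replicate, yield)
records with yields in g/plot; replicates are nested in environments
(`REP(ENV)`). All analyses require a *balanced* trial — every genotype ×
environment cell observed with the same replicate count r. Unbalanced data
are rejected rather than imputed: the exact df partition of the joint ANOVA
and the closed-form shrinkage BLUPs both presume balance, and silently
imputing cells would misstate both. Genotype/environment labels are opaque
strings; ranking ties are broken in sorted label order throughout. The
factorial structure behind the environments (location × year × sowing) is
carried only as metadata and used only to pair environments for the heat
susceptibility index.

## Joint ANOVA and the AMMI family

The two-way ANOVA with replicates-in-environments decomposes the total SS
into ENV, REP(ENV), GEN, GEN:ENV and residual with df (e−1), e(r−1), (g−1),
(g−1)(e−1), e(g−1)(r−1). Environments are tested against REP(ENV) (the
replicate stratum is the appropriate error for a whole-environment effect);
genotypes and the interaction are tested against the pooled residual. The
table also reports the overall mean and CV% = 100·√MS_res/mean.

AMMI doubly centers the cell means, Z = Y − rowmeans − colmeans + grand, and
takes its SVD. Conventions:

- **Per-axis tests** use Gollob df, df_k = g + e − 1 − 2k, with axis SS on the
  replicate scale (r·λ_k²) so that the PC rows sum exactly to the GEN:ENV SS
  and are F-tested against the residual mean square. Cross-validation-based
  axis tests are out of scope; the RMSPD module addresses model choice
  directly.
- **Sign convention:** for each axis the environment-score entry of largest
  magnitude is made positive (deterministic, applied to both score vectors),
  so coordinates are reproducible across runs and platforms.
- **Score scaling:** biplot scores use the symmetric split
  s = √λ·(eigenvector) for both genotypes and environments; ASV and WAAS/WAASB
  are computed from these scores. Other conventions rescale axes but do not
  change any ranking produced here.
- **ASV** combines the first two axes, weighting axis 1 by SS₁/SS₂
  (Purchase-type form). It is undefined when the second axis carries no
  variance; that degenerate case raises an explicit error.

## Mixed model, BLUPs and heritability

Environments and replicates-within-environments are fixed; genotypes and GEI
are random: y = Xb + Z_g u_g + Z_ge u_ge + ε with u_g ~ N(0, V_G),
u_ge ~ N(0, σ²_gei), ε ~ N(0, σ²_err).

- **EMS estimation** inverts the expected mean squares: σ²_err = MS_res,
  σ²_gei = (MS_GE − MS_res)/r, V_G = (MS_G − MS_GE)/(re). Negative estimates
  are truncated at zero and flagged. A replicate quasi-component
  (MS_REP − MS_res)/g is reported for completeness even though replicates are
  fixed in the model.
- **REML**: in the balanced design the residual space after removing fixed
  effects splits into three orthogonal strata (genotype, interaction,
  within-cell) with per-contrast variances re·V_G + r·σ²_gei + σ²_err,
  r·σ²_gei + σ²_err, and σ²_err. The restricted likelihood is then an exact
  three-term function of the ANOVA sums of squares, maximized under
  non-negativity constraints with L-BFGS-B. At interior solutions REML and
  EMS coincide; the test suite additionally cross-checks REML against an
  independent mixed-model implementation.
- **Heritability**: plot basis H² = V_G/(V_G+σ²_gei+σ²_err); entry-mean basis
  H² = V_G/(V_G + σ²_gei/e + σ²_err/(re)). The entry-mean basis is the
  default because selection in a MET acts on genotype means across the whole
  trial; with a large residual CV, plot-basis heritability would be
  implausibly low for any realistic genetic variance.
- **BLUPs** use the balanced-case shrinkage forms
  BLUP_g = c_g(ȳ_g. − ȳ..) with c_g = V_G/(V_G + σ²_gei/e + σ²_err/(re)) and
  BLUP_ge = c_ge·Z with c_ge = σ²_gei/(σ²_gei + σ²_err/r). Note c_g < 1
  whenever σ²_gei > 0 even at σ²_err = 0: the genotype mean still contains
  interaction noise averaged over finitely many environments.

## WAASB, WAASBY, scenarios, quadrants, clusters

WAASB_g(p) = Σ_{k≤p} |s_gk|·EP_k / Σ_{k≤p} EP_k over the SVD of the BLUP
interaction matrix (WAAS: same formula on the fixed-effect AMMI scores). The
default uses all min(g−1, e−1) axes, and the full ranking-by-p table is always
emitted, because rankings can shift materially with the number of retained
axes (typically stabilizing after about four); fixing a single p would hide
that sensitivity. WAASB is invariant to the SVD sign convention because only
absolute scores enter.

WAASBY rescales yield to rY (100 = best) and WAASB to rW (100 = most stable)
and averages them with weights θ_Y/θ_S summing to 100 (default 65/35 —
breeding programs usually weight performance above stability). The weight
sweep emits ranks for θ_Y = 0, 5, …, 100. Quadrants split the yield × WAASB
plane at the two means: IV = productive & stable, II = productive & unstable,
III = stable & unproductive, I = neither; boundary values (≥ mean) count as
"high" on both axes. Rank-profile clustering uses Ward linkage on Euclidean
distances between scenario-rank rows with k = 4 groups by default — the
algorithm, distance and k are conventional choices, configurable, and cluster
ids are deterministic (renumbered by first appearance).

## RMSPD cross-validation

Each resample assigns one randomly chosen replicate block per environment to
validation and refits every model on the remaining replicates' cell means
(the modeling set stays balanced). RMSPD = √(mean over the g×e validation
observations of (ŷ − y_val)²). Predictions contain no replicate effect — the
validation block's replicate effect is unobservable by construction, so it
inflates all models equally. AMMI models need r ≥ 2; the BLUP predictors need
r ≥ 3 because the modeling set must retain at least two replicates to
separate σ²_err from σ²_gei. The default 1000 resamples follow common
practice; tests and the scaled-down acceptance battery use 100–200, which is
ample for median orderings at these dimensions.

## GGE geometry

The environment-centered matrix M = Y − colmeans (optionally column-scaled by
sd) is decomposed by SVD, and the first two axes displayed under singular
value partitioning svp = 1 (genotype-focused, UΛ | V), 2
(environment-focused, U | VΛ) or 3 (symmetric, UΛ^½ | VΛ^½). In all three
the dot product of a genotype and an environment marker equals the rank-2
reconstruction M̂ — the algebraic fact every pattern reduces to, and the
property the test suite verifies against brute-force argmax/sign oracles on
random matrices. Axes whose singular value is below 1e−12·λ₁ are zeroed so
that degenerate geometry (coincident or collinear markers) is detected
exactly rather than hidden by √λ-amplified numerical noise.

- *Which-won-where*: convex hull of genotype markers; each environment's
  winner is the hull vertex with the largest projection on the environment
  direction (computed in angle space, so hull edges not facing the origin are
  handled); boundary rays are the equal-projection directions between
  consecutive winning vertices. Ties go to the counter-clockwise sector.
  Fewer than 3 non-collinear markers: direct argmax over M̂, flagged
  degenerate.
- *Mean vs stability*: the average-environment axis (AEA) is the unit vector
  toward the mean environment marker; genotype projections on it estimate
  mean performance, signed perpendicular components estimate instability.
  An average environment at the origin (perfectly antagonistic environments)
  makes the AEA undefined and raises an error.
- *Genotype ranking*: distance to the ideal point, on the AEA at the largest
  genotype projection. *Environment ranking*: vector length
  (discriminativeness), cosine to the AEA (representativeness), distance to
  the ideal environment. *Pairwise comparison*: sign of the environment's
  projection on the marker difference (the equality-line rule).
  *Environment profile*: sign of the environment's projection on the
  genotype's axis.
- Default svp per pattern: 3 for which-won-where, 2 for the AEA-based
  patterns, both overridable. Patterns use axes 1–2 only.

## Stress and adaptability indices

- **HSI** (Fischer–Maurer): S_g = (1 − Yh_g/Yn_g)/SI with SI = 1 − Xh/Xn per
  normal/late pair; pairs are built from environment metadata matching
  location and year. Classes: < 0.51 highly tolerant, < 0.76 tolerant,
  ≤ 1.00 moderately tolerant, > 1.00 susceptible (values in the printed gaps
  of the conventional boundaries go to the more tolerant class). The
  per-pair table is primary; the across-pairs mean is emitted as a derived
  summary. A genotype with a zero normal-sown cell mean (possible in heavily
  stressed recorded data, where negative measurements floor at zero) carries
  no susceptibility information and is masked NaN for that pair rather than
  failing the table.
- **Annicchiarico**: ω_g = mean_e(p_ge) − z_{1−α}·sd_e(p_ge) on the
  percentage-of-environment-mean scale (sd with e−1 denominator). Default
  α = 0.25 (z ≈ 0.6745), the method's original confidence level; configurable.
- **Environmental index**: I_e = ȳ_.e − ȳ.., favorable iff I_e > 0, with the
  per-environment best genotype reported.

## Synthetic data generator

`simulate_met` draws y_ger = μ + E_e + R_r(e) + G_g + (GE)_ge + ε_ger with
independent Gaussian effects and a low-rank interaction: k* orthonormal
random factor pairs (orthogonal to the intercept), singular values on a
geometric profile (ratio 0.6 by default), scaled so Σ(GE)² =
(g−1)(e−1)·σ²_gei. Gaussian effects are used throughout: nothing in standard
MET ANOVA practice motivates a different family, and normality makes every
estimator's expectation exact. Negative simulated yields are floored at zero
with a warning and a count in the ground truth — yields are physical
quantities — which at the default scale affects ~5% of draws and slightly
shrinks realized variances.

Default conditions emulate a large chickpea landrace MET: g = 42, e = 12,
r = 3, μ = 174.5 g/plot, σ²_env = 2701, σ²_rep = 799, σ²_gen = 2174,
σ²_gei = 2120, σ²_err = 4273 (g²/plot²), interaction rank 4. These give an
expected grand mean of 174.5, CV ≈ 37.5%, entry-mean heritability ≈ 0.85 and
interaction mean squares ≈ 2.5× the residual — a strongly interactive trial
in which roughly the first four axes matter.

`simulate_heat_pairs` builds e/2 location-year pairs; the late-sown cell
expectation is (1 − d_g) times the normal-sown one, so the true HSI is
d_g/SI_p exactly. Default reductions d_g ~ Uniform(0.05, 0.45) span the
tolerance classes (HSI ≈ d_g/mean(d) from ~0.2 to ~1.8). Because the
multiplicative reduction needs strictly positive expectations while Gaussian
effects at a realistic variance scale have a small negative tail, effect
draws are rejected and resampled until all normal-sown cell expectations are
positive (a mild conditioning of the effect distribution, recorded here).

**What the generator does not emulate:** right-skewed yield distributions,
spatial field trends and incomplete-block structure, heteroscedastic
environments, and weather-driven environment covariates. Passing recovery
tests therefore demonstrates estimator correctness under the stated Gaussian
balanced model, not robustness to those real-data features.

**An exactness note used by the recovery tests.** The generator's interaction
matrix has rows and columns summing to zero. Under that construction the
classical genotype EMS estimator (MS_G − MS_GE)/(re) has exact expectation
V_G − σ²_gei/e, not V_G, because the classical formula assumes i.i.d.
(uncentered) interaction effects whose genotype means carry σ²_gei/e. The
other three components are recovered without bias. `SimConfig.expected_ems()`
returns these exact expectations, and the calibration tests assert against
them; recovery is tested at μ = 600 so the zero-floor never engages and the
Gaussian model is exact. (At the default μ = 174.5 the floor shrinks all
recovered components by roughly 5–9% — a property of the truncation, not the
estimators.)

## Numerical conventions and degenerate inputs

- Constant data: ANOVA F-statistics are reported NA; zero-variance axes give
  F = 0, p = 1 in the Gollob table.
- WAASBY rescaling requires non-constant yields and non-constant WAASB;
  constant inputs raise an explicit error rather than returning 0/0.
- All rank columns are dense 1..g permutations; ties break by label order via
  stable sorts.
- Geometry tolerances scale with the coordinate magnitude (1e−9·max|coord|).
- Seeds: every stochastic routine takes an explicit seed and is bit-reproducible;
  the pipeline writes every resolved default to `run_log.json`.

## Problem sizes in the test suite

Unit tests run on small trials (g ≤ 12, e ≤ 8). The calibration battery uses
200 seeds at g = 60, e = 12, r = 3 for variance components, 100 seeds for HSI
class recovery, 20 seeds at the default 42×12×3 scale for the WAASB–truth
correlation, and 50 experiments × 200 resamples for the cross-validation
orderings — sizes at which Monte-Carlo error is far below every asserted
margin while the whole suite stays fast.

## Known limitations

- Balanced trials only; no EM-style imputation for missing cells (v1 scope).
- REML is exact only for the balanced design it targets; there is no general
  sparse mixed-model solver behind it.
- GGE patterns use axes 1–2 only; no confidence regions on biplots.
- HSI uses cell means, not BLUPs, as inputs.
- Figure rendering is out of scope: the package emits coordinates and rank
  tables, not styled plots.
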