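# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `brainpad`.

## The normative brain-age framework

**Brain-age prediction.** A regressor maps a subject's regional features
plus sex to an age estimate, trained on a healthy reference cohort.  The
predicted age difference PAD = predicted − chronological age summarizes
deviation from normal aging, but every imperfect predictor shrinks its
predictions toward the training mean age, so PAD is negatively correlated
with age even in perfectly normal samples.  Comparisons across ages, and
correlations of PAD with age-linked clinical variables (illness duration,
onset age), are confounded unless this bias is removed.

**Normative scoring.** Instead of correcting PAD after the fact, the
framework models the *distribution* of predicted age in the reference
population as a function of age and sex, using Gaussian-process regression
with predicted age as the outcome and (chronological age, sex) as inputs.
For any query the GPR returns the peer mean x̄̂_peers and peer SD Ŝ_peers of
predicted age, and a subject is scored as

    nPAD = (predicted_age − x̄̂_peers) / Ŝ_peers .

Whatever systematic age- or sex-dependent error the predictor makes —
linear shrinkage or otherwise — is part of the reference distribution and
is absorbed into x̄̂_peers, so nPAD is a bias-free z-score by construction
and is comparable across modalities whose predictors have different error
scales.  The linear benchmark cPAD (PAD minus an age-linear trend fitted by
OLS in the reference) is provided for comparison; in a homoscedastic world
the two rank subjects nearly identically (held-out Spearman > 0.95 in the
default synthetic study), while nPAD additionally absorbs non-linear and
sex-specific structure.

**Predictive SD.** Ŝ_peers is the *total* predictive SD — latent GP
variance plus the fitted observation-noise variance.  A normative range
describes where individual observations fall; using the latent SD alone
would shrink Ŝ_peers toward 0 in large samples and inflate every z-score.
This is a deliberate design choice; a latent-only variant would change only
the scale of nPAD, not its ordering.

**Kernel and fitting.** Kernel = constant × RBF over (standardized age,
sex dummy) + white noise.  The age length-scale is initialized at half the
age SD with bounds [1, 50] years (in standardized units); the noise level is
initialized at the residual variance of a linear pre-fit of predicted age on
age and sex; targets are variance-normalized during fitting; the marginal
likelihood is optimized with 5 seeded restarts.  Sex enters as an input
dimension of one joint model rather than as two per-sex fits — it matches
the "age and sex as independent variables" formulation and shares the age
trend across sexes; with 200+ subjects per sex the difference is
negligible, and per-sex fitting can be emulated by filtering the input.
Queries more than 5 years outside the training age range return values but
carry an extrapolation flag into all downstream score tables.

## Brain-age backends

The default architecture is a **cascade feed-forward network**: 12 hidden
blocks of width 16 with tanh activation, where block *i* receives the
standardized inputs concatenated with the outputs of all previous blocks,
and a linear output head reads the inputs plus every block output.  It is
trained by full-batch Adam (lr 0.01, weight decay 1e-4) with early stopping
on a 10% internal validation split (patience 30, max 400 epochs), after
which the output head is re-solved exactly by ridge least squares on the
training set.  Because the raw inputs reach the head directly, the network
nests linear regression: on a noise-free linear world it attains MAE ≈ 0,
matching a linear backend to well under a year (a tested invariant).

The normative machinery is predictor-agnostic, so the backend is pluggable:
`ridge` (cross-validated ridge regression), `gbt` (gradient-boosted trees)
and `constant` (mean-age dummy) honor the same contract.  The repeated
simulations in the test suite and the acceptance script use the ridge
backend: on the synthetic cohorts, whose features are linear-plus-quadratic
in age, it is statistically equivalent to the cascade at a fraction of the
cost, and nPAD's properties do not depend on the regressor.  Features are
standardized per column (sex included as a standardized binary input) with
training-set statistics; zero-variance features are rejected by name rather
than silently dropped.  Cross-validation uses a seeded shuffle with
contiguous 10-fold splits; each subject is held out exactly once.

## The synthetic study

The generator emulates a cross-sectional case–control brain-aging study
with a separate normative reference: reference n=482 (ages 14–92, uniform),
independent test n=70, cases n=147 vs controls n=130 (ages 16–62, normal
with mean 31, SD 8.4), ~47% male.  Feature blocks follow the field's
modality conventions: 56 regional volumes (~mL), 68 cortical thickness
values (~2–3.4 mm), 45 tract GFA (~0.35–0.65) and 45 tract MD
(~0.65–0.95 × 10⁻³ mm²/s).  Each feature follows

    value = μ_j + β_j·age + κ_j·age² + γ_j·sex + ε,   ε ~ N(0, σ_j²),

with 80% of features carrying a nonzero aging slope (volume, thickness and
GFA decline; MD rises), a small quadratic term so the normative model faces
genuine non-linearity, and an independent sex effect so the GPR's sex input
is testable.  Education is drawn group-dependently (controls ≈ 1.5 years
higher), exercising covariate adjustment.

**Scales.** Per-block slopes and noise were chosen once so that the default
study lands at the performance scale typical of regional-feature brain-age
models: 10-fold CV MAE ≈ 5.6 y (GM), 3.1 y (WM), 2.9 y (multimodal) with
pooled ρ = 0.95–0.99.  GM features are individually weakly age-informative
but collectively predictive, while WM indices are individually strong; this
asymmetry makes nPAD-WM couple tightly with the latent case shift (powering
the phenotype analyses) while keeping per-feature background coupling in
the GM interaction scan small.

**Cases.** Each case carries a latent advanced-aging shift
Δᵢ ~ N(5, 3²) years, applied by evaluating the aging law at age + Δᵢ across
all features — the generative definition of "brain is older than its
chronological age".  Ten planted *interaction features* (cortical thickness
by default) respond to the shift with amplified gain,
value += 20·β_j·Δᵢ, so that only they co-vary with the shift beyond the
global aging law.  The gain of 20 was calibrated once so the planted
effects sit at Cohen's f² ≈ 0.08, the scale of the strongest reported
regional effects in this literature.  An earlier design that changed the
planted features' *age* slope in cases was discarded: a group-specific age
slope is collinear with the group×age population trend and loads
non-selectively on every age-dependent feature's interaction term under the
analysis model (which includes age but no age×group term); coupling the
planted features to the latent shift makes "distinct contribution to
advanced aging" identifiable per feature.

**Phenotypes** exist only for cases: PANSS negative score is generated with
correlation 0.5 to the standardized latent shift (FSIQ with −0.4); positive
and general scores share a 0.3 symptom factor with the negative score;
onset age is truncated-normal (23.4, 6.9) bounded below the subject's age,
duration = age − onset, and antipsychotic dose is truncated-normal
(312.8, 269.8) mg.  The `truth_delta_age` column and the recorded planted
feature names make every downstream recovery metric computable without
re-deriving the generative model.

**Determinism.** Each cohort draws from its own child of a single seed
sequence, so cohorts are independent of draw order and byte-identical under
a fixed seed; the `draw` argument redraws a cohort under the *same* feature
model, which is how the repeated-simulation tests vary the case/control
sample while holding the fitted reference instrument fixed.

**What the generator does not emulate:** site/scanner effects, missing
data, diagnosis uncertainty, non-Gaussian feature noise, spatial
correlation between neighboring ROIs, and medication-by-time confounds.
Passing tests demonstrate that the estimators recover what the generative
model plants at realistic sizes — not that real cohorts satisfy these
assumptions.

## Statistical analyses

- **Group ANCOVA**: OLS of the metric on group + covariates with a Type-II
  F-test of the group term (no interactions in the model, so Type-II equals
  Type-III).  nPAD comparisons adjust education; cPAD comparisons adjust
  sex and education (cPAD, unlike nPAD, does not normalize out the sex
  structure of predicted age), which costs one residual degree of freedom.
- **Paired modality test**: paired t with df = n − 1; zero-variance
  differences are reported as degenerate (t = 0 or ±∞) rather than raised.
- **Correlation comparison**: per-group Pearson ρ plus Fisher r-to-z for
  the between-group difference, z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)).
- **Sex differences**: Welch two-sample t within group (the robust default
  when the test is otherwise unspecified), unadjusted, with BH correction
  across the modalities within each group.
- **Outlier rule**: a subject is excluded iff any listed clinical field
  deviates from the *pre-exclusion* sample mean by more than 3 sample SDs —
  a single pass, so one gross outlier can mask a moderate one; the
  exclusion log records subject, field, value and z.
- **Phenotype regressions**: three model classes per nPAD outcome —
  clinical factors (duration + onset age + dose), symptom severity (three
  PANSS scores), FSIQ (controlling education).  Complete cases only, counts
  logged.
- **BH families**: the correction is applied within each analysis block —
  the modalities of a group comparison, the sex tests within a group, each
  phenotype model class across its named predictors and all outcomes (the
  education covariate is not part of the family), and all features within
  one interaction scan (124 GM / 90 WM).  The policy is configurable
  (`bh_policy`, `bh_scope`) because no single grouping is canonical; the
  default corrects within the block a reader would interpret together.
- **Interaction mapping**: per feature, OLS of npad on feature + group +
  feature×group + age + sex + education, pooled over cases and controls,
  with control = 0 / case = 1 coding so the interaction coefficient is the
  case-specific slope increment (this fixes the sign convention: declining
  features with case-amplified response yield negative coefficients, MD
  positive ones).  Cohen's f² = (R²_full − R²_reduced)/(1 − R²_full) with
  the reduced model dropping only the interaction term.  Volumes and
  thickness are both scanned for GM — no pre-filtering by feature type.
  Features are fitted in natural units; a standardized coefficient column
  is emitted for cross-feature comparison.  Output is ranked by f² (ties by
  name) because significance rank and effect-size rank can differ.
  The per-feature fits use closed-form least squares and are verified
  against a general-purpose OLS implementation to 1e-10.

p-values for plain correlations use the two-sided t approximation, with a
seeded permutation option that engages automatically below n = 30.

## Simulation design of the operating-characteristic tests

The z-scoring and bias-freeness properties refit the normative model per
seed (20 seeds at n = 500).  The offset-recovery, phenotype-power and
interaction-scan properties (200 draws each) fit the reference instrument
— predictor plus normative model — once and redraw only the case/control
cohorts, mirroring how a fixed normative model is deployed on new clinical
samples and keeping the suite's runtime in minutes.  Bias-freeness is
diagnosed on the cohort the normative model was fitted to (the reference
bias table of the framework): correlations of a *transferred* correction
with age on a second finite cohort carry an irreducible sampling floor of
SD ≈ 1/√n per component, which is a property of finite samples, not of the
correction.  The offset-recovery scenario disables the planted interaction
features: they amplify the predicted-age response beyond the pure shift,
and that scenario isolates pure advanced aging.  The recovered group mean
(≈ 0.85 of one local peer-SD) reflects the predictor's shrinkage slope —
the same attenuation any real brain-age model shows.

## Known limitations

- The GPR is homoscedastic; heteroscedastic or warped-likelihood normative
  variants are out of scope, so age-dependent error *variance* is captured
  only through the age-dependence of the posterior, not modeled explicitly.
- cPAD implements the slope-intercept residual form only (no quadratic
  variant).
- The cascade architecture's exact original layer sizes are not public;
  the implementation here is a declared standard reading of dense-skip
  cascade networks, and all of its dimensions are overridable.
- Multimodal interaction scans are supported but off by default; reported
  scans pair GM features with nPAD-GM and WM features with nPAD-WM.
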