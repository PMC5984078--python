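# Methods

This note records the statistical model, the simulator's generative
assumptions, the numerical choices and the known limitations of the package.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The two-stage design

The package implements a *coordinated* (prospective) meta-analysis: every
site fits the identical covariate-adjusted model on its own subjects and
exports only summary statistics; a central stage pools the per-site
estimates per ROI. No subject-level data crosses sites, and no mega-analysis
(pooled subject-level mixed model) is attempted — that is a deliberate
non-goal, matching how imaging consortia actually operate.

### Per-site models

The outcome is one of 25 skeleton measures (24 bilaterally combined JHU
tract ROIs + the whole-skeleton average) for one metric (FA, MD, AD, RD).
The case-control model is ordinary least squares on

    diagnosis + age_c + sex + age_c×sex + age_c² + age_c²×sex,

where `age_c` is age mean-centered *within site* before squaring. Centering
is our choice (it tames the strong collinearity between age and age²; the
consortium scripts do not document whether they centered) and changes only
the parameterization, not the diagnosis t statistic.

The diagnosis t is converted to Cohen's d with the consortium convention

    d = t·(n1+n2)/(√(n1·n2)·√df),    se_d = √((n1+n2)/(n1·n2) + d²/(2(n1+n2−2))),

the Hedges–Olkin large-sample form. Note that with no covariates this d
equals the classical pooled-s.d. d times exactly √((n1+n2)/df) — a ~1+1/n
inflation that vanishes asymptotically; the property test pins this relation.
No small-sample (Hedges g) correction is applied, again following the
convention. Sign: patients minus controls, so deficits are negative.

Moderator regressions run within patients only: outcome on moderator + sex
(+ the age terms, except for the duration-without-age model, kept as a
separate model id so the pooled stage can reproduce the attenuation contrast
when age enters). `duration_pct` is computed as duration/age. Subgroup
contrasts (smoker vs nonsmoker; pairwise medication classes) reuse the group
model with the subgroup indicator replacing diagnosis. Every model enforces
the inclusion cutoff of 10 complete cases per group; excluded site × model
cells are logged with the triggering rule, and the pipeline's
`provenance.json` records per-model contributing-site counts.

The dispersion comparison between groups (`variance_comparison`) defaults to
a two-sided variance-ratio F test, with a Brown–Forsythe/Levene option. The
comparison the source study describes ("independent t-test between s.d.
measures") is not specified precisely enough to reproduce; both variants are
labelled as our implementations.

### Pooling

Random-effects inverse-variance weighting with τ² from REML (default) or
DerSimonian–Laird. REML maximizes the restricted log-likelihood

    −½[Σ ln(vᵢ+τ²) + ln Σ 1/(vᵢ+τ²) + Σ wᵢ(yᵢ−μ̂)²]

by bounded scalar optimization (Brent, absolute tolerance 1e-10, boundary at
τ²=0 accepted when at least as likely); DL is the closed-form moment
estimator clamped at zero. REML is the default because it is the default of
the metafor-style tooling this stage emulates; DL is retained for
closed-form tests and speed. p-values are two-sided normal on z = pooled/se;
a Knapp–Hartung adjustment (scaled s.e., t reference with k−1 df) is
available but off by default, as it is not part of the emulated workflow.
I² is defined as max(0, 100(Q−(k−1))/Q), zero for k ≤ 1. Report tables sort
by |pooled estimate| descending with ties broken by ROI name. The primary FA
family uses the Bonferroni threshold α/m = 0.05/25 = 0.002; secondary
families apply the same per-family rule, our reading of an ambiguous
"correction for multiple comparisons".

## The simulator

One subject's value on measure r is

    y_r = μ_r + b_site + dx·(d_r + u_site)·σ_pool + f(age, sex) + extras + ε_r

* `μ_r`: control-group mean per measure (plausible JHU-scale FA values;
  these only locate the scale and never affect standardized effects).
* `b_site ~ N(0, site_location_sd²)`, default 0.01 FA units: scanner/protocol
  offsets. A multiplicative residual-scale jitter (`site_scale_sd`) exists
  but defaults to 0: a single scale draw would visibly perturb the
  within-site s.d. away from the printed calibration targets, and between-site
  heterogeneity is already carried on the d scale by τ.
* `u_site ~ N(0, τ²)`, default τ = 0.05, shared across measures within a
  site: between-site heterogeneity of the standardized effect.
* `f` is the quadratic age trend with sex interactions given in the README;
  defaults produce a gentle decline (~0.005 FA over 25 years) plus a small
  male offset — the minimal structure under which the per-site covariate
  model is correctly specified.
* `extras` collects optional injections: moderator slopes on FA
  (mean-centered, patients only), a diagnosis-by-age slope, an extra
  standardized deficit for female patients (`sex_d_shift`) and for smokers
  (`smoker_d`). All default to 0.
* `ε` is Gaussian with compound-symmetric correlation ρ = 0.5 across the 25
  measures (whole-skeleton FA must covary with tract ROIs; the true
  cross-ROI correlation structure is unreported, so a single exchangeable ρ
  is exposed in config).

**Variance calibration.** The residual s.d. per group is solved, not set:
var(ε) = target² − var(deterministic covariate structure), where the target
marginal s.d.s of whole-skeleton FA default to the published dispersions
(0.0194 controls, 0.0176 patients) and the covariate-effect variance is
measured by a fixed-seed Monte-Carlo quadrature over the group's (age, sex,
moderator) sampling distribution (200 000 draws; the solve is deterministic
given the config and cached). Configurations whose covariate effects exceed
the target variance are rejected. We subtract covariate-effect variance
only, not site-intercept variance: the published dispersions describe
within-group spread at the per-site stage, and site offsets add between-site
variance on top. Injected diagnosis shifts are scaled by
σ_pool = √(mean of the two groups' *analysis-scale* residual variances)
(target² − model-explainable variance), so that the covariate-adjusted
pipeline recovers the configured d. Constant-within-group shifts add no
within-site variance, so the calibration survives nonzero `true_d`;
`sex_d_shift`/`smoker_d` do add within-group variance and slightly inflate
the patient s.d. when used.

**Demographics and clinical moderators.** Control age is a truncated normal
(mean 36, s.d. 12, range 18-80). Patient age is built as onset + duration:
onset is a lower-truncated normal (s.d. 5, floor 13) whose location is
solved numerically so the *truncated* mean equals 23 exactly; duration is
gamma (mean 14, shape 2). This makes onset/duration/age exactly consistent
and duration collinear with age by construction — which is what lets the
pipeline reproduce the qualitative attenuation of the duration-FA
association once age enters the model, with all moderator slopes at their
default 0. CPZ is gamma with mean 371.23 (shape 4, i.e. CV 0.5), drawn for
medicated patients only; symptom scales are normals at the published means
(dispersions are our choice), clipped at 0; medication classes are
multinomial 71/6/10/13%; smoking is Bernoulli(0.5), consistent with the
near-even published smoker/nonsmoker split. Only a configurable fraction of
sites records each moderator family (site-level missingness mirroring the
varying per-analysis cohort counts, e.g. duration at ~20 of 29 sites, CPZ at
~10); controls have all clinical fields missing.

Per-site group sizes default to uniform draws on [20, 250] per group —
spanning the cohort-size range of the emulated consortium without copying
any site's actual n. Diffusivity metrics (MD/RD/AD) are generated with
stylized effects (MD/RD elevated in patients across ROIs, AD null except the
fornix), a linear age slope and the same machinery; their absolute scales
are plausible but not calibration targets.

**What the simulator does not emulate.** No images, tensors, registration or
skeleton-projection error; no scanner-protocol confounds beyond site
location shifts; subject-table measure columns (including core/periphery FA
and the compound ROIs CC/CR/IC) are generated marginally, so the exact
voxel-count reconstruction identity and compound-ROI consistency hold only
in the voxel-level `skeleton` module, not across subject-table columns.
Passing tests therefore demonstrate the *statistical* correctness of the
two-stage pipeline under a correctly specified additive model — not
robustness to registration artefacts, non-Gaussian tails, or model
misspecification in real cohort data.

## Skeleton module

ROI summaries operate on flat labelled vectors: per-ROI means are arithmetic
means over labelled voxels, hemispheres combined by voxel-count weighting
(equal to the mean over the union — the reason this, and not the average of
hemisphere means, is the right combination rule). Compound ROIs are
voxel-count-weighted unions; the core/periphery decomposition satisfies
n_total·average = n_core·core + n_periphery·periphery exactly, with an empty
periphery reported missing (never zero). The real skeleton template
(112 889 voxels) is not shipped; a synthetic atlas with
template-proportional ROI sizes (default 2000 voxels, minimum 2 per ROI) is
generated for tests, with callosal segments and fornix treated as midline
(unpaired) structures.

## Numerical choices and degenerate inputs

* Exact OLS for the all-ROI site stage is computed by a single shared
  normal-equations solve per site (one design matrix, 25 outcome columns);
  a test pins agreement with statsmodels per-ROI fits to 1e-10.
* Rank-deficient designs raise an error naming the collinear columns (e.g. a
  single-sex site with sex terms requested); sex-stratified analyses use
  `CovariateSpec(sex_terms=False)`.
* k = 1 meta-analysis degenerates to the single study with τ² = Q = I² = 0;
  zero-length input and non-positive standard errors raise errors naming the
  offending record.
* CSVs are written with 17 significant digits and read with
  correctly-rounded parsing (`float_precision="round_trip"`), so write-read
  round-trips are bit-exact.
* Determinism: all simulation randomness flows from a single integer seed
  through one `numpy` generator; identical configs produce byte-identical
  tables, and the variance-calibration quadrature uses its own fixed
  internal seed so calibration is a function of the config alone.

## Problem sizes used in validation

The recovery checks simulate the full 29-cohort design (20-250 per group,
τ = 0.05) and average the pooled estimate over 20 seeds; type-I control uses
200 replicate null meta-analyses of the same design; calibration checks use
5000 subjects per group at a single site. These sizes make Monte-Carlo error
comfortably smaller than the tolerances being checked (±0.02 on recovered d,
±0.0005 on calibrated s.d.s) while keeping the whole suite to about two
minutes.

## Known limitations

* The d-from-t conversion inherits the consortium convention's √((n1+n2)/df)
  factor and applies no small-sample bias correction; at the smallest
  allowed sites (n = 10-20 per group) recovered |d| is biased upward by
  roughly 2%, largely cancelled in pooled estimates by the covariate-overlap
  attenuation below.
* Covariate-adjusted d is attenuated by √VIF when group covariate
  distributions differ (patients and controls have different age
  distributions by construction), an inherent property of adjusted
  standardized effects rather than an implementation artefact; at the
  default calibration the net pipeline bias is well inside the ±0.02
  recovery tolerance.
* The normal-approximation z test on pooled estimates is mildly liberal at
  small k; Knapp–Hartung is provided but not default.
* The exact τ² estimator, CI method and dispersion test of the emulated
  study are unreported; estimator choices here are validated by recovery
  simulation and by cross-checks against independent implementations
  (statsmodels, metafor), not by matching published p-values.
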