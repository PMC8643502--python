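# Methods

This note documents the statistical model behind the package, the
choices made where the design was genuinely open, what the synthetic
cohort emulates (and does not), and the numerical details a user needs
to interpret or reproduce results.

## Standardization

Volumes of each cortical area are converted to Z-scores using the mean
and sample SD (ddof = 1) of the *baseline* volumes across datasets, and
change is measured as `Δz(t) = z(t) − z(0)` within a dataset. The
baseline pool for an area includes both hemispheres of unilateral
datasets (target and reference). This is deliberate: the target change
and the reference band then share one per-area scale estimate, so
per-area noise in the estimated baseline SD cancels between the two
sides of the comparison. Standardizing the roles separately leaves a
multiplicative scale mismatch between the observed target change and
the band fitted on reference data and measurably inflates the null
flag rate.

Degenerate inputs are rejected with the offending area named: a missing
or duplicated baseline record, fewer than two baseline datasets, or
zero baseline variance.

## Reference model

Per area, reference-hemisphere follow-ups are fitted with an
intercept-free linear mixed model

    Δz_ij = (β + b_i)·t_ij + ε_ij,  b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²)

There is no intercept because change at baseline is zero by
construction, and consequently the subject-level random effect is a
slope on time, not an intercept (a random intercept would contradict
the zero-at-baseline constraint). Estimation is maximum likelihood
(not REML), so nested fits remain comparable; the variance ratio
γ = σ_b²/σ_e² is profiled out — given γ, the fixed slope is a
generalized-least-squares solve and σ_e² has a closed form, leaving a
one-dimensional bounded search over γ with the boundary γ = 0 checked
explicitly. Per-subject covariance matrices are rank-one updates of the
identity, so each likelihood evaluation is linear in the number of
observations; a full cohort of 60 area fits takes tens of milliseconds,
which is what makes the 200-cohort calibration experiments cheap. The
fit exposes empirical-Bayes subject effects (BLUPs) and their
conditional variances for conditional prediction.

Degenerate branches: a single observation is fitted by exact
interpolation (β = Δz/t, σ_b = σ_e = 0) and flagged; exactly collinear
(noise-free) data return the closed-form slope with zero variances.
When every subject has a single follow-up the variance split is
unidentifiable (the profile likelihood is flat in γ); the fit resolves
to γ = 0, which leaves the *total* predictive variance — the quantity
the bands use — well defined.

A cross-check against an independent general-purpose mixed-model
implementation (statsmodels MixedLM, ML) is part of the test suite: the
profiled optimum must match its parameters and not be beaten in
log-likelihood.

## Prediction bands and atrophy calling

For a new observation at time t the predictive variance is

* marginal: `t²·se_β² + t²·σ_b² + σ_e²`
* conditional: `t²·se_β² + t²·Var(b_i | data) + σ_e²`, centered at
  `(β + b̂_i)·t`

The slope-estimation term `t²·se_β²` is included by default and can be
dropped (`include_fixed_uncertainty=False` / `--no-fixed-uncertainty`).
Unilateral datasets are judged with conditional bands — the subject's
own reference data estimate b_i — and bilateral datasets, which have no
reference hemisphere, with marginal bands. When σ_b = 0 the two modes
coincide.

**Quantile family.** Band limits default to Student-t quantiles with
`n_subjects − 1` degrees of freedom rather than standard-normal ones.
With ~20 reference cases contributing ~1.5 follow-ups each, the
estimated scale σ̂ carries roughly between-subject information only: its
effective degrees of freedom sit near the subject count, and plug-in
normal quantiles are then markedly anti-conservative. Measured on
atrophy-free synthetic cohorts at the default conditions, normal
quantiles give a per-area lower-tail exceedance of ≈0.0026 against a
nominal 0.00069 and a per-dataset ≥1-flag rate of ≈0.14 against the
α = 0.05 bound; t quantiles with df = n_subjects − 1 restore the rate
to ≈0.045 (nominal construction value 0.0417). The family and df are
recorded in each fit and in the run report, and `quantile_family:
normal` remains available in the run config.

Multiplicity is Bonferroni over datasets (m = number of datasets, 36 at
the default design; configurable as `fixed:<m>`): adjusted two-sided
coverage `1 − α/m`, hence the 99.86% PI at α = 0.05, m = 36, and the
per-test threshold 0.05/20 = 0.0025 for the reference-area tests with
20 reference cases. A target area is atrophic iff its observed Δz at
the dataset's *last* follow-up is strictly below the lower limit —
a value exactly on the limit is not called. The sweep repeats the
calling at nominal levels 95/90/80/70/60/50%, each Bonferroni-adjusted;
per-dataset counts are non-increasing in the level by band nesting.

Reference-area change tests (slope = 0, and a baseline-volume × time
interaction) use Wald statistics on the same t reference distribution;
areas where no subject has two follow-ups report missing p-values with
a degeneracy flag.

## Lesion topography maps

Group membership: a dataset joins a lobe group iff it has ≥1 atrophic
area in that lobe (non-exclusive; no-atrophy datasets join nothing;
bilateral patients contribute each dataset's mask separately). Per
group, the probability map is the voxelwise fraction of member masks
containing the voxel; the ratio map divides it by the overall
stroke-location probability map. Voxels with zero overall probability
have undefined ratios: they are set to 0 and recorded in an explicit
undefined-support mask rather than NaN. Ratio maps are smoothed with a
separable Gaussian, σ = FWHM/(2√(2 ln 2)) (2.1233 mm at FWHM 5 mm)
converted to voxel units per axis from the affine, with reflection
padding so total mass is preserved (≤1e-6 relative error); the
probability maps themselves are left unsmoothed, following the stated
order of operations (ratio first, then smoothing). The combined map
assigns each voxel inside the overall-map support to the lobe with the
highest smoothed ratio; exact ties are broken deterministically in the
fixed order frontal, occipital, parietal, temporal and flagged in a tie
mask; voxels outside the support, or where all ratios are zero, are
background. Every stage is checked against brute-force per-voxel
recomputation on toy grids.

I/O is NIfTI-1 via nibabel; masks must be binary (values other than
{0,1} are rejected unless explicitly binarized at 0.5), NaNs are
rejected with a count, and the combined map ships with a JSON code
legend.

## Outcome models

The number of atrophic target areas per dataset is fitted with a
log-link Poisson GLM. Overdispersion is handled by Pearson-based
quasi-likelihood: φ = X²/df_resid, all standard errors scaled by √φ,
point estimates untouched; Wald CIs and p-values on the corrected
scale. (Negative-binomial models are out of scope.) Continuous
covariates — follow-up time, baseline cortical volume (10 ml units),
age — are centered on the cohort mean, so main effects are interpreted
at mean covariates; centering leaves interaction RRs unchanged.
Stratum-specific effects (volume within unilateral vs bilateral) come
from a nested reparameterization of the interaction model: the two
stratum slopes enter as direct coefficients while shared covariates
stay in the model. The joint log-likelihood is identical to interaction
coding, and without shared covariates the stratified estimates equal
separate per-stratum fits.

The 3-month mRS is fitted over its observed levels with a
proportional-odds cumulative-logit model,
`P(Y ≤ k) = logistic(c_k − x'β)`, so OR = exp(β) is the odds of a
one-category-worse outcome per unit predictor. Baseline severity enters
dichotomized (mRS 0–2 vs ≥3; NIHSS <6 vs ≥6), and the atrophy-count
effect is stratified by the dichotomized baseline via the same nested
coding. Stroke volume is excluded from this model as a mediator-like
confounder of the atrophy count, and lesion side/baseline cortical
volume are excluded against multi-collinearity; the default term lists
encode these exclusions but are overridable. The proportionality of
odds is inspected, not auto-judged: for every cumulative split Y ≥ k a
binary logistic model with the same terms yields an OR per predictor
per level; unstable levels (perfect separation at extreme splits) are
flagged in the table. On a two-level outcome the proportional-odds fit
reduces exactly to logistic regression.

## Synthetic cohort generator

Defaults reproduce the study conditions: 22 unilateral + 7 bilateral
patients (36 hemisphere-level datasets), 60 areas per hemisphere with
the packaged lobe partition (22/12/14/12), follow-up counts drawn
17:11:1 for 1:2:3 scans with times uniform on 0.75–12 months, lesion
volumes lognormal targeting the 5.4 (SD 8.7) ml scale (clipped to what
the 40³ mm template box holds, so the realized mean is ~3–4 ml), and a
median of ~1.5 injected atrophic areas per dataset.

Trajectories: per-area baselines are Normal(8, 1.2) ml across datasets;
follow-up change on the Z scale is `(slope + b_subject)·t + ε` with
slope −0.005 z/month (slow ageing drift), σ_b = 0.01 z/month,
σ_e = 0.25 z — the subject slope is shared across areas and both
hemispheres, which is exactly the intra-subject reference rationale the
conditional bands exploit. Atrophy (−2 z by default) is injected in
randomly chosen target areas at the last follow-up only, matching the
"change at last follow-up" evaluation; progressive loss is not
modelled. The injected-area count is Poisson, with a log-linear lesion
volume link in the bilateral arm (`volume_count_link`; the RR 1.08/ml
scenario) and a flat rate in the unilateral arm. Lesions are ellipsoids
with seeded anisotropy jitter whose voxel count equals the requested
volume (error ≤ one voxel volume), template x < 0 being left; the
target hemisphere is contralateral to the lesion. Clinical scores use a
latent-logistic proportional-odds construction: baseline mRS has median
2, and the 3-month mRS latent predictor is
`2.0·[mRS₀ ≥ 3] + ordinal_link_beta·count·[mRS₀ ≥ 3] + Logistic(0,1)`
categorized at fixed cutpoints. The latent model conditions on the
*dichotomized* baseline — the same covariate the shift analysis
adjusts for — so the generator's coefficient is exactly the estimand of
the stratified fit (using the raw 0–5 baseline in the latent scale
would attenuate the recovered OR through unmodelled heterogeneity,
logistic effects being non-collapsible).

What the generator does **not** emulate: realistic cortical geometry or
image intensities, measurement error at baseline distinct from
between-subject variation, progressive (multi-timepoint) atrophy,
spatially realistic lesion shapes or a cerebellar anatomy prior, missing
data, or scanner/sequence heterogeneity. Passing tests therefore show
that the statistics behave as designed under the assumed data model,
not that the pipeline is robust to violations real data may present.

## Problem sizes for validation

The calibration and recovery experiments use: 200 atrophy-free
study-sized cohorts for null calibration (rate compared against
α + 3·MC-SE, with the MC-SE over cohort means because datasets within a
cohort share fitted bands); 100 replicates at 200 subjects for
reference-model recovery (3 MC-SE unbiasedness bands); 500 replicates
of 100 bilateral datasets for quasi-Poisson CI coverage at RR 1.08/ml;
and 200 replicates of 150 patients for stratified ordinal CI coverage
at OR 1.34/area. These sizes give the Wald intervals a fair asymptotic
footing while keeping the full suite around three minutes on one CPU.

## Known limitations

* The Bonferroni multiplicity follows the study design (over datasets,
  not over the 60 areas per dataset); family-wise control is per
  dataset, with the per-dataset ≥1-flag probability ≈ 60·α/(2m) under
  the null, not over the whole area × dataset family.
* Wald inference throughout (symmetric CIs on the log scale); no
  profile-likelihood or exact small-sample intervals.
* The t degrees of freedom `n_subjects − 1` are a pragmatic choice for
  an ill-posed mixed-model df problem; they calibrate well at the
  default design but are not exact.
* Complete-case handling of clinical scores; no imputation.
* mRS is modelled over observed levels only; unobserved categories are
  collapsed.
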