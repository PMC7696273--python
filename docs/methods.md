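# Methods

`resifc` implements a seed-based *residual* functional-connectivity
analysis for a fatigue-inducing working-memory experiment, together with a
synthetic-data generator that plants a known, fatigue-modulated coupling so
every stage of the analysis can be validated end to end.

## The experimental design being emulated

Two groups (multiple sclerosis, n = 26; healthy controls, n = 14) perform
an n-back task in the scanner under two loads: 0-back (control) and 2-back
(fatigue-inducing). Each condition comprises four runs of 65 letter trials
(1.5 s stimulus + 0.5 s base inter-trial interval). Six null events, each a
multiple of the 2-s trial length, are inserted at random gaps between
trials so that the total timeline closes an exact 260-s budget; this
jitters the inter-trial intervals for event-related deconvolution. The
scanner acquires 140 volumes per run at TR = 2 s. State fatigue is measured
on the 0-100 Visual Analogue Scale of Fatigue (VAS-F) five times per
condition: before the first run and after each of the four runs.

## Analysis model

**First-level deconvolution.** The four runs of one condition are modeled
jointly. The single task regressor is built from trial onsets with *unit
amplitude for every trial*, convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6; the field's default shape).
Regressors of no interest are run-blocked: per-run Legendre drift up to
order 3 (a discrete-cosine alternative was considered but polynomials are
the simpler basis with equivalent span at these run lengths), the six
motion parameters and their temporal derivatives, framewise displacement,
and the CSF / white-matter / global mean signals with derivatives. Because
the task regressor is amplitude-invariant, only stable task activation is
absorbed; any fatigue-varying signal remains in the error term. The model
is fitted by per-voxel OLS (no prewhitening: an AR noise model would
change standard errors of task betas, which are never used downstream —
only the residuals matter). Residuals are certified orthogonal to every
design column. Collinear nuisance columns (which arise in degenerate
noise-free simulations) are pruned greedily with a warning before fitting.

**Seed connectivity.** A seed is a 4-mm-radius sphere around an MNI mm
centre; a voxel belongs to the seed when its centre lies within the
radius. The five default seeds are DLPFC (44, 32, 36), vmPFC (-6, 46, -6),
dACC (-4, 20, 46), insula (34, 22, 0) and striatum (18, 12, 0). Per run,
each voxel's residual series is expressed as percent signal change against
that voxel's raw run mean, averaged over the seed, correlated with every
voxel's residual series, and Fisher-transformed (z = atanh r, r clamped at
1 - 1e-7). Correlations are computed run-wise — not on the concatenated
condition — because the group model includes run as a factor, which is
only estimable from run-wise maps.

**Behavioral arm.** Run-level fatigue is the mean of the ratings
bracketing the run; runs with both ratings exactly zero are excluded
(nothing to correlate). Retained run means are Box-Cox transformed, with
lambda maximizing the profile likelihood on [-2, 2], estimated once on the
pooled retained values (a per-group lambda would make the transformed
scales incomparable in the joint model). Transformed fatigue, accuracy and
response time are analyzed with random-intercept linear mixed models (REML)
with group x condition x (run or fatigue) fixed effects. Degrees of
freedom use the Satterthwaite approximation throughout, including the post
hocs (one df method everywhere; Kenward-Roger is materially identical at
these sizes). Pairwise post hocs compare estimated marginal means — or
covariate slopes — with Tukey adjustment via the studentized-range
distribution.

**Group inference.** Per seed and per group (groups are never pooled),
every retained run contributes one z-map with condition, run and the
group-mean-centred transformed fatigue score. Per voxel the model

    z ~ condition + fatigue + condition:fatigue + run + (1 | subject)

is fitted by REML; the reported map is the condition-by-fatigue
interaction, the difference of fatigue slopes (2-back minus 0-back),
positive where connectivity rises with fatigue more under high load. Run
enters as a categorical factor (4 levels). A voxel whose subject variance
estimate hits the zero boundary degrades gracefully to OLS; the count of
such voxels is logged, never silent. The signed Z map converts the
two-sided interaction p-value back to a normal quantile carrying the
estimate's sign, matching the reporting convention of the cluster tables.

**Cluster-extent correction.** Spatial smoothness is estimated from
standardized residual maps via first differences: for each axis,
FWHM = 2 d sqrt(ln 2 * var / var(diff)) at voxel size d, averaged over
maps (white noise yields the estimator floor d sqrt(2 ln 2) ~ 1.18 d).
Null Gaussian fields at that smoothness are simulated (white noise
smoothed with a padded Gaussian kernel and re-standardized), thresholded
two-sided at the voxelwise p (default 0.001), and the maximal cluster
extent recorded per simulation. The extent threshold k is the smallest
extent whose empirical exceedance probability, *inflated by one binomial
standard error*, is at most the corrected alpha (default 0.05). The
standard-error margin makes boundary cases round conservative, so the
procedure delivers the FWE <= alpha guarantee it claims instead of
straddling it; the margin is configurable (`margin_se=0` recovers the
plain point estimate). Default connectivity is faces-only (NN1), the most
conservative rule; NN2/NN3 are available. Positive and negative
suprathreshold voxels are clustered separately; each cluster's peak is the
voxel of maximal |Z| (ties: smallest linear index), reported in mm.

## The random-intercept REML engine

The group model must be fitted at every voxel, so the mixed-model core
(`resifc.lme`) profiles the REML criterion over the variance ratio
lambda = sigma_u^2 / sigma_e^2. Because the random-effects structure is a
single intercept per subject, whitening, log-determinants, and the REML
information matrix all reduce to per-subject scalar aggregates; thousands
of voxels sharing one design are fitted with a few matrix products per
candidate lambda (81-point log grid plus the OLS boundary; single-response
fits refine the grid optimum by bounded scalar minimization). Satterthwaite
df for a contrast are computed from the analytic REML information of
(sigma_e^2, sigma_u^2); for this model the df depend only on the design and
the selected lambda, so they are shared across voxels. The engine matches
statsmodels MixedLM (estimates, variances, REML log-likelihood) to ~1e-6
and R lmerTest (Satterthwaite df) to ~0.2% on frozen fixtures.

## The synthetic generator

Each simulated run is

    baseline (100)
  + task amplitude x (onsets * HRF)          - identical in every run
  + per-run polynomial drift
  + shared global physiological fluctuation  - amplitude 0.5
  + latent seed/target coupling
  + spatially smoothed Gaussian noise

The planted coupling injects a smoothed unit-variance latent l(t) into the
seed region and w l(t) + sqrt(1 - w^2) m(t) into the target region, with
w = intercept + slope(condition) x fatigue (fatigue on a fixed standardized
log scale of the run-mean VAS-F, so ground truth never depends on a fitted
quantity). The generator refuses |w| >= 1. Motion is a random walk with
occasional spikes so the FD/DVARS outlier rules are exercised; confound
tables are computed from the true motion and the simulated data. Only the
independent noise component is spatially smoothed (then rescaled), so
smoothing cannot dilute the planted correlation. VAS-F scores are built on
a latent scale (baseline 12, MS offset +26, small MS-specific 2-back
offset -2.7, accumulation +2 per rating, noise SD 8 — matching the
reported group medians of ~38 vs ~12) and clipped to [0, 100]; clipping
rather than resampling is the simplest monotone choice. Behavioral
accuracy uses the reported slope structure (HC 2-back +0.021, MS 2-back
-0.016 per transformed-fatigue unit) and response time the reported
+148 ms 2-back cost.

The **global fluctuation** deserves a note: on a desk-scale grid the
planted regions are a visible fraction of all voxels, so without a genuine
shared global component the global-signal regressor becomes a proxy for
the planted latents and regression destroys the planted coupling — an
instance of the well-known fact that global signal regression removes
coherent neural signal. With a realistic shared component the regressor
removes that component, as intended, and leaves the plant intact.

What the generator does *not* emulate: anatomy (tissue masks are nominal
corner blocks), scanner physics, physiological noise spectra,
between-region connectivity beyond the single planted pair, and the exact
inter-trial-interval moments of the original optimized schedules (the
optimizer's parameters are unpublished; the jitter sampler reproduces the
design constraints, not those moments). Passing tests therefore certify
the *estimators* — not robustness to artifacts absent from the generator.

## Validation studies and problem sizes

- **FWE calibration**: 24^3 grid of 3-mm voxels, 6-mm FWHM nulls, voxel
  p < 0.001 two-sided, 1000 calibration + 1000 independent evaluation
  simulations; empirical FWE is required to stay within alpha plus two
  Monte-Carlo standard errors (typical values 0.03-0.05).
- **Pipeline recovery**: 20 replicates of 20 subjects on a 14^3 grid
  (4-mm seed sphere, 6-mm target sphere on opposite sides), planted 2-back
  slope 0.5 per generator-fatigue unit, noise SD 0.2 (chosen so the
  ~2% correlation-attenuation bias is negligible against the interaction
  SE), and a steep within-session fatigue ramp so the slope separates from
  the run factor. The recovered slope is compared with the implied
  Fisher-z estimand — the OLS projection of atanh(planted r) onto the
  analysis design — because the group model estimates slopes on the z
  scale against the Box-Cox covariate while the plant is stated in
  correlation units on the generator scale.
- **Behavioral recovery**: 200 subjects per group recovers the planted
  group effect and 2-back slope difference within their 95% CIs; 200 null
  simulations keep the Tukey-adjusted familywise rejection rate of the
  slope contrasts at or below nominal.

These problem sizes are the package's own validation designs: large enough
for the estimators' sampling error to be small against the planted
effects, small enough to run on a single CPU in minutes.

## Known limitations

- Only a single random intercept per subject is supported (no random
  slopes, no crossed effects); that is exactly the structure the analysis
  prescribes, but the engine is not a general mixed-model solver.
- OLS first-level (no AR(1) prewhitening); residual autocorrelation
  inflates neither the connectivity estimates nor the group model, which
  treats maps, not time points, as observations, but voxel-p thresholds in
  the time domain would need prewhitening.
- The smoothness estimator assumes an approximately Gaussian
  autocorrelation; heavy-tailed spatial ACFs (observed in real fMRI) would
  need the mixed-ACF refinement of newer ClustSim variants.
- The vectorized lambda grid resolves the variance ratio to ~12% per step;
  single-response fits refine continuously. Contrast estimates and df vary
  smoothly in lambda, so the grid error is far below sampling error.
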