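# Methods

## Signal model and processing chain

Surface EMG is modelled at the amplitude level only: each channel of a
trial is zero-mean Gaussian noise band-limited to 10–400 Hz whose RMS
envelope is piecewise-constant over the four 3-s task phases. This is not
a motor-unit or biomechanical simulation; it is the weakest model that
makes every downstream statistic (RMS, normalization, centroid, DISTANCE,
regression coefficients) well defined and recoverable, which is all the
pipeline consumes.

Processing follows standard surface-EMG practice:

- **Filtering.** 4th-order Butterworth band-pass, 10–400 Hz, applied
  forward–backward (`sosfiltfilt`), i.e. zero phase, so the fixed 3-s
  phase windows stay aligned with the signal. Passband gain is unity to
  within 1% and DC/movement artefact below 10 Hz is suppressed by more
  than 40 dB (two-pass). Inputs shorter than the filter's edge-padding
  length are rejected with the minimum length named.
- **Segmentation.** The task is auditory-cued at fixed 3-s intervals, so
  phases are exact half-open 3,000-sample blocks from trial onset; no
  onset detection is attempted.
- **RMS and normalization.** RMS per (phase, channel) cell; experimental
  values are divided, per channel, by that channel's extension-phase RMS
  in the reference trial. Per-channel (rather than pooled) normalization
  preserves the spatial profile for the centroid while making activity
  dimensionless. Self-normalization yields exactly 1.0 on the extension
  row, and normalized extension activity sits near 1.0 ± a few percent,
  matching the scale a normalized-EMG reader expects.
- **Noise exclusion.** A cell is masked when it deviates from its phase's
  cross-channel median by more than 5 median absolute deviations. The rule
  stands in for manual rejection of channels whose noise could not be
  removed; masked cells keep their values but are skipped by the centroid,
  the activity mean, and normalization denominators. With 8 channels the
  MAD is coarse; the threshold is deliberately permissive so only gross
  artefacts (orders of magnitude) are dropped.

## Geometry

Each side is one cranial–caudal column of five electrodes, 2.5 cm apart,
wired as four bipolar channels; a channel sits at its electrode pair's
midpoint, so channels lie at 1.25, 3.75, 6.25 and 8.75 cm from the sheet
top — the same origin as the pain-site measurement, which keeps centroid
and pain site in one coordinate frame. A 2-D (medio-lateral) grid reading
of the montage is possible, but only the cranial–caudal axis is analysed,
so the 1-D column is used throughout. Excluded channels are dropped from
the centroid (not imputed).

## Synthetic cohort

Defaults (23 patients, 3 experimental trials, 1 reference trial) emulate a
CLBP outpatient cohort: pain site from a ≥0-truncated normal whose mean is
exactly the configured 15.0 cm (the location parameter is solved for,
since naive truncation at 0 would bias the mean by ~0.4 cm at SD 7.3);
NRS from a rounded normal (4.7 ± 2.1) clipped to [1, 10] so all simulated
patients meet the NRS ≥ 1 inclusion rule; item scores zero-inflated
(p₀ = 0.5, reproducing the strong right skew of rarely-endorsed qualities)
with the non-zero component centred at mean/(1−p₀) so configured means are
*marginal* means.

The encoded mechanism is suppression near the pain site: channel weights

    w(y) = A · (1 − s · exp(−(y − y_pain)² / (2·width²))),

with width 5 cm and s = clip(Σ_k c_k·score_k / 10, 0, 0.95) linear in the
pain scores — the simplest mechanism whose ground-truth coefficients a
linear model can recover. Default drivers are the neuropathic subclass
(c = 0.4) and intermittent subclass (c = 0.2). The reference trial is
generated suppression-free so normalization has a clean denominator.
Phase amplitude factors (0.4, 0.8, 0.3, 1.0) sketch postural holding,
eccentric lowering, flexion–relaxation, and the agonist extension phase.

What the generator does *not* emulate: motor-unit structure, crosstalk,
electrode-skin artefacts, movement-speed variability, correlation between
pain scores and pain-site location, and within-patient day-to-day
variation. Passing tests therefore demonstrate that the pipeline recovers
the encoded amplitude-level mechanism, not that real CLBP data would show
it.

### The sign-recovery scenario

On a 10-cm grid the suppression kernel can displace the extension-phase
centroid by at most ~1.7 cm, while pain sites scattered with SD 7.3 cm
move DISTANCE by many centimetres irrespective of any motor adaptation; at
n = 23 the DISTANCE effect direction is then undetectable by construction.
The direction-of-effect scenario (`sign_recovery_config`) therefore
isolates the mechanism: suppression driven only by "pain caused by light
touch" (coefficient 1.5, marginal item mean raised to 3), pain sites
clustered just caudal of the grid (9.0 ± 0.75 cm) where the kernel's
centroid displacement is largest. This is a designed identifiability
condition, not a claim about clinical cohorts — in real data, DISTANCE
associations additionally require pain quality and pain location to be
suitably distributed.

## Inference

Ten Gaussian random-intercept models (5 predictor sets × 2 outcomes) are
fitted to *trial-level* outcomes (3 per patient). Trial-level observation
units make the participant intercept identifiable — with one observation
per patient, τ² and σ² are confounded; the trial-averaged patient-level
outcomes are still produced for descriptive tables. Predictors and
responses are z-scored (scores 0–10 or 0–60 and distances in cm would
otherwise put coefficients on incomparable scales); coefficients are
reported on that unitless scale. NRS can be added as a covariate
(`include_nrs_covariate`) but defaults off, as the headline report tables
carry only pain-quality rows.

Priors are proper but effectively flat and fully conjugate:
β ~ N(0, 10⁶·I), σ², τ² ~ InverseGamma(10⁻³, 10⁻³). The sampler is a
blocked Gibbs scheme: (β, u) drawn *jointly* from their Gaussian full
conditional given (σ², τ²), then σ² and τ² from inverse-gamma full
conditionals. The joint block matters: pain-quality predictors are
constant within participant, so β and u are nearly collinear a posteriori
and alternating β | u and u | β updates mix pathologically slowly at the
study's chain lengths; the joint draw removes that coupling at the cost of
one (p+G)-dimensional Cholesky per sweep (28×28 here — negligible).
Over-dispersed initialization is applied to the variances
(log-normal jitter around the OLS residual variance and the
between-patient residual variance); (β, u) need no explicit start because
the first sweep draws them from their full conditional.

Numerical conventions:

- chain seeds spawn deterministically from one integer seed (`SeedSequence`),
  so identical settings reproduce identical draws;
- split-R̂: each chain halved, R̂ = sqrt(((n−1)/n·W + B/n)/W); computed for
  every sampled parameter including random intercepts and variances;
  required < 1.1; degenerate (constant) chains raise, except in the
  summary path where R̂ is reported as NaN;
- posterior "Estimate" is the pooled posterior mean; intervals are
  equal-tailed 95% with linear-interpolation quantiles;
- an association is "credibly nonzero" when its 95% CI excludes 0;
- a predictor constant across the cohort (possible for rarely-endorsed
  items in small zero-inflated cohorts) cannot be z-scored; it is dropped
  from that model's design and reported as a NaN row, rather than failing
  the run;
- rank-deficient designs and non-finite responses are rejected with the
  offending columns named.

## Validation design

The test suite checks, at reduced chain lengths where replication is
needed (2 chains × 1,500 iterations, 500 burn-in; the full study settings
are used for the convergence check itself):

- exact hand-computed oracles for RMS, segmentation, normalization and
  centroid arithmetic;
- the fixed-effects sampler against the closed-form flat-prior
  normal–inverse-gamma posterior (within Monte-Carlo error);
- 95% credible-interval coverage of known coefficients under the exact
  mixed model (200 replicates, 23 × 3 design);
- sign recovery of the light-touch effects in ≥ 90% of 20 scenario
  replicates;
- calibration on null cohorts: ~5% of subclass coefficients flagged
  credibly nonzero over 100 replicates;
- full-settings convergence: max split-R̂ < 1.1 across all parameters of
  the subclass model on a default cohort.

## Known limitations

- Amplitude-level EMG model only; spectral content is a single shaped
  band, so frequency-domain analyses would be meaningless on these data.
- The exclusion rule is the package's own convention; real studies
  typically reject channels by inspection.
- The Gibbs sampler assumes the Gaussian identity-link model; no other
  GLMM families, and no NUTS/HMC, model comparison (WAIC/LOO) or
  posterior-predictive checking are provided.
- With 23 participants, τ² is estimated from few groups and its posterior
  is sensitive to the (weak) inverse-gamma prior in near-null data — a
  generic small-sample caveat, not specific to this implementation.
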