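# painmap

Surface-EMG spatial analysis of the lumbar erector spinae in chronic low
back pain: per-phase RMS mapping on bilateral electrode grids, the
centroid of the muscle-activity distribution, its DISTANCE to the
patient-reported pain site, SF-MPQ-2 pain-quality scoring, and Bayesian
random-intercept mixed models linking pain quality to muscle activity —
exercised end to end on synthetic patient cohorts with known ground truth.

## The scientific problem

Pain reorganizes muscle activity. The *pain adaptation* hypothesis
predicts that agonist activity is suppressed near a painful site, so in
people with chronic low back pain (CLBP) the erector spinae should be
less active close to where it hurts, and the spatial *distribution* of
activity — not just its overall level — should depend on pain intensity
and quality.

The measurement design this package implements: two columns of five
electrodes (four bipolar channels, 2.5 cm spacing) taped bilaterally over
the lumbar erector spinae; a 12-s lumbar bending-and-returning task of
four 3-s phases (standing, flexion, full flexion, extension) recorded at
1000 Hz; pain site reported as the distance (cm) from the top of the EMG
sheet; pain intensity on the 0–10 NRS; pain quality with the 22-item
SF-MPQ-2.

For each patient the pipeline computes, in the extension phase where the
erector spinae is agonist:

- **normalized RMS**: per channel *c* and phase *p*,
  `RMS_norm[p,c] = mean_trials RMS[p,c] / RMS_ref[extension, c]`,
  after zero-phase 10–400 Hz band-pass filtering;
- **muscle activity**: the mean normalized extension-phase RMS over all
  channels;
- **centroid of activity**: the RMS-weighted mean channel position
  `ȳ = Σ w_c y_c / Σ w_c` on the cranial–caudal axis;
- **DISTANCE**: `|y_pain − ȳ|` in cm.

These outcomes are related to pain-quality scores with Bayesian Gaussian
random-intercept models,

```
y_ij = x_ij' β + u_i + ε_ij,   u_i ~ N(0, τ²),  ε_ij ~ N(0, σ²),
```

(participant *i*, trial *j*; all columns z-scored), fitted by a blocked
Gibbs sampler under effectively-flat conjugate priors, at 4 chains ×
16,000 iterations with 13,000 burn-in, checked with split-R̂ < 1.1, and
summarized by posterior means and equal-tailed 95% credible intervals.
Ten models are fitted: {subclass scores; the items of each subclass} ×
{activity; DISTANCE}.

Because no patient-level data are publicly deposited, the package ships a
first-class synthetic-cohort generator that encodes the hypothesized
mechanism — a Gaussian suppression kernel centred at the pain site whose
depth is a linear, clipped function of pain-quality scores — so every
stage is testable against known ground truth (effect signs, interval
coverage, null calibration).

## Worked example

```bash
python examples/05_fit_models.py
```

simulates a 23-patient cohort whose suppression is driven by the item
"pain caused by light touch", processes all 92 recordings, and fits the
neuropathic-item models. Output (abridged):

```
neuropathic-item model, dependent = muscle activity (extension) (max Rhat 1.002)
                       estimate  ci_low  ci_high  credibly_nonzero
light_touch               -0.98   -1.07    -0.89              True
...
neuropathic-item model, dependent = DISTANCE to pain site (max Rhat 1.002)
light_touch                0.76    0.43     1.09              True
```

Read: a one-SD increase in the light-touch rating is associated with a
0.98-SD drop in extension-phase activity and a 0.76-SD increase in the
centroid-to-pain-site distance — the generator's suppression mechanism,
recovered with the correct signs, with all chains converged. The other
items' intervals cover 0, as they should.

Other examples: `01_simulate_cohort.py` (cohort tables and ground truth),
`02_rms_mapping.py` (normalized RMS maps), `03_centroid_distance.py`
(centroid/DISTANCE arithmetic, e.g. centroid 4.8 cm and pain site 15.0 cm
give DISTANCE 10.2 cm), `04_sfmpq2_scoring.py` (questionnaire scoring).

## Command line

```bash
painmap simulate --seed 1 --outdir cohort/
painmap process  --cohort-dir cohort/ --outdir processed/
painmap fit      --outcomes processed/trial_outcomes.csv \
                 --patients cohort/patients.csv --seed 1 --outdir fits/
painmap report   --fitdir fits/
```

All tabular outputs are delimited text; `fit` writes the two report
tables (26 predictor rows each: Model, Variables, Estimate, Lower CI,
Upper CI, Rhat) plus a machine-readable long-form summary and a
provenance file with all seeds and settings.

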