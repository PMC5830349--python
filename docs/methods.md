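# Methods

This note documents the generative model, the analysis choices, and the
limitations of `featattn` — what the simulations emulate, which knobs
matter, and what passing tests do and do not establish about real data.

## Task designs

Four task variants are generated (`featattn.synth.design`). The fMRI
variants use a 0.3-s cue (attention) or fixation interval (baseline), 4.1 s
of dot-field motion, a 0.2-s speedup window, and ITIs of 4.2/6.4/8.6/10.8 s
assigned in exact 40/30/20/10% proportions per run and randomly ordered.
Trial durations (8.8–15.4 s) are therefore all multiples of the 2.2-s TR,
every onset is TR-locked by construction, and a 30-trial run lasts exactly
8.8 s (fixation lead, flagged for discard) + 330 s = 338.8 s → 154 volumes,
4 discarded. The stimulation variants compress the trial (3.7-s stimulus,
ITIs 1.35/1.8/2.25/2.7 s) so a 100-trial run lasts 600 s, matching the
10-minute stimulation protocol, with no fixation lead. Cue validity is 80%
(fMRI attention), 70% (stimulation attention); the baseline variants present
a target on 70% of trials. Directions are balanced to within one trial per
run, separately within each validity/presence stratum, which keeps the
per-direction training pools for the decoder near their expected sizes.
Trial counts must be multiples of 10 so all proportions are exact — this is
what makes the printed run length an identity rather than an expectation.

## Observer model

Detection follows a Weibull psychometric with slope 2 and guess/lapse rates
of 1%; these are treated as known by the staircase (the fitted family
matches). The attention task adds the package's one substantive modeling
commitment: a latent per-trial selection fidelity `g_t ∈ [0,1]` that
*divides* the threshold (effective threshold α/g_t) and *mixes* the voxel
patterns (g_t·p_cued + (1−g_t)·p_uncued). A single scalar thus couples
behavioral accuracy to pattern fidelity; everything the downstream analyses
detect flows through it.

Defaults, with rationale:

* `g_t ~ Beta(1.0, 0.45)` — mean ≈ 0.69, SD ≈ 0.29, with a heavy low-g
  tail. The spread matters more than the mean: misses must be dominated by
  trials where the distracter captured selection (g < 0.5), because only
  then does the incorrect-trial pattern *invert* relative to the training
  patterns, reproducing below-chance decoding of error trials alongside
  above-chance decoding of correct ones. A concentrated fidelity
  distribution yields the similarity effect but not the below-chance
  signature.
* `false_alarm_rate` 0.10 (attention; the task's reported bound is "low,
  under 15%") and 0.05 (baseline, reported under 5%).
* `tms_effect` 1.3 — multiplicative post-stimulation threshold scaling for
  the disrupted task, chosen so the hit−FA decrement in a 100-trial block
  is ≈ 0.08, the magnitude of the reported parietal-stimulation effect.
* A `decouple_fidelity` switch draws the fidelity that drives the response
  independently of the fidelity recorded for the patterns. Marginals are
  untouched; only the accuracy–pattern coupling is severed. This is the
  null model for calibration runs.

## Staircase

Best PEST is implemented as maximum likelihood over a fixed grid of 201
log-spaced threshold candidates spanning ×1/30…×30 around a configurable
anchor, uniform prior, Bernoulli likelihood over the full response history,
ties broken toward the smaller (more sensitive) candidate. Each trial is
placed at ψ⁻¹(p*; α̂), clipped to a physical range. With an empty history
the anchor (grid midpoint) is used. Invalid attention trials reuse the
magnitude of the preceding valid trial, carried across run boundaries
within a session; the baseline staircase updates only on target-present
trials. Sessions are preceded by 100 staircase calibration trials,
mirroring the pre-scan titration.

Two properties worth noting. First, because placements concentrate at a
single operating point, the closed-loop fixed point is the intensity at
which the *observer's actual* psychometric equals the target rate — so the
staircase holds its target even for the composite (fidelity-mixed) observer
whose effective function is not a slope-2 Weibull. Second, the achieved
rate over a finite window is dominated by binomial noise (SD ≈ 2.1
percentage points over 500 trials); staircase tracking adds little beyond
it. A shallower-than-assumed observer also biases the achieved rate
slightly upward at targets above ~60%; at the study's parameters this is
within a couple of points.

## BOLD synthesis

A boxcar over the dot-field window, convolved with a canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1/6) and normalised to unit peak,
scales each trial's per-voxel amplitude; trial amplitudes are therefore
peak % signal change, which keeps the 5% exclusion criterion interpretable.
ROI parameters: per-voxel mean response μ ~ N(1.0, 0.2) %sig and direction
patterns p_CW, p_CCW drawn iid N(0, s²) with selectivity s = 0.3 %sig —
direction information is a modest modulation on a larger shared response,
as in visual/parietal ROIs. Nuisance terms per run: linear drift (0.5%
over the run), a slow sinusoid (0.3%, 128-s period, random phase per
voxel), and AR(1) noise (innovation SD 1%, φ = 0.3). The series is emitted
in raw scanner units (baseline 1000) so the percent-signal-change
conversion is genuinely exercised. Fine-grid resolution dt = 0.1 s; onsets
are TR-locked so sampling lands exactly on volume times.

## Analysis pipeline

* **Preprocessing**: per run — drop flagged lead volumes, percent signal
  change against the voxel's run mean, linear detrend, hard 0.01-Hz
  high-pass in the frequency domain (the cutoff is the only documented
  filter property; edge effects at desk scale are accepted), then
  concatenation per task.
* **FIR deconvolution**: 8 taps over 17.6 s; five regressor sets for the
  attention task (direction × hit/miss on valid trials + one set for all
  invalid trials — invalid-trial false alarms are too few to split by
  direction) and seven for the baseline task (direction × hit/miss/correct
  rejection + false alarms). Estimation by pseudo-inverse; conditions with
  no events leave all-zero columns and a rank-deficiency warning rather
  than an error. r² is computed on the analyzed (preprocessed) series and
  clamped to [0,1]. Note that even noiseless simulated data yield r² < 1,
  since the high-pass and detrend act on the data but not on the
  regressors; the estimator itself is exact on unfiltered data (verified
  by the oracle tests).
* **Amplitudes**: the subject's response profile is the across-voxel,
  across-condition mean FIR curve, averaged over both tasks; its peak is
  constrained to taps 3–5 (4.4–8.8 s, ties to the earlier tap) and
  amplitudes average taps [peak−1, peak+1] ∩ [1, 8]. The >5% exclusion is
  applied on absolute amplitude in any condition of either task, and the
  resulting mask is shared by all downstream analyses.
* **Similarity**: matched-direction Pearson correlations (attention-CW ×
  baseline-CW, CCW × CCW), averaged per accuracy condition, then Fisher
  z (clamped at |r| = 1−10⁻⁷). Mismatched-direction correlations are
  returned as a diagnostic only. Cross-ROI aggregation, where used,
  happens on the z scale.
* **Decoding**: top-55 voxels by baseline-task r² among non-excluded
  voxels (ties to the lower index); instances average volumes from the
  subject's peak through the 8.8-s volume (1–3 volumes); the linear SVM
  (C = 1) is trained on z-scored baseline correct rejections, and test
  instances are standardized with training statistics only. Zero-variance
  training voxels are dropped with a warning. No cross-validation is
  needed: training and test data come from different tasks. The
  permutation null shuffles the pooled attention labels into two equal
  classes (floor/ceil for odd pools) against the subject's fixed
  predictions, 10,000 times by default (reducible), then resamples one
  value per subject and averages, 10,000 times; observed group accuracies
  outside the [2.5th, 97.5th] percentile band are flagged.
* **Stats**: Cousineau-style within-subject SEM (subject means removed,
  grand mean restored; the Morey factor is an option, off by default since
  the variant is not pinned down), paired t with CI, and a
  sum-of-squares 2×2 repeated-measures ANOVA in which each effect is
  tested against its own subject-interaction stratum and generalized η² =
  SS_effect / (SS_effect + SS_subjects + ΣSS_error). The interaction F is
  algebraically t² of the paired t on the difference-of-differences, and
  the implementation is cross-checked against an independent package in
  the test suite.

## Calibration findings and known limitations

* **Trial-count attenuation bias in the similarity contrast.** Because the
  staircase holds 65% hits, correct-trial patterns are estimated from
  roughly twice as many trials as incorrect-trial patterns (≈95 vs ≈48 per
  subject at study scale). Estimation noise attenuates a pattern's
  correlation with the baseline template by λ = √(S/(S+σ²)) with σ² ∝
  1/n, so under the *null* (fidelity decoupled from accuracy) the
  incorrect-trial index is attenuated more and z_correct − z_incorrect
  has a positive offset (≈ +0.08 z at reduced scale, ≈ +0.09 at study
  scale) — an artifact of the unbalanced design itself, not of the
  coupling. The decoding contrast is immune (single-trial accuracies have
  no count asymmetry) and is therefore the cleaner null-calibrated
  measure; the similarity index's unit-level null (equal-noise patterns)
  is exactly centred. Interpreting the similarity contrast on real data
  from this design inherits the same caveat, since the procedure there is
  identical. Equalizing trial counts would remove the artifact but would
  depart from the analysis pipeline as specified, so it is documented
  rather than silently changed.
* The generator emulates one homogeneous ROI with iid voxel noise. Real
  data add spatial noise correlations, physiological noise, motion
  residuals, and between-area heterogeneity; passing tests show the
  pipeline recovers the coupling under the stated noise model, not that it
  would at arbitrary SNR.
* Behavioral realism stops at the single-channel signal-detection rule
  with a constant false-alarm rate; criterion shifts, response bias, and
  cue-processing failures are not modelled.
* The staircase assumes the observer's slope; slope mismatch biases the
  achieved rate away from target (recorded, not corrected).

## Problem sizes

Default study scale is 12 subjects × 6 runs × 30 trials per task with a
200-voxel ROI (a subject simulates and analyzes in well under a second).
Replicate-cohort calibrations use 6-subject cohorts at 3 runs × 30 trials
with 100 voxels, and permutation nulls at 1000–2000 replicates per level;
these sizes give Monte-Carlo error comfortably below the effects being
measured while keeping the full suite fast.
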