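# Methods

This note documents the models, detectors and statistical procedures the
package implements, the synthetic study conditions used to exercise them,
the numerical choices that were genuinely open, and known limitations.

## Overview

`somnotype` classifies NREM sleep slow waves into subtypes defined by their
wave-locked thalamic BOLD responses, from simultaneous EEG–fMRI sleep
recordings.  The pipeline stages are:

1. slow-wave detection on a multi-channel negative envelope,
2. spindle detection with per-epoch MAD thresholds,
3. pulse-wave-amplitude (PWA) drop detection from the fingertip PPG,
4. wave-locked ROI-BOLD feature extraction and k-means subtyping,
5. event-regressor GLMs with timing-shuffle z-scores,
6. infraslow (~0.02 Hz) sigma-rhythm phase coupling,
7. co-occurrence and topographic permutation statistics.

All event times are seconds from recording start; intervals are half-open
`[start, end)`; sleep stages are the AASM codes `W, N1, N2, N3, REM` on
30-s epochs.

## Slow-wave detection

The detector operates on an artificial channel: per time point, the four
most negative values across electrodes are selected, the single most
negative is discarded (robustness against residual artifacts in isolated
electrodes), and the remaining three are averaged.  The input is band-pass
filtered to 0.3–45 Hz beforehand; the envelope is then zero-mean centred.
Negative half-waves are maximal runs of strictly negative samples bounded
by zero-crossings; only waves with half-wave duration 0.25–1.0 s
(full-wave 0.5–2.0 Hz) whose onset epoch is N1/N2/N3 are kept, with **no
amplitude threshold**.

Per-wave features: amplitude (|envelope minimum|), descending/ascending
slopes (amplitude over phase duration), per-channel *involvement* (mean
voltage in a 40-ms window centred on the negative peak; a channel is
involved strictly below −5 µV), the *synchronization score* (mean of the
two slopes times the involved fraction), and an *isolation* flag (no other
wave peaking within −12…+5 s of the wave's onset).

Numerical choices:

- Band-pass: zero-phase forward–backward 4th-order Butterworth.  A
  zero-phase filter avoids peak-latency shifts that would bias wave
  onset/peak timing.
- A sample exactly equal to 0 counts as non-negative, so wave intervals
  are half-open and deterministic.
- The centring baseline is the mean over the recording excluding
  artifact-flagged epochs.
- Involvement uses the 40-ms window mean; the instantaneous peak-sample
  alternative is available as `involvement_mode = "peak_sample"`.
- Bad channels are excluded (not interpolated) before the envelope.

## Spindle detection

Single-channel (Cz).  Sigma power is the 10–16 Hz band-passed signal
squared and smoothed with a centred 100-ms boxcar.  Candidates cross a
high threshold (median + 4·MAD of the epoch's power; raw MAD, no scale
factor) and are delimited by the surrounding crossings of a low threshold
(median + 2·MAD); thresholds are recomputed within each 30-s epoch, and an
event straddling a boundary uses the thresholds of the epoch containing
its high-threshold crossing.  Events must last 0.3–3 s and start in N2/N3
or a *transitional* N1 epoch (an N1 epoch whose immediate neighbour is
N2/N3).  Overlapping low-threshold intervals merge.

A specificity filter retains an event only if its mean spectral density in
10–16 Hz exceeds 3× the mean density pooled over the 8–10 and 16–18 Hz
flanks (strict >).  Band means are per-Hz averages of a zero-padded
periodogram of the raw event segment — per-Hz normalisation makes a
spectrally flat broadband burst score ≈ 1 rather than the bandwidth ratio.
The band filter defaults to a zero-phase 6th-order Butterworth; a
linear-phase FIR alternative is selectable (`spindle_filter_kind`).

## PWA-drop detection

The PPG front end is a configurable band-pass (default 0.5–16 Hz — a
high-pass above the ~1 Hz cardiac fundamental would destroy the beat
structure), Savitzky–Golay smoothing (0.1-s window, order 3) and linear
detrending.  Beats are alternating local maximum/minimum pairs; cycles
lacking a clear pair, or implying a heart rate above 250 bpm, are invalid.
Per-beat PWA = max − min, then a 5-beat centred moving average.

Drops: a *baseline mask* marks stable tracts (relative deviation from the
trailing 5-beat mean below 5 % for ≥ 2 consecutive beats; a trailing mean
lags on ramps, so drop transients are excluded).  Candidates are local
maxima of the 5-beat rolling PWA variance with a negative PWA first
difference (ties in the variance resolved with a relative tolerance, so
detection is invariant to rescaling the PPG).  A candidate is retained iff
the drop amplitude — read at the trough the candidate leads into — exceeds
10 % of the baseline, the mean of the five most recent baseline-mask
beats.  Drop duration counts the consecutive beats below 90 % of baseline.

## Wave-locked BOLD clustering

Before clustering, each ROI series is residualised on the HRF-convolved
spindle regressor (censored volumes excluded from the fit and passed
through unchanged).  Per wave and ROI, a ±21-s window around wave onset is
linearly detrended and sampled at the volumes nearest to onset + {0, 3, 6,
9, 12} s; concatenating the seven thalamic ROIs (SM, FP, VA, V, DA, DM, L)
gives 35 features (`n_rois × (⌊12/TR⌋ + 1)` in general).  Waves whose
window leaves its run or touches a censored volume are dropped and counted
per reason.

k-means uses correlation distance `d(x,y) = 1 − r(x,y)`, realised as
Euclidean k-means on per-vector standardised features (equivalent up to
scaling); 20 seeded restarts; k = 2…6 searched and chosen by the mean
silhouette (cosine distance and the Calinski–Harabasz criterion are
config-selectable robustness variants).  Centroids are reported as means
of the raw member vectors.  Zero-variance vectors (undefined correlation)
are dropped.

Clusters are matched across subjects by exhaustively permuting each
subject's clusters to maximise the mean Pearson correlation with a running
reference of matched centroids.  The shared label **C1** goes to the
matched group whose mean centroid has the larger mean over the 0–6 s
features — the early-positive thalamic response; the early-negative /
late-positive group becomes **C2**.

Timepoint sampling is nearest-volume (no interpolant invented); linear
interpolation is available via `feature_sampling = "linear"`.

## Event GLM and timing-shuffle z-scores

Slow waves are square waves over the descending phase `[onset, peak)` with
height |negative-peak amplitude|; spindles are unit-height square waves
over `[onset, end)`.  Regressors are built on a fine sample grid (default
100 Hz; a coarser grid is a pure resolution choice at TR 3 s), zeroed in
wake/REM/artifact segments, convolved with a gamma-variate HRF

    h(t) = (t / (p·q))^p · exp(p − t/q),   p = 8.6, q = 0.547

(unit peak at p·q ≈ 4.7 s), per run, and sampled on the TR grid.  Ordinary
least squares with an intercept gives per-ROI betas; each beta is
converted to a z-score against a null of betas from regressors whose event
onsets are redrawn uniformly within artifact-free epochs of each event's
own stage (counts preserved; placements inside zeroed segments are
asserted impossible).  1000 shuffles by default.  Group level: subject
z-scores are tested against zero per ROI (random-intercept one-sample
test) with Benjamini–Hochberg FDR, maps thresholded at q < 0.001.

Calibration caveat: the shuffle null is exact when the observed event
configuration is exchangeable with the shuffled ones and the noise is
serially independent.  Phase-clustered event timing, or AR(1) noise
without prewhitening (prewhitening belongs to upstream fMRI
preprocessing), inflates the z standard deviation by roughly 10–20 % at
the autocorrelation levels the generator uses; the group-level
random-effects test absorbs this.

## Infraslow sigma phase coupling

Sigma power at Pz (12–15 Hz, 2nd-order zero-phase Butterworth, Hilbert
envelope squared) is expressed in dB re the mean artifact-free NREM power
and decimated to 1 Hz.  The subject's infraslow frequency is the most
prominent local maximum (prominence ≥ 1 dB) of the mean N2 wavelet
spectrum (analytic Morlet CWT over 0.005–0.05 Hz) within 0.015–0.025 Hz;
0.02 Hz is assigned when no clear peak exists.  The dB power is band-passed
at peak ± 0.005 Hz (2nd-order Butterworth) over the whole recording; the
analytic-signal angle gives the phase, 0° at the envelope peak.

The phase is read out at every slow-wave onset (all NREM epochs).  Bins
are half-open, the boundary belonging to the bin it starts: *descending*
(fragile sleep) = [330°, 360°) ∪ [0°, 140°), *rising* (stable sleep) =
[140°, 330°); per subject × cluster, P(descending) + P(rising) = 1
exactly.  A 2 (cluster) × 2 (phase) within-subject ANOVA on the occurrence
probabilities is computed from the per-subject interaction contrast
(F(1, n−1) = t² of the paired contrast; verified against pingouin in the
test suite), with post-hoc paired t-tests per cluster and circular
summaries (circular means, Rayleigh test).

The phase is extracted from the dB power series; the raw band-passed
sigma envelope is an undocumented alternative that changes phases by only
a few degrees in the generator's regime.

## Associations and group statistics

A wave is associated with a PWA drop if the drop starts within −1…+5 s of
the wave's negative peak, and with a spindle if the spindle occurs within
±1.2 s of the peak (the spindle anchored at its onset; midpoint
selectable).  Observed association probabilities per subject × cluster ×
stage group (all NREM; light = N1∪N2; deep = N3; grouped by the wave's
stage) are z-scored against 1000 timing shuffles of the other events
within artifact-free epochs of their own stage.  Cluster differences use
paired t-tests with FDR.

Feature comparisons (amplitude, duration, density, isolation, sync score,
K-complex overlap, association probabilities) are paired at the subject
level: Shapiro–Wilk on the paired differences selects a paired t-test or
a Wilcoxon signed-rank test; FDR across the feature family.  Wave density
uses artifact-free stage time as the denominator.

Topographic comparisons of involvement use per-channel paired t-values;
channels with p < 0.05 form candidate clusters under the channel
adjacency (neighbours within a radius, or supplied explicitly); cluster
mass is the sum of |t|; the null of the maximal cluster mass comes from
random within-subject sign flips (10,000 by default) and a cluster is
significant iff its mass exceeds the null's 95th percentile.

## Synthetic study conditions

The generator (`somnotype.simulate`) plants all the structure the analysis
assumes, with a single seed determining every output (per-signal
sub-streams keep cross-signal structure stable under parameter changes).

- **EEG**: 8 channels at 100 Hz (waves and spindles live below 20 Hz, so
  this grid loses nothing); background is per-channel Gaussian noise with
  a 1/f amplitude spectrum, sd 12 µV — the steep spectrum of NREM sleep.
- **Slow waves**: zero-integral biphasic templates (half-sine negative
  lobe, longer compensating positive lobe).  Type A: −80 µV, 0.6-s
  negative lobe, on 80 % of channels; type B: −30 µV, 0.4 s, 50 % of
  channels.  3/min each over NREM, ≥ 2.5 s apart.  Onset phases relative
  to the infraslow clock are von Mises draws: A centred at 55° (middle of
  the descending arc), B at 235° (rising arc), concentration κ = 1.2 — a
  moderate preference (P(descending|A) ≈ 0.75).
- **Spindles**: 1-s Hann-windowed 13 Hz bursts, 25 µV, on Cz (and 0.7× on
  Pz), 7/min in N2/N3 — an N2-dense sleeper; the per-epoch MAD thresholds
  adapt to overall sigma activity, so planted density also governs the
  detector's noise-burst specificity.  Occurrence is thinned by
  (1 + 0.6·cos φ) of the infraslow phase; 30 % of type-A waves get an
  extra spindle near their peak.  A weak continuous sigma tone (0.5 µV,
  modulated at the same depth) keeps the infraslow rhythm present between
  bursts.
- **Infraslow clock**: 0.02 Hz; phase 0° at the sigma-envelope maximum.
- **BOLD**: 7 ROIs at TR 3 s in 600-s runs.  Template A peaks (+) near
  3 s with an undershoot near 10.5 s; template B dips (−) near 3.5 s and
  peaks near 12 s; amplitude 0.3 % PSC against AR(1) noise (φ = 0.4,
  sd 0.15 % — template amplitude twice the noise sd); responses are
  clipped at run boundaries.  A small spindle-locked response (0.05 %)
  exercises the spindle-regressor removal.
- **PPG**: 100 Hz, 60 bpm with 2 % beat jitter, asymmetric gamma-shaped
  pulses.  Drops multiply 8 consecutive beats by (1 − 0.25), start 1–3 s
  after the peak of a type-A wave in N1/N2 with probability 0.5, plus
  0.3–0.5/min independent drops; planted drops stay ≥ 20 s apart so each
  is a discrete, recoverable episode.
- **Hypnogram**: a repeating 20-min cycle (1 W, 2 N1, 16 N2, 10 N3, 8 N2,
  2 REM, 1 N1 epochs) truncated to the session length.

What the generator does **not** emulate: realistic scalp topography and
volume conduction, EEG artifacts (gradient, cardio-ballistic, movement),
wave trains / near-continuous N3 oscillations, heart-rate variability,
respiratory or cardiac fMRI noise, and session-level nonstationarity.
Passing the recovery suite therefore demonstrates correctness of the
implementations under the stated signal model, not field performance on
raw EEG–fMRI data (which additionally requires the out-of-scope
preprocessing chain).

## Benchmark problem sizes

The packaged benchmarks (`somnotype.evaluation`, also recomputed by
`scripts/acceptance.py`) use desk-scale sessions chosen to give stable
statistics: 100-min sessions for detector recovery (≈ 550 planted waves,
≈ 640 spindles, ≥ 100 drops), 50–75-min BOLD sessions for clustering
(20 simulations; 12 subjects for cross-subject matching), an 80-min
session for phase recovery (≥ 200 waves per cluster), 200 repeats × 200
shuffles for GLM null calibration (600 z-scores), 100 repeats × 1000
shuffles for association calibration, and 500 runs × 1000 sign-flip
permutations for the topographic FWER.

## Known limitations

- The timing-shuffle z is mildly over-dispersed for structured event
  timing or autocorrelated noise (see above); absolute single-subject z
  magnitudes should be interpreted with this in mind.
- The MAD-threshold spindle detector has an irreducible background rate of
  short sigma-band noise events (≈ 0.2–0.5/min under the generator's
  conditions); the power-ratio filter removes broadband but not
  narrowband chance bursts.
- Correlation k-means is implemented on standardised vectors; with very
  small feature variance the standardisation amplifies noise.
- The infraslow phase estimate degrades when sigma activity is weak
  (little N2 sleep) — the frequency fit then falls back to 0.02 Hz.
- EDF writing quantises to 16 bits over the data's physical range.
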