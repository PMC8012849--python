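# Methods

## Experimental model

The package models a block-design mental-workload (MWL) experiment on the
prefrontal cortex recorded with a 12-channel continuous-wave fNIRS device
(760/850 nm, 8 Hz). A session is a 146 s resting baseline followed, per
workload level, by 10 trials of 20 s mental arithmetic and 20 s rest, with
a 25 s resting delay between levels. Block intervals are half-open
`[onset, onset + duration)` with 0-based time, so each 8 Hz sample belongs
to exactly one block; a sample on a boundary belongs to the later block.
A single-level session is 546 s; the two-level session used for
classification is 971 s. Whether the original two-level protocol was one
continuous recording or two separate segments is not decisive for any
stage here; the package treats it as one continuous 971 s session, which
keeps a single time base for labeling and epoching.

## Synthetic subjects

No human data ship with the package; the generator produces recordings
with known ground truth.

- **Activation.** Ground-truth ΔHbO is the task boxcar — amplitude 0.5 µM
  for MWL-1 and 1.0 µM for MWL-2 — convolved with a canonical HRF. The HRF
  is a difference of two gamma densities (shapes 6 and 16, undershoot
  ratio 1/6) calibrated so the positive lobe peaks at 6 s, inside the
  physiological 5–8 s window, with the undershoot placed so the response
  to sustained stimulation levels off roughly 10–12 s after onset. The
  discrete kernel is normalized to unit area, so the configured amplitudes
  are sustained-response plateaus in µM. No published amplitude or SNR
  exists for this protocol; the defaults (half-µM scale activation against
  0.3 µM white noise) were chosen once as a realistic prefrontal contrast
  and give cohort accuracies on the scale reported for comparable
  mental-arithmetic BMI studies.
- **ΔHbR** is modeled as −ΔHbO/3, the conventional negative scaling of
  deoxyhemoglobin against oxyhemoglobin during activation; the ratio is
  configurable. ΔHbR's additive noise is scaled by the same ratio so all
  chromophores carry the same signal-to-noise ratio.
- **Physiological nuisance** is three fixed-frequency sinusoids with
  uniformly random phases per channel — cardiac 1.1 Hz (0.1 µM),
  respiration 0.25 Hz (0.15 µM), Mayer waves 0.1 Hz (0.1 µM) — the
  simplest model matching the named artifact sources. White Gaussian
  channel noise has SD 0.3 µM.
- **Bad channels** carry nuisance and white noise only, with no task
  coupling, emulating detached or noise-contaminated optodes.
- All 12 channels share the same activation (the prefrontal region is
  treated collectively) unless a per-channel gain map is supplied.
- Concentrations are projected to optical densities with the same
  forward Beer–Lambert map the analysis inverts. Identical configuration,
  schedule and seed give byte-identical recordings.

What the generator does *not* emulate: motion artifacts (spikes, drifts,
optode slippage), serially correlated physiological noise beyond pure
sinusoids, inter-channel anatomical variability, and patient-specific
hemodynamics. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under controlled SNR, not clinical
performance on real recordings.

## Optics

The modified Beer–Lambert law is applied per sample:
`ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·l·d`. The extinction
coefficients are taken from a standard compiled absorption tabulation
(760 nm: 586 and 1548.52 M⁻¹cm⁻¹ for HbO₂/Hb; 850 nm: 1058 and
691.32 M⁻¹cm⁻¹), stored in 1/(µM·cm) and user-overridable. Defaults
`l = 3 cm` and DPF `d = 6` (a single value for both wavelengths, with a
per-wavelength override). All concentrations are µM throughout to avoid
silent unit errors. Inversion and forward projection are exact mutual
inverses for any nonsingular table (matrices with condition number above
1e12 are rejected).

## Filtering

A fourth-order Butterworth low-pass designed at 0.3 Hz (half-power point
exactly at the cutoff) is applied forward and backward, giving zero net
phase; "fourth order" names the designed one-pass filter, and the two-pass
application squares its magnitude response. Edges are handled by odd
reflection about the endpoints so the baseline is not corrupted by
startup transients. Only the low-pass is implemented; no high-pass or
detrending stage is applied.

## Quality control

The reference is the binary 20 s step signal (1 in task blocks, 0
elsewhere). Per channel and per trial, an independent two-sample t-test
compares task-block ΔHbO samples with the adjacent rest block's samples;
the channel's significance fraction is the share of trials with p < 0.05,
and the channel passes at a threshold of 89.16 %. That threshold is read
as a required fraction of significant per-trial comparisons — the only
reading that yields a per-channel proportion — and is configurable. A
pooled all-task-vs-all-rest test is reported for diagnostics. No
multiple-testing correction is applied across channels by default
(matching plain p < 0.05 practice); a Bonferroni flag exists but is off.
Samples within a trial are autocorrelated after low-pass filtering, which
makes nominal p-values anticonservative; this inflates per-trial
significance symmetrically for coupled and uncoupled channels and the
89.16 % trial-fraction criterion still separates them cleanly (sensitivity
and specificity 1.0 over 50 seeded simulations at default SNR).

Contamination combines QC failure with flat-line and clipping detection;
a subject is rejected when more than 10 % of channels are contaminated.
Note this channel-fraction reading means 2 of 12 bad channels reject a
subject.

Trial averaging computes the spatial channel mean first, then averages
over the level's 10 trials (task + following rest, 40 s windows). With
the unit-area canonical kernel, a 20 s boxcar response peaks where the
kernel's running integral does, ≈ 11–14 s after onset — later than the
5–8 s impulse peak, as expected for sustained stimulation. For channels
that are noisy but retained, a least-squares projection onto
{intercept, HRF-convolved reference} reconstructs a model HRF with a gain
coefficient; the reconstruction is for plotting and diagnostics only and
never replaces data in the classifier.

## Features and decoding

Mean, variance, standard deviation, slope, kurtosis and skewness are
available per 2 s window (16 samples) with a 1 s step; mean + slope is the
default classification set. The printed-formula conventions are kept:
variance uses the sample (n−1) denominator while kurtosis and skewness
use the population σ with an n denominator. Slope is the least-squares
fit over the window (degenerating to the two-point rise-over-run at
n = 2) rather than the noise-dominated two-point difference. Features are
computed per channel over the retained set and concatenated; a
channel-averaged mode exists as an option.

The split is stratified 70:30 within class, rounding toward the training
set, at window level by default. Window-level splitting lets windows from
one epoch land in both sets and is optimistic in that respect; an
epoch-level split mode (`by_epoch=True`) is provided for an unbiased
estimate. Features are z-scored with training-set statistics only, then a
linear soft-margin SVM (hinge loss, C = 1 by default) is fit; the same
row split is reused for HbO, HbR and HbT so the three accuracies are
comparable. A noiseless subject is decoded near-perfectly but not at
100 %: windows on the rise/fall transitions of the two levels are exact
scalar multiples of each other and overlap genuinely in (mean, slope)
space.

Information transfer is computed exactly as defined: Wolpaw bits/trial
from (P, N) with the 0·log 0 convention, and bits/minute as
(60/T)·Cn·Bt.

## Actuation

Decoded states map to `open` (MWL-1), `close` (MWL-2) and `tied`
(undecided / below the confidence margin, interpreted as hold-state);
consecutive repeats emit no duplicate actuation. The hand's link-length
kinematics are not reproducible from published geometry, so the
stroke-to-angle map is calibrated to the design endpoints instead: a
strictly monotone smooth saturating curve (log1p shape, k = 9,
replaceable by a user calibration table) with f(0) = (0, 0, 0) and
f(25.5 mm) = (63.1°, 118.2°, 63.1°) for MCP/PIP/DIP. A published
stroke-angle figure quotes far larger extreme joint values than the
design range-of-motion table; the table is taken as authoritative. Stroke
trajectories follow a minimum-jerk profile (monotone, no overshoot)
completing in 1 s, matching the design goal of smooth trajectories; the
pose is a pure function of the command history.

## I/O and provenance

Recordings are written as SNIRF (HDF5, with the paradigm embedded as
stimulus tables and seed/config hash in the metadata tags) or as a plain
TSV dialect (`# key: value` headers, one column per channel × wavelength).
Every output carries the seed and a SHA-256 hash of the scientific
configuration (input/output paths excluded). All data outputs are
byte-deterministic for a fixed seed; only the JSON-lines run log contains
wall-clock timings.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study-sized problems
directly: 546 s single-level sessions for QC properties (50 seeded
replicates) and 971 s two-level sessions for decoding (cohorts of 10
subjects, 380 windows each). The cohort accuracy check uses consecutive
subject seeds derived from the global seed. Degenerate inputs (zero
variance channels, all-rest schedules, empty channel sets, out-of-range
strokes) raise explicit errors rather than propagating NaNs; zero-duration
blocks are omitted from schedules rather than stored.

## Known limitations

- Simulated noise is stationary and Gaussian/sinusoidal; real fNIRS noise
  is not, so reported accuracies characterize the pipeline, not hardware.
- The per-trial t-test inherits the independence assumption it is
  conventionally used with; p-values are anticonservative under
  autocorrelation (see above).
- The exoskeleton model is kinematic only: no forces, torques, servo
  dynamics or grasp adaptation.
- The serial-port protocol for real hardware is documented as one byte
  per command but only a file-backed transport is implemented.
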