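# Methods

This note documents the models, parameter choices and numerical
decisions behind `drivevigil`, and what the synthetic-data studies do
and do not establish about real recordings.

## Scenario and session model

A session is one driving condition — PAD (partially automated) or
Manual — on a common float-seconds clock starting at 0. The scenario
generator reproduces the study conditions exactly where they are
defined: constant 80 km/h; wind gusts with strictly alternating
direction at uniform 260–330 m spacing (11.7–14.85 s) and uniform
0–30 km/h strength; hazard cars at uniform 4–6 s gaps beginning 550 m
(~25 s) into the drive, with the unsafe fraction drawn uniformly from
[0.12, 0.15] and realized counts clamped so rounding never leaves that
band. Non-adjacent unsafe placements are sampled uniformly via the
bijection between non-adjacent u-subsets of n slots and plain u-subsets
of n−u+1 slots.

Every stream draws from its own generator spawned from the master seed
(`SeedSequence.spawn`), so changing one stream's parameters cannot
reshuffle another's realization; identical configuration and seed give
bit-identical sessions.

**Reduced scale.** The analysis always splits a session into
`n_sections` equal sections, so the section length is configurable:
full scale is six 600 s sections, desk-scale runs (tests, examples) use
six 60 s sections. Durations under 10 minutes require an explicit
`section_s` override. All recovery studies below state the scale used.

## Vehicle dynamics

The lane model is a deliberately simple second-order plant at 10 Hz:
gusts apply a lateral acceleration of 0.012 m/s² per km/h of gust speed
for 3 s (a 30 km/h gust displaces an uncontrolled car by >1.5 m, enough
to cross the 1.75 m lane bound and crash; crashes reset position to
lane center). PAD uses a stiff undelayed PD controller (kp = 40, kd =
12; residual deviation < 1 cm). The manual driver is a PD correction
(kp = 1.5 /s², kd = 2.0 /s) acting on 0.3 s delayed state plus white
steering-accelerator noise of 3.0 m/s² SD at T1, growing linearly by
25 % to T6 and scaled per subject. These constants were calibrated once
so that full-scale manual lane RMSE spans ≈0.51→0.61 m from T1 to T6 —
the observable the model exists to produce — and were not revisited.
Only those observable consequences are meaningful; the gains themselves
are not estimates of human steering behavior.

## EEG signal model

Each channel carries, at 250 Hz:

- a 1/f background with PSD `P(f) = P10 · 10/f`, `P10 = −125 dB re
  1 V²/Hz`, half of its power shared across the system's channels
  (realistic inter-channel correlation) and half channel-specific;
- per band (theta 4–8, alpha 8–12, beta 13–26 Hz) one band-limited
  Gaussian source per EEG system, flat in band, projected onto channels
  with fixed spatial weights (alpha posterior-weighted, beta/theta
  frontal-weighted; weight 1 on the analysis channels P4/Fz and the
  virtual-channel sources of P4_M2/FPz_M2);
- blink pulses (120 µV Hann, 0.3 s) time-locked to the eye stream's
  blink times with a fixed frontal gain vector;
- occasional 500 µV 0.3 s bursts and zeroed dropouts, both logged in
  the ground truth;
- small mastoid/common-mode and sensor noise (−140 dB flat), so cap
  channels are full-rank and the mastoid reference behaves like a real
  recording reference.

The per-section oscillator power is solved analytically so that the
*total* band-mean PSD (background + oscillator) equals the dB target
`base + mode_delta·[PAD] + profile[section] + cell noise`; the realized
targets (including the N(0, 0.4 dB) cell noise) are logged in the
ground truth. Grid electrodes are constructed so that each virtual
channel (electrode − grid mastoid) carries its source content exactly.

**Scale choice.** The injected mode deltas (+1.24 dB alpha, +1.18 dB
beta, +0.55 dB theta) and the T1-relative time profiles are the study's
reported effect structure. The absolute baselines sit at physiological
µV-range amplitudes (alpha −118.25, beta −117.43, theta −110.03 dB re
1 V²/Hz): reported-scale absolute levels would imply band signals of
tens of µV RMS whose peak-to-peak amplitude violates the pipeline's own
>200 µV epoch-rejection rule under any Gaussian signal model. All
comparisons of interest are differences in dB, which are invariant to
this shift.

## Eyes and ECG

Openness is a plateau at the subject's maximum (10 device units)
interrupted by Hann-shaped 0.3 s blinks (6/min; a blink contributes
half its duration as closure) and by 2–5 s full-closure episodes whose
per-section duty cycle is sized as `target − blink duty`, so the
windowed mean closure recovers the target within ±1 % absolute.
Validity flags drop ~0.5 % of samples (mixture of binocular and
monocular dropout). The ECG is a Gaussian P-QRS-T template train (R
amplitude 1 mV) whose R-R intervals are drawn per beat with the
section's target SD (default schedule 162.6→202 ms, heart rate 72 bpm),
floored at 300 ms.

PERCLOS defaults: closure is `1 − openness/max`, with max estimated as
the 99.5th percentile of valid samples (robust to spikes; contributes a
≲0.3 % positive bias at the default noise level); the classic
"%-time-below-threshold" variant is available by setting
`max_quantile=1.0` and thresholding externally. Printed PERCLOS-style
values are treated as fractions and emitted ×100 as percent.

## Cleaning chain

Bandpass filters are windowed-sinc (Hamming) linear-phase FIR kernels
(transition width `max(0.5 Hz, 0.25·low)`, ≈53 dB stopband, <0.1 dB
passband ripple) applied in a single zero-phase pass by FFT convolution
with reflection padding. Bad cap channels are flagged by robust SD
(flat below 2 % or noisy above 5× the median channel SD) and by a
*relative* neighbor-correlation rule (best |r| below 0.2 **and** below
half the montage median — an all-i.i.d. montage flags nothing);
interpolation is a 1/d² distance-weighted mean of the 4 nearest good
neighbors, refused for the sparse grid. Mastoid re-referencing
subtracts (M1+M2)/2 once and sets a provenance flag that refuses a
second application; the mastoid rows are dropped before merging.

ASR calibrates on the cleanest 10 % (≥60 s) of 1 s windows by RMS: PCA
of the calibration covariance gives the component basis, and each
component's rejection threshold is `mean + k·SD` (default k = 20) of
its variance across 0.5 s calibration windows. Application slides
half-overlapping 0.5 s Hann windows, zeroes components above threshold,
reconstructs from the rest and overlap-adds; clean windows pass through
exactly (orthonormal basis), and boundary samples with no taper weight
pass through unchanged. Exact rank deficiency (e.g. after
interpolation) raises by default; the pipeline opts in to dropping null
components when it knows channels were interpolated.

## Spectral analysis

10 s contiguous epochs from the start of the recording, trailing
remainder dropped. An epoch is rejected if its half-open interval
intersects any data-loss window (0.5 s tiles advancing 0.4 s, anchored
at the gap onset) or if any channel exceeds 200 µV peak-to-peak.
Sections are half-open sixths of the session assigned by epoch start
time. PSD is a DPSS multitaper estimate (full bandwidth 0.8 Hz over a
10 s epoch, i.e. time-half-bandwidth 4, eigenvalue-weighted,
non-adaptive) on 1–30 Hz; the *linear* PSD is averaged over epochs and
over band bins (edges inclusive; the 8 Hz bin belongs to both theta and
alpha, as the band definitions overlap), and converted to dB once at
the end. A flag-controlled dB-then-average variant is not provided:
averaging in the linear domain follows the processing order stated for
the study, and the choice is documented here instead of hidden behind a
switch.

## Statistics tree

Gate: Shapiro–Wilk per design cell (mode × section); any cell with
p < 0.05 — or a constant cell, where the test is undefined — flips the
whole feature to the nonparametric branch.

Parametric branch: balanced within-subject ANOVA from the standard sum
of squares decomposition. Greenhouse–Geisser ε is computed from
orthonormal (Helmert) contrast scores — `(tr S)² / (d · tr S²)` —
which for main effects equals the classical double-centered-covariance
formula; for the interaction the contrasts are the Kronecker product of
the factor contrasts. The GG-corrected p is *applied* when Mauchly's
test (chi-square approximation) rejects sphericity at 0.05 and the
effect has more than 1 numerator df; both corrected and uncorrected p
are always reported. Rationale: the always-corrected variant is
measurably conservative under true sphericity (null time-effect
rejection ≈0.028 instead of 0.05 at n = 28, k = 6), which would
miscalibrate the tree. Partial η² = SS_effect/(SS_effect+SS_error).
Post-hocs within significant factors are paired t tests,
Holm-corrected per family. Implementation is cross-checked against
pingouin (F, ε, GG p agree to machine precision) in the test suite.

Nonparametric branch: Friedman per mode (fully tied blocks short-cut to
χ² = 0, p = 1), with Conover pairwise rank statistics, df = (n−1)(k−1),
following a significant Friedman test; the *time family decision*
Holm-combines the two per-mode Friedman p-values, and the *mode family
decision* Holm-combines the six per-section paired Wilcoxon tests.
Without those family corrections the tree's null family-wise error
provably exceeds nominal (two and six uncorrected tests per family);
the per-test raw values are still reported.

Holm adjustment is the step-down rule `adj_i = max_{j≤i} min(1,
(m−j+1) p_(j))`; correlations are Pearson r with two-sided p from t at
df = n−2, per section and for T1–T6 subject averages.

Null calibration (table-level sampler, n = 28, 200 and 1000 replicate
runs): mode family rejects at ≈0.038, time at ≈0.039 — inside the
binomial 95 % interval around the nominal 0.05.

## Cohort model

The table-level sampler draws `value = base + subject offset +
(mode_delta + subject jitter)·[PAD] + profile[section]·subject slope
scale + cell noise` with defaults subject SD 1.5, mode-jitter SD 0.3,
lognormal slope-scale σ 0.2, cell SD 0.4 (dB units for EEG features).
The signal-level cohort applies the same subject structure to the
generator configuration; a latent subject factor (ρ = 0.7 with the band
baseline offset) also scales the driver's steering noise, so synthetic
cohorts reproduce the qualitative EEG-versus-lane-RMSE correlation
structure. Condition order is counterbalanced across subjects (odd
subjects drive PAD first) — in the generator this is bookkeeping only,
as no order effect is injected. Questionnaire and PVT tables are drawn
around the reported condition means (NASA-TLX Manual 8.16 vs PAD 6.98;
SSS baseline 2.61, Manual 4.29, PAD 4.71; PVT 307→323 ms).

## What the synthetic studies do and do not show

Passing parameter recovery shows the pipeline is *internally
consistent*: filters, ASR, epoch bookkeeping, PSD scaling, windowing
and the statistics recover what was injected, at the injected effect
sizes, under Gaussian stationary-per-section signals. It does not show
robustness to real-EEG phenomena the generator omits: non-Gaussian and
nonstationary background, volume-conducted sources with realistic
topographies, electrode drift and motion artifacts beyond short bursts,
eye-movement EOG leakage into theta, or clock drift between amplifiers
(alignment corrects a constant offset only). The driver model is not a
human model; DRT and accuracy are sampled, not emergent.

## Known limitations

- XDF container I/O is not implemented; sessions serialize as
  per-stream CSV plus JSON manifests and YAML configs.
- Exact virtual-channel coefficients of the physical grid are device
  metadata; the default map uses nearest-electrode-minus-mastoid and
  periocular differences and is fully configurable via the montage
  YAML.
- Full-hour 34-channel sessions occupy ≈250 MB in memory; desk scale is
  the intended mode for iterative work.
- Section smearing: at desk scale the 60 s PERCLOS/HRV windows span a
  whole section, so windowed features blur across section boundaries;
  slope-recovery checks for those features run at full scale.
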