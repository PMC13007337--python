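# Methods

This note records the models, conventions and numerical choices behind
`odorbulb`, and what the synthetic-data experiments do and do not establish.

## Trial structure and frame arithmetic

A trial is baseline → odor stimulation → post-stimulus, with durations in
seconds and an acquisition rate in frames/s (defaults 3 s / 5 s / 16 s at
25 Hz).  All frame indices are 0-based with half-open windows; the stimulus
onset frame is `round(baseline_s × frame_rate_hz)` (frame 75 by default) and
the stimulation window is `[onset, onset + round(stimulus_s × rate))`
(frames [75, 200)).  Frame arithmetic is exact integer arithmetic, so window
boundaries are identical across runs and platforms.  The default stimulus
panel is a control water line plus six odorants (NaCl, lithocholic acid,
adenosine, cadaverine, alanine, NH₄Cl), three trials per stimulus.

## ΔF/F convention

Raw ROI traces are divided by the per-cell mean of the 10 frames immediately
preceding onset (F0).  We store `dff = F/F0 − 1` so the F0 window has mean 0
by construction; the pure-ratio convention `F/F0` differs only by the
constant +1, and every downstream quantity (response magnitude, baseline SD,
peak z) is a difference or an SD ratio, hence invariant to that shift.
Traces with F0 ≤ 0 are rejected by name rather than silently propagated.

## Analysis trace and processing order

All response quantities are computed on the *analysis trace*: the mean of
the retained trials, converted to ΔF/F, then low-pass filtered at 5 Hz with
a 4th-order Butterworth filter applied forward-backward (`sosfiltfilt`).
Zero-phase filtering keeps transient peaks in place (≤1 frame shift) and has
unit DC gain; the measured gain is ≈1 at 1 Hz and <0.01 at 10 Hz.  Averaging
precedes filtering; for a linear filter the order affects nothing but edge
effects, and averaging first filters 7 traces per subject instead of 21.
Trial discards are caller-supplied flags (movement artifacts are judged by
the experimenter, not auto-detected).

## Response quantification

* **Magnitude** `r` = mean ΔF/F over the first 30 stimulation frames minus
  the mean over the 10 frames before onset.  Signed: suppressions are
  negative.  The 10-frame pre-window deliberately matches the F0 window.
* **Significance**: peak ΔF/F over the *full* stimulation window must be at
  least 6 SD above the pre-stimulus mean.  The SD is the sample SD of the
  full 75-frame baseline, not the 10-frame F0 window — 10 frames of
  low-passed data give an unusably unstable SD estimate.  A zero-SD baseline
  (possible only on noiseless synthetic input) is an error; noiseless
  round-trip checks use the magnitude path instead.
* **Preference**: argmax of signed magnitude across stimuli, assigned only
  to cells with ≥1 significant response; cells whose only responses are
  suppressions are left unclassified.  Exact ties go to the earlier stimulus
  in protocol order and emit a warning.
* **Lifetime sparseness**: `(Σr/m)² / (Σr²/m)` after rectifying negative
  magnitudes to 0.  The rectification is a deliberate choice: the formula is
  ill-behaved on mixed-sign vectors (it can exceed 1 and loses its
  selectivity interpretation).  All-zero rectified vectors yield NaN, never
  a number.  The statistic is invariant to positive rescaling, equals 1/m
  exactly on one-hot vectors and 1 on uniform vectors.
* **Heat-map ordering**: classified cells sorted by (preferred-stimulus rank
  in protocol order, descending magnitude to the preferred stimulus,
  cell id) with a stable sort, so the ordering is fully deterministic.
* **Category counts**: per-preparation counts of preferred stimuli, with
  group summaries as mean ± SEM across preparations.  Because the mean is
  linear, per-category group means sum exactly to the group's mean number of
  classified cells per preparation — the consistency property the acceptance
  report checks against the published group summaries.

## Frame-subtraction maps

`map = mean(frames [onset+offset, onset+offset+10)) − mean(frames
[onset−10, onset))` on a trial-averaged movie, so activation is positive and
suppression negative.  The stimulation window defaults to `offset = 25`
frames (1.0–1.4 s after onset), near the peak of a GCaMP6s-like transient;
the exact placement within the stimulation period is a free parameter.
Scaling modes divide by the per-map or across-map maximum |value|; zero maps
are left untouched.

## Group statistics

* **t-test families**: unpaired, two-sided, pooled-variance (Student)
  t-tests, df = n₁ + n₂ − 2, with step-down Holm-Sidak adjustment
  (`p_adj(i) = max_{j≤i} 1 − (1 − p(j))^(k−j+1)` over ascending raw p).
  Degenerate comparisons (n < 2, or zero variance in both groups with
  unequal means) are reported with an error and excluded; the family
  continues with k reduced accordingly.  Under a simulated global null
  (k = 7, 10,000 replicates) the measured familywise error is ≈0.05.
* **Mixed RM ANOVA**: between-group × within-stimulus design with subject as
  the repeated-measures block, fit by the classical mixed-design ANOVA when
  every subject is measured at every level.  Unbalanced designs fall back to
  a REML linear mixed model (random subject intercept) with Wald F tests;
  the denominator df there is the fixed-effects residual df, an
  approximation we document rather than hide.  Post-hoc per-stimulus group
  comparisons are pooled-variance t-tests with single-step Sidak correction,
  k = number of within levels.  An all-constant input returns F = 0, p = 1
  by convention (the sums of squares are 0/0).
* **Normalization**: count/volume ratios are computed per sample and
  summarized as means of per-sample ratios — never the ratio of group
  totals, which weights samples by volume.
* α = 0.05 throughout; significance flags are conveniences, not gates.

## Simulator

Each soma is an isotropic Gaussian intensity profile (σ = radius/2, default
radius 3 px) with center intensity `F0 × (1 + ΔF/F(t))` on a flat
background, rendered into 256 × 256 frames at 25 Hz.  The ΔF/F transient is
the stimulation-window boxcar convolved with a difference-of-exponentials
kernel (rise τ 0.2 s, decay τ 2.0 s — order-of-magnitude GCaMP6s values,
exposed as configuration, not claimed as estimates), rescaled so the trace
extremum equals the planted signed amplitude.  Suppressions are negative
amplitudes on the positive baseline.  Movie-level nuisances: additive
Gaussian sensor noise (default SD 20 counts — a tractable shot-noise
surrogate), optional exponential bleaching, and rigid integer-pixel
inter-trial drift (default ±1 px) that the emitted ROI tables compensate via
per-trial offsets, mirroring manual ROI adjustment on real recordings.

Default tuning: each cell prefers one uniformly chosen stimulus with peak
ΔF/F amplitude U(0.3, 0.8); 70% of cells are "selective" (off-stimulus
amplitudes 0–20% of the preferred), 30% "broad" (30–90%), and each
off-stimulus response is a suppression with probability 0.1.  Baseline soma
brightness F0 ~ U(800, 1200) counts, so every preferred response has peak
SNR = amplitude × F0 / noise_sd ≥ 12.  Somata centers are placed by dart
throwing with a minimum separation of 8 px (≳5σ), keeping cross-soma ROI
contamination below 1%.

The **background defaults to 0 counts** (a dark-subtracted camera model).
This matters: ROI-ratio ΔF/F is exact only when the ROI signal is pure soma;
a flat background of b counts attenuates recovered ΔF/F by a factor
`s/(s+b)` where s is the soma's ROI-mean intensity.  With the dark
background, the noiseless round-trip recovers planted amplitudes to ≈0.05%
(the residual is filter attenuation).  A side effect is that additive noise
drives about half of the pure-background pixels below zero; they are clipped
at 0 and a `ClippingWarning` is raised above 1% clipping.  This distortion
never touches the bright ROI pixels, and the simulation driver filters the
warning as expected behavior.

Everything — placement, tuning, noise, drift — is a deterministic function
of the ground-truth seed; per-(stimulus, trial) noise streams derive from
`(seed, stimulus index, trial)` so any single movie can be re-rendered
bit-identically in isolation.

## What the synthetic experiments show (and don't)

The validation experiments demonstrate that the implementation recovers
exactly what it plants: ΔF/F peaks within 2% (measured ≈0.05%), window
magnitudes equal to ideal-trace means at double precision, ≤1% false
positives from the 6-SD rule on pure noise (measured ≈0.1%), ≥95%
preferred-stimulus accuracy at peak SNR ≥ 10 (measured 100% at 200 cells),
and deterministic heat-map ordering.  The magnitude-equivalence check runs
on the unfiltered ΔF/F because the 5 Hz filter deterministically reshapes
the transient by ~2 × 10⁻⁵ in the 30-frame window mean — real but unrelated
to extraction fidelity.

The simulator omits optics (no PSF), Z-drift, neuropil/hemodynamic
contamination, correlated (shot) noise, and spontaneous activity; real
recordings contain all of these.  Passing these experiments therefore
establishes correctness of the computations under the stated noise model,
not performance bounds on arbitrary real data.  Published group-level
t/F statistics from real recordings depend on unpublished raw data and are
not recomputable here; the only in-paper quantities the acceptance report
touches are the published per-category mean counts, used as inputs to the
aggregation-consistency check.

## Problem sizes and runtime

Reference scales: 50 cells for the noiseless round-trip, 1000 cells
(7 stimuli × 3 trials, 256 × 256 × 600 frames) for the null control,
200 cells for classification recovery, 10,000 replicates for the familywise
error simulation.  Movies are rendered and analyzed one (stimulus, trial) at
a time, so peak memory stays near a single stack (~160 MB in float32); the
full validation run completes in a few minutes on one core.
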