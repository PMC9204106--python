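# Methods

This note documents the models, numerical choices and defaults behind
`mobigait`, and what the synthetic-data validation does and does not show.

## Synchronization

The two recording systems (EEG amplifier; wireless body-sensor base) share a
square synchronization pulse. `align_streams` resamples both pulse channels
to a common 1 kHz rate, locates the lag maximizing their cross-correlation
within a ±30 s search window (configurable), and refines it by parabolic
interpolation of the correlation peak. Jitter is the standard deviation of
per-edge residuals after applying the lag, with rising edges localized by
linear interpolation of the threshold crossing. Accuracy is limited by the
coarser of the two sampling rates; at matched 1 kHz rates the recovered lag
is within one sample. After alignment, body-sensor timestamps are shifted
into the EEG clock; data channels are never resampled at this stage.

## Gait segmentation

Total acceleration is the Euclidean norm of the three axes, mean-removed
(this removes gravity and sensor bias; norm-then-demean is a deliberate
choice — demeaning per axis first would discard the orientation-independent
impact signature). Velocity is the cumulative trapezoidal integral after a
zero-phase 0.3 Hz high-pass; the integral is high-passed once more to bound
drift. Stable-walking segments are where the 4-s windowed RMS of velocity
stays within ±20 % of a 40-s running median and above an absolute motion
floor (0.02 m/s) that excludes standstill; runs shorter than 5 s are
dropped.

Heel strikes are impact peaks of |total acceleration| (prominence 2 SD,
minimum spacing 0.4 cycles); toe offs are the onset of the following swing
burst, found by walking back from the burst maximum to 30 % of its peak in
a 5 Hz-low-passed envelope. Cycles are left-referenced (LHS→LHS) and any
cycle violating the LHS < RTO < RHS < LTO < next-LHS ordering or the
0.5–2.5 s duration bounds is discarded and counted. These detection rules
are not prescribed by any single standard; they are ordinary accelerometry
practice and are validated against the simulator's ground-truth event times
(recall ≥ 95 % within ±30 ms across cadences 0.8–1.2 Hz at 10 % sensor
noise).

## Body envelopes and cycle standardization

EMG: zero-phase Butterworth band-pass 1–500 Hz (hence the ≥ 1024 Hz sampling
requirement), full-wave rectification. Velocity and processed EMG are
reduced to Hilbert amplitude envelopes and anti-alias resampled to 200 Hz.
The "envelope of velocity" is taken literally as the Hilbert magnitude of
the velocity signal even though velocity is already slow.

Cycle standardization is a piecewise-linear time warp per cycle through
five anchors — (LHS, 0 %), (RTO, p₁), (RHS, p₂), (LTO, p₃),
(next LHS, 100 %) — where (p₁,p₂,p₃) are the participant-median event
percentages. The warp is inverted analytically (percent → time is piecewise
linear) and the envelope linearly interpolated at 200 grid points. A known
template replayed with ±10 % duration jitter is reconstructed by
warp-and-average to well under 1 % of its range. Trial-averaged curves are
correlated across sensors (Pearson by default, Spearman available);
correlations are Fisher-transformed with |r| capped at 1−10⁻⁷ so that
degenerate perfect correlations stay finite; constant envelopes yield
missing cells that are excluded from summaries.

## EEG cleaning

Bad channels: median absolute correlation with the montage < 0.4 or
log-variance > 5 MAD from the montage median; repaired as the mean of the
4 most-correlated good channels; more than 25 % bad aborts. Filtering:
zero-phase high-pass (order 4) at 1 Hz plus a steep low-pass (order 10) at
80 Hz, then polyphase resampling to 200 Hz — the steep low edge keeps
content at the post-resampling Nyquist > 40 dB down.

Artifact attenuation runs three decompose/screen/reconstruct stages in a
fixed order, removing components that fail the stage criterion:

| stage    | statistic                               | threshold |
|----------|------------------------------------------|-----------|
| ocular   | max kurtosis over 5-s windows            | > 12      |
| movement | mean sample entropy over 20-s windows    | < 0.8     |
| myogenic | Welch band power P[30–80] / P[1–30] Hz   | > 1       |

Kurtosis is excess (Fisher) kurtosis; windows are non-overlapping; sample
entropy uses m = 2 and tolerance r = 0.2 × window SD (standard defaults).
The sample-entropy kernel is an O(N²) template match (numba-compiled) and
is tested for 10⁻¹⁰ agreement with a brute-force implementation of the
definition. Components at numerical-noise variance (the residue of an
already-removed component) are marked degenerate rather than scored, since
every screening statistic is scale-free.

Decomposition backends are pluggable. The production backend is
scikit-learn FastICA — deflation mode for the ocular stage, symmetric
(parallel) mode for the later stages; the third stage uses the same
symmetric FastICA in place of a joint independent-vector decomposition, for
which no maintained implementation is available in this stack. The test
suite exercises the screening logic through a ground-truth backend whose
unmixing is the simulator's known mixing, which separates "are the rules
right" from "did the ICA converge". Removal subtracts only the flagged
components' scalp projections, so data outside the decomposition span are
untouched and an all-pass screen is exactly the identity.

## Source reconstruction

eLORETA weights solve the fixed point W_v = (K_vᵀ (K W⁻¹ Kᵀ + αH)⁺ K_v)^½
per source v, with K the average-referenced lead field, H the centering
operator, and symmetric 3×3 matrix square roots; iteration stops when the
maximum relative weight change is below 10⁻⁶ (at most 100 iterations,
otherwise an error carrying the last residual). α defaults to 10⁻³ × the
mean eigenvalue of the gain Gram matrix. The defining property — exact
localization of noiseless point sources — is verified exhaustively: on a
100-voxel grid with 32 channels, every scanned source is localized at its
true voxel, and the result is insensitive to α over several orders of
magnitude.

Dipole and ROI collapse both take the first principal component, with a
deterministic sign rule (loading-vector sum positive; ties broken by the
first non-zero element) so results are reproducible across platforms. ROIs
are 6-mm spheres on the source grid, specified directly in grid
coordinates.

## Connectivity and statistics

The spectrogram uses a complex Morlet CWT on a 6-octave × 8-voice frequency
grid descending from 50 Hz, masked to [1, 50] Hz. Cycles inside the cone of
influence of the slowest wavelet (3/f_min from either record edge) are
excluded before warping, because boundary effects bias their power.
Per-frequency warped power is cycle-averaged and z-scored across the grid;
since Pearson correlation is affine-invariant this standardization choice
cannot alter the connectivity values, only the plotted modulations. Band
values are means of per-frequency r over half-open bands [8,13), [13,30),
[30,50) Hz.

Group statistics: Fisher z per cell, one-sample t-tests across
participants, Benjamini–Hochberg FDR applied within one results table at a
time (one table = one test family; for voxel-wise maps, one image per
effect = one family). The four-way ANOVA (sensor × ROI × band × signal
type) fits main effects only; two-way ANOVAs include the interaction. Both
go through an OLS fit with sum-to-zero coding; the voxel-wise two-way ANOVA
is a vectorized balanced sums-of-squares computation verified to match the
OLS route exactly at individual voxels. Degenerate all-equal layouts are
reported as F = 0, p = 1 rather than an indeterminate 0/0. Voxel-wise
significance masks use q < 0.001; the r > 0.2 threshold is applied only
when rendering images, never to stored values.

## The synthetic generator

The generator is the package's test bed and defines its study conditions.

* **Timeline**: cycle durations (1/cadence)(1 + cv·ε), ε truncated normal
  (±3σ); cv ≥ 0.5 rejected as non-physiological. Default event fractions
  RTO = 0.12, RHS = 0.50, LTO = 0.62.
* **Body**: ankle acceleration is the analytic derivative of a sin² swing-
  velocity bump (zero in stance) plus a damped-oscillation impact at each
  ipsilateral heel strike (4× the swing peak), distributed over three axes
  with gravity on the vertical; muscle-site sensors carry attenuated copies
  of the same limb swing (thigh 0.5×, shank 0.9×), which is what makes
  ipsilateral velocity envelopes almost collinear — and hence more
  inter-dependent than EMG envelopes, the direction the analysis recovers.
  EMG is 20–450 Hz noise amplitude-modulated by raised-cosine activation
  windows with the classical phasing: vastus around its own heel strike,
  biceps femoris in terminal swing → double support, tibialis anterior
  through swing and the following double support, gastrocnemius through
  stance (antiphase with the rest).
* **EEG**: each source emits per-band band-filtered Gaussian noise with the
  gait-phase amplitude modulation imposed (floored at 5 %), plus a 1/√f
  broadband floor. Sources carry all three rhythms plus that floor because
  genuinely narrowband components are regular enough to fall below the
  0.8 sample-entropy threshold — broadband source activity is both more
  realistic and what makes the movement-stage screen meaningful. Default
  bilateral "M1" sources sit at the most lateral top-layer grid voxels;
  alpha/beta amplitude drops 40 % during the contralateral swing, gamma
  rises 15 % (the reversed, weaker modulation). Artifacts: ~250 ms
  biexponential blinks at 0.25 Hz, a step-frequency locked near-sinusoid,
  and 30–80 Hz broadband noise, each with a smooth random topography;
  artifact amplitudes and the blink shape are chosen so the planted
  components clear their screening thresholds with a wide margin (minimum
  blink window-kurtosis ≈ 26 across seeds against the threshold of 12).
* **Lead field**: closed-form quasi-static current-dipole potentials in a
  homogeneous conductor, evaluated at Fibonacci-spiral electrodes on the
  upper hemisphere of a 95-mm sphere and average-referenced, with per-source
  rank-3 orientation checks. This is deliberately not a realistic
  volume-conductor model: all downstream properties being tested
  (linearity, depth fall-off, eLORETA's fixed point) are independent of the
  conductor's realism.

**What passing tests show — and don't.** Ground-truth validation
demonstrates that each stage implements its definition correctly and that
the full chain recovers planted couplings with the right sign structure. It
does not show robustness to real-world pathologies the generator omits:
non-stationary cadence, electrode motion and impedance drift, volume-
conduction leakage between nearby sources under a realistic head model,
EMG crosstalk between neighbouring muscles, or artifact components that
violate the screening statistics' assumptions.

## Study conditions used by tests and the acceptance script

One participant = 80–90 cycles (~90 s) of walking at cadence 0.9–1.0, 32
EEG channels at 200 Hz on a 5×5×4 six-mm source grid, 10 % body-sensor
noise, default artifact amplitudes, oracle decomposition backend; the group
study uses 24 participants (12 in the acceptance script) sharing one lead
field and inverse operator. These sizes keep the complete validation suite
to a few minutes on a single CPU while leaving every statistical margin
wide (sign recovery, screening specificity, FDR behaviour are all far from
their pass boundaries).

## Known limitations

* The third screening stage substitutes symmetric FastICA for independent
  vector analysis; with the screening rules unchanged this affects only
  which decomposition the production backend offers, not the science being
  tested, but it is a substitution.
* Only treadmill-like stationary walking is modelled; no overground gait,
  turning, or speed changes.
* NKC uses sensor-site velocities only (no joint angles or ground-reaction
  forces), and connectivity is trial-averaged — no trial-level lag
  modelling between brain and body signals.
* ROI coordinates live on the synthetic source grid; warping individual
  anatomy to a template space is out of scope.
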