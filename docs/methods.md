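# Methods

This note records the models, numerical choices and known limitations of
`boldhrf`, in the order data flows through the pipeline.

## Synthetic event-related BOLD data

**Generative HRF.** The kernel is a sum of three independently tunable
parts:

* a gamma-variate positive lobe `g(t) = (t/tp)^a exp(a(1 - t/tp))` with
  `a = (tp/w)^2`, reparameterized so `peak_time_seconds` (tp) is the
  literal argmax and `dispersion_seconds` (w) behaves like a Gaussian sigma
  near the peak (FWHM ≈ 2.355 w);
* a delayed gamma-variate undershoot lobe (peak at
  `peak_time + undershoot_delay`, width 1.6 w by default) scaled by
  `undershoot_ratio` ∈ [0, 1), so the undershoot trough is that fraction of
  the peak;
* an exponentially damped sinusoid starting at the peak (zero before it,
  continuous at it) for post-peak "ringing".

This form reproduces the qualitative features seen in real event-related
data — fast/slow TTP, narrow/wide FWHM, absent/present undershoot,
subject-specific ringing — with parameters that remain individually
interpretable. The single-trial response is the kernel averaged over the
2-s stimulus boxcar and rescaled so `amplitude_percent` is the literal
peak of the *trial response*; runs superpose one response per trial onset
(linear summation).

**Acquisition presets.** Two geometries are built in: TR 1.25 s, 16 slices,
26.25-s trials (21 volumes), 17 trials/run, 5 runs; and TR 1.5 s, 10
slices, 25.5-s trials (17 volumes), 17 trials/run, 8 runs; both with a
12-s lead-in blank and 2-s stimulus. The trial period must be an exact
multiple of the TR. The 12-s lead-in is not a multiple of the 1.25-s TR,
so the first trial is placed on the next volume boundary (12.5 s, 10
volumes); at 1.5 s the lead-in is exactly 8 volumes. The lead-in is
discarded entirely before epoching and no partial epochs are ever emitted.

**Noise.** White Gaussian noise (SD in percent of baseline) optionally
AR(1)-filtered (stationary variance preserved); slow cosine drift
(default period 120 s, random phase) plus an optional linear term; and an
optional Rician regime (`rician_floor` > 0) in which the measurement is
the magnitude of a complex Gaussian — the non-Gaussian behavior that
motivates bootstrap inference in the first place. All-zero amplitudes give
a deterministic run; a fixed seed gives bit-identical output.

**What the generator does not emulate:** motion, physiological
(cardiac/respiratory) waveforms, k-space/reconstruction effects, spatial
noise correlations, and true between-subject HRF heterogeneity (simulated
subjects share a ground truth unless given different models). Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator and the inference machinery under the stated noise model, not
robustness to every artifact of real acquisitions.

## Preprocessing

**Slice-timing correction.** Slice z of volume k is acquired at
`k·TR + offset_z`; each voxel series is cubic-spline interpolated — after
replicating the first and last frames one TR outward, so the spline does
not extrapolate — and evaluated at the reference offset. Requires ≥ 4
frames.

**Drift removal.** The baseline is the series smoothed twice with a
unit-area RECT (boxcar) kernel, then subtracted. The kernel duration
defaults to the trial repetition period (26.25 s / 25.5 s), not the 2-s
stimulus: a 2-s kernel would make the baseline track — and the subtraction
annihilate — the response itself. With the kernel matched to the trial
period, the moving average of the periodic response train is (away from
run edges) the constant per-trial mean, so the evoked shape survives
detrending nearly intact; the per-trial mean offset it removes is restored
by the endpoint adjustment at epoching. The noiseless-pipeline bias this
leaves on the descriptors, pinned once against the dense-convolution
oracle, is 0.000 s on TTP and 0.007 s on FWHM for the default model; an
*isolated* (non-periodic) trial is attenuated by the pinned factor 0.949.

Edge handling is whole-sample reflection padding, implemented via the
2(n−1)-periodic reflected extension so the pad may exceed the series
length; reflection avoids the edge droop that zero padding would inject
into the first and last trials. Padding once and filtering twice makes
double-boxcar smoothing *exactly* equal to a single pass with the
(2L−1)-tap triangular kernel, which the tests verify to 1e-10.

**Percent conversion.** `100 × detrended / mean(raw run)`, using the raw
run mean before detrending as denominator — the field convention, and it
keeps fixed thresholds (e.g. peak amplitude > 0.2%) comparable across
runs. Units transition raw → percent exactly once.

## Epoching

The ROI time series is the unweighted voxel mean, computed *before*
epoching. Runs are cut independently at `leadin + k·trial_period` into
`trial_period/TR`-sample epochs and pooled (17 × 5 = 85 at the UHF
geometry; 17 × 8 = 136 at 3T), so cross-run discontinuities never enter an
epoch. Each epoch then has the mean of its first and last samples
subtracted (idempotent), anchoring the curve near zero at both ends.

## HRF descriptors

Curves are upsampled ×5 with a cubic Hermite spline using central
finite-difference (Catmull–Rom) tangents — deliberately *not* the
monotonicity-preserving PCHIP variant, which flattens extrema. Original
samples are reproduced exactly. On the fine grid:

* **P_amp / TTP**: global maximum and its time; ties broken to the
  earliest time. A maximum inside the final 25% of the epoch raises a
  `late_peak` quality flag (likely drift residue) rather than an error.
* **onset**: earliest fine sample at/above P_amp/2, refined by linear
  interpolation between the bracketing fine samples.
* **FWHM**: falling half-max crossing (first fine sample after the peak
  below half, same linear refinement) minus onset. Asymmetric responses
  are allowed; only onset < falling crossing is guaranteed.
* **undershoot amplitude**: minimum of the curve after the falling
  crossing, signed, clamped to 0 when nothing goes below baseline. The
  sign convention is negative-down; the descriptor is reported as is and
  never made positive.

A curve whose measured samples contain no positive value has no defined
parameters (`NoPositivePeakError`); interpolation overshoot alone cannot
create a peak. Voxel screening keeps voxels with CNR > 3 **and**
P_amp > 0.2%; negative-response voxels are excluded by construction.

## Bootstrap inference

**Within subject (500 replicates).** Epochs are resampled with
replacement and averaged; descriptors are estimated on each replicate's
*mean curve* (vectorized), never on single epochs, whose CNR is far too
low for stable half-max crossings. Per-timepoint 68% CIs are 16th/84th
percentiles (linear interpolation between order statistics); the
*variability* is the mean CI half-width — equal to the standard error of
the mean under Gaussian noise — and CNR = P_amp / variability. Identical
epochs give zero variability; CNR is then reported as `inf` with a
`degenerate` flag rather than an error, keeping screening logic total.

**Across subjects (2,000 replicates).** Each group replicate draws one
within-subject replicate (curve and its carried parameters) per subject
and averages across subjects; subjects themselves are not resampled, so
the group distribution reflects within-subject measurement uncertainty of
the fixed subject panel. Carrying the within-subject parameters is the
default; re-estimating on each group mean curve is available as an
option. Mixed TR panels must opt into regridding onto a 0.25-s common
grid (0.25 divides both supported TRs) with the same Hermite
interpolation; parameter-level comparisons need no regridding. Because
the resampling distribution is obtained once over the entire sample set,
no additional multiple-comparison correction is applied.

**Undershoot significance.** The descriptive undershoot (a minimum) is an
extreme-value statistic: under resampling noise its expectation is below
zero even when no undershoot exists, so a test built directly on it
rejects almost always under the null — and any window chosen from the
observed tail inherits the same selection bias. The test therefore uses
the *late-window amplitude*: the mean of each group replicate curve over
the final quarter of the epoch, a window fixed by the trial design (the
trial period is chosen so the response has evolved and decayed before the
next trial) rather than by the data. Under a null HRF that returns to
baseline this statistic is centred at zero; a genuine undershoot, which
persists well past the positive lobe, pulls it negative. The p-value is
the fraction of group replicates at or above baseline, floored at
1/n_boot2; p < 0.05 declares a significant undershoot. Simulation places
the false-positive rate at the nominal 5% (±3% band verified over 200
group replications) with essentially full power against an undershoot of
0.3 × peak at cortical-like CNR.

**Pairwise comparisons.** Two-sided bootstrap p-value from the paired
(by replicate index) difference of group parameter means:
`2 · min(frac(diff ≥ 0), frac(diff ≤ 0))`, floored at 1/n and capped at 1.
Ties count toward both sides so identical distributions give p = 1.

## Problem sizes and defaults

Simulation studies use the UHF geometry (85 epochs/subject), 7 subjects
per group, 500/2,000 bootstrap replicates — the study sizes the pipeline
is designed around. Recovery studies use 200 simulated subjects at noise
SD = 0.5 × peak amplitude; calibration and power studies use 200 group
replications. The default test suite and the reproducibility script each
complete in well under a minute of compute for these sizes because
parameter estimation over bootstrap replicates is fully vectorized.

## Known limitations

* The drift and AR(1) parameters are user-set surrogates, not calibrated
  to any measured noise spectrum.
* The fixed final-quarter undershoot window assumes the trial period
  comfortably contains the response; much slower responses (late peaks)
  are flagged by QC rather than handled.
* The across-subject bootstrap does not resample subjects, so its CIs do
  not cover true between-subject heterogeneity beyond the sampled panel.
* Slice-timing correction near run boundaries relies on replicated end
  frames; the first fraction of a second of the first trial after a very
  large offset is the least accurate region.
* No motion correction, spatial smoothing, registration or field-map
  undistortion: input volumes are assumed motion-corrected and aligned
  (the CLI warns on large frame-to-frame intensity jumps).
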