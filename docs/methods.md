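# Methods

## Scope and data model

beatkit analyses the four recording modalities of a cardiomyocyte
electrical-conditioning experiment — beating-EB brightfield video,
PIV-grade texture video, calcium fluorescence, and current-clamp voltage —
plus qPCR Ct tables. Raw videos are `FrameStack`s (T×H×W float intensities,
uniform frame interval, optional pixel size); traces are (time, value)
pairs. All channels are deterministic given their inputs; all synthetic
data are deterministic given spec + seed.

## Synthetic generators and their ground truth

The generators exist so that each analysis channel can be validated against
values computed *analytically from the generating parameters*, never by
running the analysis itself.

**Contraction video.** Each beating focus is a bright disk (plateau 0.55 of
full scale, soft rim of 0.5 px) carrying Gaussian particle texture
(σ = 1 px, ~0.05 particles/px² at default density, amplitudes 0.45·U(0.5,1)).
A material point at rest radius r sits at `r·λ(t)` with
`λ(t) = 1 − a·s(t)`, where s(t) is the normalized beat waveform (raised
cosine or fast-rise/slow-relax, duty fraction 0.3 of the period by default)
and `a` the peak fractional linear contraction (default 0.1; the segmented
area then dips to `(1−a)² = 0.81` of its maximum). Particles are rendered
*analytically at their continuous advected positions* — there is no grid
resampling anywhere. This matters: advecting a stored texture by bilinear
interpolation renders a convex mixture of integer-shifted copies whose
correlation peak is genuinely displaced toward the nearer integer lag
(10–30% displacement bias in our measurements), so an interpolation-based
video cannot serve as a PIV truth standard. Particles keep 3 px clear of
the rest rim so their stamps do not bleed past the disk edge. Recorded
truths per frame pair: `λ`, radius, area `πR²`, and the contraction-positive
mean strain rate `−2(λ_{k+1}/λ_k − 1)/Δt` (frame-difference convention —
what frame-pair PIV can observe, not the instantaneous derivative).

**Speckle pairs.** Smoothed uniform noise, displaced by an exact Fourier
shift; used for displacement oracles. SNR for noisy fixtures is defined as
texture SD over noise SD (texture SD ≈ 0.096 at default contrast).

**Calcium.** Per beat: linear rise over `rise_time` (default 50 ms) to
`baseline·(1+ΔF)`, then an exponential decay with time constant τ that is
end-corrected — rescaled by its (< e⁻³) end residual so the transient
reaches baseline exactly when the next beat starts; the decay is still of
the form `C + A·e^(−t/τ)` with the same τ. Analytic truths: time to peak
`0.9·rise_time` (10 % rule on a linear rise), FWHM
`rise_time/2 + τ·ln(2/(1+E))` with `E = e^{−(period−rise)/τ}`, and τ. The
resolvability invariant `rise_time + 3τ < period` is enforced.

**Action potentials.** Piecewise per cycle: linear phase-4 ramp from MDP to
the take-off potential (default MDP + 12 % of amplitude) at `phase4_slope`;
a raised-cosine upstroke whose maximal slope equals dV/dt_max *exactly* at
its midpoint (the APD reference time); a monotone cubic (PCHIP)
repolarization forced through the 30/50/90 % repolarization levels at
exactly apd30/50/90 after the reference time. A 95 %-repolarization knot
placed 5 % of APD90 after the APD90 crossing keeps phase 3 steep through
the 90 % level before the trace flattens into diastole, as in recorded
APs — without it the spline would glide through the APD90 level at a
near-diastolic slope, making the crossing unlocalizable under noise.
Morphology presets: ventricular-like (dV/dt_max 24 mV/ms, APD90 400 ms,
1 Hz) and rapid depolarizer (88 mV/ms, APD90 200 ms, 2 Hz), the cohort
mean and outlier upstroke velocities of the conditioning study.

**Cohorts and Ct tables.** dV/dt_max cohorts are normal draws plus planted
outlier values with truth flags. Ct tables follow
`Ct = base_ct(gene) − log2(fold) + sample_offset (+ noise)`; the per-sample
offset emulates loading differences and must cancel in ΔCt.

## Analysis choices

**Segmentation** (contractility): Gaussian blur (σ = 1 px) so the threshold
separates object from background rather than texture from texture; Otsu on
the median frame applied fixed across frames (deterministic stand-in for
interactive sliding-scale thresholding; per-frame and quantile/fixed
policies available), hole filling, largest connected component with
centroid-proximity tie-break. Empty-mask frames are flagged, never silently
zeroed.

**Beat detection**: local minima of the 3-frame-smoothed fractional-area
trace with prominence ≥ 0.01 and refractory 0.125 s (a quarter period at
the 2 Hz pacing ceiling). Frequency defaults to beats/duration (robust to a
single missed beat); the inverse-median-interval estimate is always
reported alongside.

**PIV**: per-lag normalized cross-correlation (correlation coefficient at
every candidate lag, `skimage.feature.match_template`) over a ±win/2 search
region per window; three-point Gaussian subpixel fit with parabolic
fallback; peak-ratio ≥ 1.3 against the second peak (5×5 exclusion zone);
local normalized-median (universal outlier) validation with invalid vectors
filled by the neighbourhood median but left flagged; multi-pass 64/32/16 px
with integer window offsets carried between passes (offset-only — no window
deformation, adequate at ≤ a few px/frame). Two deliberate details: a
correlation coefficient of exactly 1 skips subpixel refinement (identical
frames return exactly zero), and a peak on the correlation-map border
invalidates the vector unless the search was already clipped by the image
boundary. Measured accuracy: ≤ 0.005 px RMS on known shifts of 0.25–7 px.
Known floor: displacements below ~0.1 px/frame are attenuated toward zero
by ~0.007 px (peak-shape asymmetry of finite windows); choose frame rates
so inter-frame tissue motion stays above ~0.2 px.

**Strain**: central-difference velocity gradients on the interrogation
grid; scalar = −divergence/Δt, so contraction is positive (sign convention
chosen so positive rates mark contractile events; the tensor components are
kept for alternatives). The spatially averaged trace is restricted to the
beating area: without an explicit mask, the always-tissue region (AND of
per-frame segmentations) eroded by ¾ of the final window is used — spatial
averages over unmasked grids are dominated by background windows with no
texture. Cumulative strain integrates the positive part of the mean rate
(`Σ max(s̄,0)·Δt`, dimensionless — the time-integral reading of "summed
up"; the raw sum is a one-liner away); strain per beat divides by the beat
count and is absent when no beats occurred.

**Calcium metrics**: metrics are computed on the smoothed trace (50-ms
moving average by default, configurable off). Beat windows run from the
last upward crossing of `baseline + 0.1·(peak − baseline)` before each peak
to the start of the next beat; the per-beat baseline is the median of the
last 10 % of the previous window (global minimum for the first beat). The
10 % and 50 % levels are amplitude-relative (relative to peak − baseline),
which is what makes the triangular-pulse identity FWHM = W/2 hold and is
robust to camera offsets; a 1.1·baseline reading would not be. Peaks must
reach half the recording's normalized range — a bump that does not is noise,
not a beat (limitation: very strong photobleaching could push late beats
under this floor; the generator's default bleach is 0). The τ fit is
free-offset nonlinear least squares of `C + A·e^(−t/τ)` from the peak to
the window end (`τ₀` from the observed 1/e fall time); non-convergence and
non-positive τ are flagged, never fabricated. A per-recording τ is the
median of the per-beat fits — at amplitude-to-noise 10 the *single-
transient* free-offset fit has an intrinsic (information-limit) scatter of
7–12 %, so only the per-recording estimate can be expected to land within
10 % reliably.

**AP metrics**: noise is estimated robustly from successive differences;
noise-free traces use plain central differences and raw extrema (clean
fixtures stay exact). On noisy traces: detection uses a ~2-ms quintic
Savitzky–Golay derivative with a threshold of max(5 mV/ms, 25 % of the
trace's derivative maximum); dV/dt_max is re-measured with a
Savitzky–Golay window matched to ~0.38× the estimated upstroke duration
and de-biased with a parabolic fit around the derivative peak (a plain
moving average would blunt the 1.5-ms rapid-depolarizer upstroke by ~5 %);
MDP is read from a 10-ms moving average around the diastolic minimum;
APD crossings are refined by a local linear regression whose window is
sized to the local slope, re-centred once. APDs run from the time of
dV/dt_max (reference selectable to the AP peak); the take-off potential is
the voltage where the derivative first exceeds 10 % of dV/dt_max (fixed
0.5 mV/ms rule available); phase-4 slope is fitted over the middle 50 % of
the MDP→take-off interval. Per-cell features are medians over the cell's
detected beats. Measured recovery at 0.5 mV noise over both morphologies:
MDP within 0.5 mV, dV/dt_max within 4 %, APD90 within 1.5 ms.

**Classifier**: type-7 (linear-interpolation) quartiles — documented
because tiny cohorts can flag differently across quartile conventions;
strictly-greater-than cutoff so an all-equal cohort flags nothing; cohorts
under 4 cells are rejected. Cohort summaries pool the fence across groups
by default (the fence describes the whole recorded population; per-group
fencing is available).

**qPCR**: technical replicates are averaged at the Ct level; per-sample
folds then arithmetic group mean ± s.e.m. Control-group ΔΔCt is referenced
to the control *mean* ΔCt, so control folds have unit geometric mean by
construction. Amplification efficiency is fixed at 2; samples lacking a
reference-gene Ct are excluded with a warning.

## Problem sizes

Validation workloads were sized to run comfortably on one CPU: frequency
recovery uses 60 ten-second 96×96 videos at 30 frames/s; τ recovery ~210
transients per noise level (τ 0.2/0.3 s at 1 Hz, τ 0.5 s at 0.5 Hz — the
resolvability invariant forbids 0.5 s at 1 Hz, and 0.5 Hz is a study pacing
rate); AP recovery 100 three-beat cells at 10 kHz; the classifier oracle
1,000 random cohorts.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure the analyses assume*:
periodic radial contraction with advected texture, transients with sharp
rise and exponential decay, APs with prescribed feature values, Tukey-fence
outlier cohorts. They do not emulate out-of-plane motion, uneven
illumination, dye loading gradients, electrode drift, seal instability, or
biological beat-to-beat variability. Passing tests therefore demonstrate
correctness of the measurement definitions and estimator accuracy under
controlled noise — not robustness to every artifact of real recordings.
Conduction-velocity mapping, ionic-current modelling, single-cell
segmentation and microarray analysis are out of scope.
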