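"""Synthetic cardiomyocyte recordings with known ground truth.

Generators for the raw artifacts the analysis channels consume: beating
embryoid-body (EB) videos, displaced speckle frame pairs for PIV
validation, calcium-transient traces, spontaneous action-potential (AP)
trains in ventricular-like and rapid-depolarizer morphologies, upstroke-
velocity cohorts with planted outliers, and qPCR Ct tables. Every
generator records a :class:`GroundTruth` whose values are computed
analytically from the specification, never by running an analysis stage,
so downstream recovery tests are genuine round trips.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
artifact; identical spec + seed gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .io import FrameStack

__all__ = [
    "BeatWaveformSpec", "SyntheticVideoSpec", "SyntheticCalciumSpec",
    "SyntheticAPSpec", "GroundTruth",
    "gen_beat_waveform", "gen_contraction_video", "gen_speckle_pair",
    "gen_calcium_trace", "gen_calcium_stack", "gen_ap_trace",
    "gen_cohort", "gen_ct_table", "ap_spec_for_morphology",
]


@dataclass
class GroundTruth:
    """Record of every generator parameter a downstream stage must recover.

    ``params`` holds the input spec; ``truths`` holds derived analytic
    values (per-frame radii and displacement scale factors for videos,
    time-to-peak / FWHM / tau for calcium, per-beat AP features, planted
    outlier flags for cohorts). All values are computable from the spec
    without running any analysis.
    """

    params: dict
    truths: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# beat waveform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BeatWaveformSpec:
    """Periodic contraction pulse shape.

    frequency : beat rate in Hz.
    duty_fraction : fraction of the period occupied by the pulse.
    amplitude : peak fractional linear contraction (radius shrinks by this
        fraction at full contraction). Does not affect the normalized
        waveform s(t), only how the video generator applies it.
    waveform_shape : "raised_cosine" (symmetric) or "asymmetric"
        (fast rise, slow relaxation).
    """

    frequency: float
    duty_fraction: float = 0.3
    amplitude: float = 0.1
    waveform_shape: str = "raised_cosine"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 0 < self.duty_fraction < 1:
            raise ValueError("duty_fraction must lie in (0, 1)")
        if not 0 < self.amplitude < 1:
            raise ValueError("amplitude must lie in (0, 1)")
        if self.waveform_shape not in ("raised_cosine", "asymmetric"):
            raise ValueError(f"unknown waveform_shape {self.waveform_shape!r}")


_ASYM_RISE = 0.3  # fraction of the pulse spent rising in the asymmetric shape


def gen_beat_waveform(spec: BeatWaveformSpec, t_grid: np.ndarray) -> np.ndarray:
    """Normalized contraction drive s(t) in [0, 1].

    s is periodic with period 1/frequency, reaches 1 at the pulse centre
    (raised-cosine) or at the end of the fast rise (asymmetric), and is 0
    between pulses.
    """
    t = np.asarray(t_grid, dtype=np.float64)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    phase = (t * spec.frequency) % 1.0          # position within the period
    d = spec.duty_fraction
    s = np.zeros_like(phase)
    in_pulse = phase < d
    p = phase[in_pulse] / d                      # position within the pulse, [0,1)
    if spec.waveform_shape == "raised_cosine":
        s[in_pulse] = 0.5 * (1.0 - np.cos(2.0 * np.pi * p))
    else:
        rising = p < _ASYM_RISE
        val = np.empty_like(p)
        val[rising] = 0.5 * (1.0 - np.cos(np.pi * p[rising] / _ASYM_RISE))
        val[~rising] = 0.5 * (1.0 + np.cos(np.pi * (p[~rising] - _ASYM_RISE) / (1.0 - _ASYM_RISE)))
        s[in_pulse] = val
    return s


# --------------------------------------------------------------------------
# contraction video
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticVideoSpec:
    """A beating-EB phase-contrast-like video: one or two bright speckled
    disks on a dark background, each contracting radially by its own
    periodic drive.

    centers are in (row, col) pixels; omitted centers are auto-placed
    (single focus at the image centre, two foci side by side).
    """

    beat: tuple[BeatWaveformSpec, ...]
    duration: float = 10.0
    frame_rate: float = 30.0
    image_size: tuple[int, int] = (96, 96)
    base_radius: tuple[float, ...] = (30.0,)
    centers: tuple[tuple[float, float], ...] | None = None
    speckle_density: float = 0.5
    noise_sd: float = 0.0
    drift: float = 0.0            # px/s, applied along +col to all foci
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.beat, BeatWaveformSpec):
            object.__setattr__(self, "beat", (self.beat,))
        if len(self.beat) != len(self.base_radius):
            raise ValueError("one base_radius per beating focus required")
        if self.duration * self.frame_rate < 2:
            raise ValueError("need at least 2 frames")
        centers = self.centers
        if centers is None:
            h, w = self.image_size
            if len(self.beat) == 1:
                centers = ((h / 2.0, w / 2.0),)
            elif len(self.beat) == 2:
                centers = ((h / 2.0, w * 0.25), (h / 2.0, w * 0.75))
            else:
                raise ValueError("auto-placement supports 1 or 2 foci")
            object.__setattr__(self, "centers", centers)
        # foci must not overlap at rest
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                dist = np.hypot(centers[i][0] - centers[j][0],
                                centers[i][1] - centers[j][1])
                if dist <= self.base_radius[i] + self.base_radius[j]:
                    raise ValueError("foci overlap at rest")


def _speckle_texture(shape: tuple[int, int], rng: np.random.Generator,
                     density: float, smooth_sigma: float = 0.5) -> np.ndarray:
    """Positive speckle field in [0.35, 1].

    Higher density gives finer grain; the default correlation length
    (~1 px Gaussian) keeps the PIV correlation peak sharp, like the
    2-3 px particles of a well-seeded PIV image.
    """
    raw = rng.random(shape)
    tex = ndimage.gaussian_filter(raw, smooth_sigma / max(density, 1e-3))
    lo, hi = tex.min(), tex.max()
    tex = (tex - lo) / (hi - lo + 1e-12)
    return 0.35 + 0.65 * tex


_PARTICLE_SIGMA = 1.0     # px, Gaussian particle image radius
_PARTICLE_STAMP = 4       # px, half-size of the rendered particle patch
_EDGE_SOFT = 0.5          # px, softness of the disk rim
_DISK_BASE = 0.55         # brightness of the disk plateau (full scale 1);
                          # high enough that a bimodal threshold falls near
                          # half the rim height, keeping the segmented
                          # radius aligned with the geometric radius
_RIM_CLEAR = 3.0          # px, particles stay this far inside the rest rim
                          # so their stamps do not bleed past the disk edge


def _render_particles(img: np.ndarray, py: np.ndarray, px: np.ndarray,
                      amp: np.ndarray) -> None:
    """Accumulate Gaussian particle images at continuous positions."""
    h, w = img.shape
    r = _PARTICLE_STAMP
    off = np.arange(-r, r + 1)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    cy = np.round(py).astype(int)
    cx = np.round(px).astype(int)
    keep = (cy >= r) & (cy < h - r) & (cx >= r) & (cx < w - r)
    cy, cx, py, px, amp = cy[keep], cx[keep], py[keep], px[keep], amp[keep]
    yy = cy[:, None, None] + oy[None]
    xx = cx[:, None, None] + ox[None]
    g = amp[:, None, None] * np.exp(
        -((yy - py[:, None, None]) ** 2 + (xx - px[:, None, None]) ** 2)
        / (2.0 * _PARTICLE_SIGMA ** 2))
    np.add.at(img, (yy.ravel(), xx.ravel()), g.ravel())


def gen_contraction_video(spec: SyntheticVideoSpec) -> tuple[FrameStack, GroundTruth]:
    """Render a contracting-EB video and its analytic ground truth.

    Each focus is a soft-edged bright disk carrying Gaussian particle
    texture. A material point at rest radius r sits at ``r * lam(t)`` with
    ``lam(t) = 1 - amplitude * s(t)``; particle positions are advected
    through this field and rendered analytically at their continuous
    positions (no grid resampling, so the texture displacement recoverable
    by frame-pair PIV equals the recorded truth without interpolation
    bias). The truth velocity between frames k and k+1 at position x is
    ``(x - c) * (lam_{k+1}/lam_k - 1)`` and its contraction-positive mean
    strain rate is ``-2 (lam_{k+1}/lam_k - 1) / dt``, both stored in the
    ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n_frames = int(round(spec.duration * spec.frame_rate))
    dt = 1.0 / spec.frame_rate
    t = np.arange(n_frames) * dt

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.zeros((n_frames, h, w))

    s_per_focus, lam_per_focus, particles = [], [], []
    for b, R0 in zip(spec.beat, spec.base_radius):
        s = gen_beat_waveform(b, t) if n_frames > 1 else np.zeros(1)
        s_per_focus.append(s)
        lam_per_focus.append(1.0 - b.amplitude * s)
        # rest positions uniform in the disk (area-uniform polar sampling),
        # ~0.1 * speckle_density particles per px^2
        n_part = max(30, int(round(0.1 * spec.speckle_density * np.pi * R0 ** 2)))
        r_max = max(R0 - _RIM_CLEAR, 0.5 * R0)
        rad = r_max * np.sqrt(rng.random(n_part))
        ang = 2.0 * np.pi * rng.random(n_part)
        amp = (1.0 - _DISK_BASE) * rng.uniform(0.5, 1.0, n_part)
        particles.append((rad * np.sin(ang), rad * np.cos(ang), amp))

    for k in range(n_frames):
        drift_col = spec.drift * t[k]
        img = np.zeros((h, w))
        for f, ((cy, cx), R0) in enumerate(zip(spec.centers, spec.base_radius)):
            lam = lam_per_focus[f][k]
            rr = np.hypot(rows - cy, cols - (cx + drift_col))
            # analytic soft-edged disk base; the rim follows R(t) = lam * R0
            img += _DISK_BASE / (1.0 + np.exp((rr - lam * R0) / _EDGE_SOFT))
            dy0, dx0, amp = particles[f]
            _render_particles(img, cy + dy0 * lam, cx + drift_col + dx0 * lam, amp)
        frames[k] = img
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)

    truths = {
        "frequency_hz": [b.frequency for b in spec.beat],
        "amplitude": [b.amplitude for b in spec.beat],
        "s": [s.tolist() for s in s_per_focus],
        "lam": [lam.tolist() for lam in lam_per_focus],
        "radius_px": [(np.asarray(lam) * R0).tolist()
                      for lam, R0 in zip(lam_per_focus, spec.base_radius)],
        "area_px2": [(np.pi * (np.asarray(lam) * R0) ** 2).tolist()
                     for lam, R0 in zip(lam_per_focus, spec.base_radius)],
        "min_fractional_area": [float((1.0 - b.amplitude) ** 2) for b in spec.beat],
        # contraction-positive mean strain rate per frame pair, per focus
        "strain_rate_1_per_s": [
            (-2.0 * (np.asarray(lam)[1:] / np.asarray(lam)[:-1] - 1.0) / dt).tolist()
            for lam in lam_per_focus
        ],
        "centers": list(spec.centers),
        "seed": spec.seed,
    }
    stack = FrameStack(frames, frame_interval=dt)
    return stack, GroundTruth(params=asdict(spec), truths=truths)


# --------------------------------------------------------------------------
# speckle pair (PIV fixture)
# --------------------------------------------------------------------------

def gen_speckle_pair(shift: tuple[float, float], seed: int = 0, *,
                     image_size: tuple[int, int] = (128, 128),
                     noise_sd: float = 0.0,
                     independent_noise: bool = False,
                     speckle_density: float = 0.5) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """A speckle frame and a copy displaced by exactly ``shift`` (dy, dx) px.

    Subpixel shifts use Fourier shifting. By default the same noise
    realization is added to both frames; set ``independent_noise`` for
    per-frame noise (the realistic null for zero-motion tests).
    """
    dy, dx = float(shift[0]), float(shift[1])
    h, w = image_size
    if abs(dy) >= h / 4 or abs(dx) >= w / 4:
        raise ValueError("|shift| must be < image_size/4")
    rng = np.random.default_rng(seed)
    a = _speckle_texture(image_size, rng, speckle_density)
    b = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(a), (dy, dx))).real
    if noise_sd > 0:
        n1 = rng.normal(0.0, noise_sd, image_size)
        n2 = rng.normal(0.0, noise_sd, image_size) if independent_noise else n1
        a, b = a + n1, b + n2
    truth = GroundTruth(params={"shift": (dy, dx), "seed": seed,
                                "noise_sd": noise_sd, "image_size": image_size},
                        truths={"shift_dy_dx": (dy, dx)})
    return a, b, truth


# --------------------------------------------------------------------------
# calcium
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCalciumSpec:
    """Fluo-4-like calcium transient train.

    Each beat rises linearly from baseline over ``rise_time`` to
    ``baseline * (1 + peak_dF)`` then decays exponentially with time
    constant ``tau_decay`` toward baseline until the next beat.
    ``bleach_rate`` applies a slow multiplicative exponential decay to the
    fluorescent (above-background) signal; ``background_level`` is an
    additive camera/bath offset.
    """

    beat_frequency: float = 1.0
    tau_decay: float = 0.3
    rise_time: float = 0.05
    peak_dF: float = 1.0
    baseline: float = 100.0
    background_level: float = 0.0
    bleach_rate: float = 0.0
    noise_sd: float = 0.0
    duration: float = 10.0
    frame_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_frequency <= 0 or self.tau_decay <= 0 or self.rise_time <= 0:
            raise ValueError("beat_frequency, tau_decay, rise_time must be positive")
        if self.rise_time + 3.0 * self.tau_decay >= 1.0 / self.beat_frequency:
            raise ValueError("transients do not resolve between beats "
                             "(rise_time + 3*tau must be < beat period)")


def gen_calcium_trace(spec: SyntheticCalciumSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate (time, fluorescence) and analytic per-beat truths.

    Truths per beat: time_to_peak = 0.9 * rise_time (10%-above-baseline
    rule on a linear rise), fwhm = rise_time/2 + tau*ln 2, tau, peak time,
    amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    n = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n) * dt
    period = 1.0 / spec.beat_frequency

    phase = t % period
    g = np.zeros(n)
    rising = phase < spec.rise_time
    g[rising] = phase[rising] / spec.rise_time
    # exponential decay with time constant tau, rescaled by its (small,
    # < e^-3) end residual so the transient reaches baseline exactly at the
    # next beat; still of the form C + A*exp(-t/tau)
    e_end = np.exp(-(period - spec.rise_time) / spec.tau_decay)
    g[~rising] = (np.exp(-(phase[~rising] - spec.rise_time) / spec.tau_decay)
                  - e_end) / (1.0 - e_end)

    fluor = spec.baseline * (1.0 + spec.peak_dF * g)
    if spec.bleach_rate > 0:
        fluor = fluor * np.exp(-spec.bleach_rate * t)
    trace = fluor + spec.background_level
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, n)

    n_beats = max(int(np.floor(spec.duration / period + 1e-9)), 1)
    beat_starts = np.arange(n_beats) * period
    truths = {
        "n_beats": n_beats,
        "beat_start_s": beat_starts.tolist(),
        "peak_time_s": (beat_starts + spec.rise_time).tolist(),
        "time_to_peak_s": 0.9 * spec.rise_time,
        # half-level crossings: 0.5*rise_time on the linear upstroke;
        # tau*ln(2/(1+e_end)) on the end-corrected exponential downstroke
        "fwhm_s": 0.5 * spec.rise_time
        + spec.tau_decay * np.log(2.0 / (1.0 + np.exp(-(period - spec.rise_time)
                                                      / spec.tau_decay))),
        "tau_s": spec.tau_decay,
        "amplitude": spec.baseline * spec.peak_dF,
        "baseline": spec.baseline + spec.background_level,
        "seed": spec.seed,
    }
    return t, trace, GroundTruth(params=asdict(spec), truths=truths)


def gen_calcium_stack(spec: SyntheticCalciumSpec, *,
                      image_size: tuple[int, int] = (32, 48)
                      ) -> tuple[FrameStack, np.ndarray, np.ndarray, GroundTruth]:
    """Wrap the 1-D transient into a small fluorescence video.

    The left half of each frame is the signal ROI (per-pixel value = trace),
    the right half is background at ``background_level``; returns the stack
    plus boolean ROI and background-ROI masks.
    """
    t, trace, truth = gen_calcium_trace(spec)
    rng = np.random.default_rng(spec.seed + 1)
    h, w = image_size
    roi = np.zeros((h, w), dtype=bool)
    bg = np.zeros((h, w), dtype=bool)
    roi[:, : w // 2 - 2] = True
    bg[:, w // 2 + 2:] = True
    frames = np.empty((len(t), h, w))
    frames[:] = spec.background_level
    frames[:, :, : w // 2 - 2] = trace[:, None, None]
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    stack = FrameStack(frames, frame_interval=1.0 / spec.frame_rate)
    return stack, roi, bg, truth


# --------------------------------------------------------------------------
# action potentials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticAPSpec:
    """Spontaneous AP train with prescribed per-beat features.

    The beat is piecewise: a linear phase-4 ramp from MDP to the take-off
    potential at ``phase4_slope``; a raised-cosine upstroke whose maximal
    slope equals ``dvdt_max`` exactly (attained at its midpoint, which is
    the APD reference time); a monotone cubic (PCHIP) repolarization forced
    through the 30/50/90% repolarization levels at exactly apd30/50/90
    after the reference time, returning to MDP at the start of the next
    beat. APDs are in ms; dvdt_max in mV/ms; phase4_slope in mV/s.
    """

    morphology: str = "ventricular_like"
    mdp: float = -60.0
    peak: float = 30.0
    dvdt_max: float = 24.0
    apd30: float = 200.0
    apd50: float = 280.0
    apd90: float = 400.0
    rate: float = 1.0
    phase4_slope: float = 50.0
    take_off: float | None = None
    sampling_rate: float = 10_000.0
    n_beats: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology not in ("ventricular_like", "rapid_depolarizer"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if not (self.apd30 < self.apd50 < self.apd90):
            raise ValueError("need apd30 < apd50 < apd90")
        if self.apd90 >= 1000.0 / self.rate:
            raise ValueError("apd90 must be shorter than the cycle length")
        if self.dvdt_max <= 0 or self.phase4_slope <= 0:
            raise ValueError("dvdt_max and phase4_slope must be positive")
        if self.take_off is None:
            object.__setattr__(self, "take_off", self.mdp + 0.12 * (self.peak - self.mdp))
        if not (self.mdp < self.take_off < self.peak):
            raise ValueError("need mdp < take_off < peak")
        # feasibility of the timeline within one cycle
        cl = 1.0 / self.rate
        t4 = (self.take_off - self.mdp) / self.phase4_slope
        t_up = (self.peak - self.take_off) * np.pi / (2.0 * self.dvdt_max) / 1000.0
        if t4 + t_up / 2.0 + 1.05 * self.apd90 / 1000.0 >= cl * 0.97:
            raise ValueError("infeasible morphology: ramp + upstroke + apd90 "
                             "do not fit in the cycle length")


def ap_spec_for_morphology(morphology: str, **overrides) -> SyntheticAPSpec:
    """Representative parameter sets for the two observed AP phenotypes.

    The ventricular-like cell has the cohort-average upstroke velocity
    (24 mV/ms); the rapid depolarizer the outlier value (88 mV/ms) with a
    much shorter action potential.
    """
    if morphology == "ventricular_like":
        base = dict(morphology=morphology, mdp=-60.0, peak=30.0, dvdt_max=24.0,
                    apd30=200.0, apd50=280.0, apd90=400.0, rate=1.0,
                    phase4_slope=50.0)
    elif morphology == "rapid_depolarizer":
        base = dict(morphology=morphology, mdp=-62.0, peak=35.0, dvdt_max=88.0,
                    apd30=80.0, apd50=120.0, apd90=200.0, rate=2.0,
                    phase4_slope=100.0)
    else:
        raise ValueError(f"unknown morphology {morphology!r}")
    base.update(overrides)
    return SyntheticAPSpec(**base)


def _single_beat_voltage(spec: SyntheticAPSpec, phase: np.ndarray) -> np.ndarray:
    """Voltage over one cycle as a function of time-in-cycle (s)."""
    cl = 1.0 / spec.rate
    t4 = (spec.take_off - spec.mdp) / spec.phase4_slope
    amp_up = spec.peak - spec.take_off
    t_up = amp_up * np.pi / (2.0 * spec.dvdt_max) / 1000.0  # s
    t_ref = t4 + t_up / 2.0                                  # time of dvdt_max

    amp = spec.peak - spec.mdp
    levels = [spec.peak - frac * amp for frac in (0.30, 0.50, 0.90)]
    # a 95%-repolarization knot shortly after APD90 keeps phase 3 steep
    # through the 90% level before the trace flattens into diastole, as in
    # recorded APs; without it the monotone spline would glide through the
    # APD90 level at a nearly diastolic slope
    t95 = t_ref + spec.apd90 / 1000.0 * 1.05
    knot_t = np.array([t4 + t_up,
                       t_ref + spec.apd30 / 1000.0,
                       t_ref + spec.apd50 / 1000.0,
                       t_ref + spec.apd90 / 1000.0,
                       t95,
                       cl])
    knot_v = np.array([spec.peak, *levels, spec.peak - 0.95 * amp, spec.mdp])
    repol = PchipInterpolator(knot_t, knot_v)

    v = np.empty_like(phase)
    ramp = phase < t4
    upstroke = (phase >= t4) & (phase < t4 + t_up)
    rest = phase >= t4 + t_up
    v[ramp] = spec.mdp + spec.phase4_slope * phase[ramp]
    pu = (phase[upstroke] - t4) / t_up
    v[upstroke] = spec.take_off + amp_up * 0.5 * (1.0 - np.cos(np.pi * pu))
    v[rest] = repol(phase[rest])
    return v


def gen_ap_trace(spec: SyntheticAPSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate (time, voltage) for an AP train plus per-beat truths."""
    rng = np.random.default_rng(spec.seed)
    cl = 1.0 / spec.rate
    dt = 1.0 / spec.sampling_rate
    n = int(round(spec.n_beats * cl * spec.sampling_rate))
    t = np.arange(n) * dt
    v = _single_beat_voltage(spec, t % cl)
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, n)

    t4 = (spec.take_off - spec.mdp) / spec.phase4_slope
    t_up = (spec.peak - spec.take_off) * np.pi / (2.0 * spec.dvdt_max) / 1000.0
    beat_starts = np.arange(spec.n_beats) * cl
    truths = {
        "mdp_mv": spec.mdp,
        "peak_mv": spec.peak,
        "amplitude_mv": spec.peak - spec.mdp,
        "take_off_mv": spec.take_off,
        "dvdt_max_mv_per_ms": spec.dvdt_max,
        "apd30_ms": spec.apd30, "apd50_ms": spec.apd50, "apd90_ms": spec.apd90,
        "phase4_slope_mv_per_s": spec.phase4_slope,
        "rate_hz": spec.rate,
        "upstroke_time_s": (beat_starts + t4 + t_up / 2.0).tolist(),
        "n_beats": spec.n_beats,
        "seed": spec.seed,
    }
    return t, v, GroundTruth(params=asdict(spec), truths=truths)


# --------------------------------------------------------------------------
# cohorts and qPCR tables
# --------------------------------------------------------------------------

def gen_cohort(n_normal: int, normal_mean: float, normal_sd: float,
               outlier_values: Sequence[float] = (), seed: int = 0
               ) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort of per-cell dV/dt_max values with planted rapid-depolarizer
    outliers flagged in the ground truth."""
    if n_normal < 4:
        raise ValueError("need at least 4 normal cells for stable quartiles")
    rng = np.random.default_rng(seed)
    normal = rng.normal(normal_mean, normal_sd, n_normal)
    values = np.concatenate([normal, np.asarray(outlier_values, dtype=float)])
    planted = np.concatenate([np.zeros(n_normal, bool),
                              np.ones(len(outlier_values), bool)])
    df = pd.DataFrame({
        "cell_id": [f"cell{i:03d}" for i in range(len(values))],
        "dvdt_max": values,
        "planted_outlier": planted,
    })
    truth = GroundTruth(
        params={"n_normal": n_normal, "normal_mean": normal_mean,
                "normal_sd": normal_sd, "outlier_values": list(outlier_values),
                "seed": seed},
        truths={"planted_flags": planted.tolist(),
                "fraction_planted": float(planted.mean())})
    return df, truth


def gen_ct_table(genes: Sequence[str], groups: Sequence[str],
                 true_fold_changes: dict, reference_gene: str,
                 control_group: str = "control", *,
                 n_replicates: int = 3, ct_noise_sd: float = 0.0,
                 seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format qPCR Ct table with known fold changes.

    ``true_fold_changes[gene][group]`` is expression relative to the control
    group; the reference gene must have fold 1 everywhere. The model is
    ``Ct = base_ct(gene) - log2(expression) + sample_offset + noise`` where
    sample_offset emulates per-sample loading differences (removed by the
    reference-gene normalization).
    """
    if reference_gene not in genes:
        raise ValueError("reference_gene must be in genes")
    if control_group not in groups:
        raise ValueError("control_group must be in groups")
    ref_folds = true_fold_changes.get(reference_gene, {})
    for g in groups:
        if ref_folds.get(g, 1.0) != 1.0:
            raise ValueError("reference gene must have true fold 1 in every group")
    rng = np.random.default_rng(seed)
    base_ct = {gene: rng.uniform(18.0, 28.0) for gene in genes}
    records = []
    for group in groups:
        for rep in range(n_replicates):
            sample_id = f"{group}_s{rep + 1}"
            sample_offset = rng.normal(0.0, 0.3)
            for gene in genes:
                fold = 1.0 if gene == reference_gene else \
                    true_fold_changes.get(gene, {}).get(group, 1.0)
                ct = base_ct[gene] - np.log2(fold) + sample_offset
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                records.append((sample_id, group, gene, ct))
    df = pd.DataFrame(records, columns=["sample_id", "group", "gene", "ct"])
    truth = GroundTruth(
        params={"genes": list(genes), "groups": list(groups),
                "reference_gene": reference_gene, "control_group": control_group,
                "n_replicates": n_replicates, "ct_noise_sd": ct_noise_sd,
                "seed": seed},
        truths={"fold_changes": {g: {grp: (1.0 if g == reference_gene else
                                           true_fold_changes.get(g, {}).get(grp, 1.0))
                                     for grp in groups} for g in genes}})
    return df, truth
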