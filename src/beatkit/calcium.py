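"""Calcium-transient extraction and per-beat kinetics.

From a fluorescence video (or a precomputed trace), the signal is the
ROI mean minus the background-ROI mean per frame, min-max normalized over
the whole recording and lightly smoothed. Per beat, three metrics are
computed: time to peak measured from the 10%-above-baseline upward
crossing; full width at half maximum from the 50% crossing on the upstroke
to the 50% crossing on the downstroke (both relative to peak-above-
baseline); and the decay time constant tau from a nonlinear least-squares
fit of ``A * exp(-t / tau)`` (plus baseline) from the peak to the start of
the next beat.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .io import FrameStack

__all__ = [
    "CorrectedTrace", "TransientWindow", "TransientMetrics",
    "extract_corrected_trace", "trace_from_series", "segment_transients",
    "time_to_peak", "fwhm", "fit_decay_tau", "transient_metrics",
]


@dataclass
class CorrectedTrace:
    time: np.ndarray            # s
    F_corrected: np.ndarray     # ROI mean - background mean, smoothed
    F_norm: np.ndarray          # min-max normalized over the recording
    smoothing_window_s: float = 0.0

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class TransientWindow:
    """One beat: samples [start, stop), its peak index and local baseline."""

    beat: int
    start: int
    stop: int
    peak: int
    baseline: float

    @property
    def degenerate(self) -> bool:
        return self.peak <= self.start


@dataclass
class TransientMetrics:
    beat: int
    time_to_peak: float | None  # s
    fwhm: float | None          # s
    tau: float | None           # s
    amplitude: float | None     # fitted A, trace units
    r_squared: float | None
    flags: tuple[str, ...] = ()


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, np.ones(w) / w, mode="same")[pad:pad + len(x)]


def extract_corrected_trace(stack: FrameStack, roi: np.ndarray,
                            background_roi: np.ndarray,
                            smoothing_window: float = 0.05) -> CorrectedTrace:
    """Background-corrected, normalized, smoothed fluorescence trace.

    Per frame: mean over the signal ROI minus mean over the background ROI;
    the result is smoothed by a moving average of ``smoothing_window``
    seconds (default 50 ms, i.e. 5 samples at 100 frames/s) and min-max
    normalized against the whole recording.
    """
    roi = np.asarray(roi, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    if roi.shape != stack.frames.shape[1:] or bg.shape != roi.shape:
        raise ValueError("ROI shapes must match the frames")
    if not roi.any() or not bg.any():
        raise ValueError("empty ROI")
    if (roi & bg).any():
        raise ValueError("signal and background ROIs must be disjoint")
    f_roi = stack.frames[:, roi].mean(axis=1)
    f_bg = stack.frames[:, bg].mean(axis=1)
    return trace_from_series(stack.times, f_roi - f_bg,
                             smoothing_window=smoothing_window)


def trace_from_series(time: np.ndarray, values: np.ndarray, *,
                      smoothing_window: float = 0.0) -> CorrectedTrace:
    """Build a CorrectedTrace from an already-corrected 1-D series."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    dt = float(np.median(np.diff(time)))
    w = max(1, int(round(smoothing_window / dt))) if smoothing_window > 0 else 1
    if w % 2 == 0:
        w += 1
    sm = _moving_average(values, w)
    lo, hi = sm.min(), sm.max()
    norm = (sm - lo) / (hi - lo) if hi > lo else np.zeros_like(sm)
    return CorrectedTrace(time, sm, norm, smoothing_window_s=(w - 1) * dt if w > 1 else 0.0)


def segment_transients(trace: CorrectedTrace, threshold_fraction: float = 0.10,
                       *, min_prominence: float = 0.3, min_height: float = 0.5,
                       min_period: float | None = None) -> list[TransientWindow]:
    """Split the trace into per-beat windows.

    Peaks are found on the normalized trace (prominence >= min_prominence
    and height >= min_height of the full range — a bump that does not reach
    halfway up the recording's range is noise, not a beat); each beat's
    window starts at the last upward crossing of ``baseline +
    threshold_fraction * (peak - baseline)`` before its peak and ends at
    the start of the next beat. The baseline for a beat is the median of
    the last 10% of the previous window; the global minimum is used for
    the first beat.
    """
    y = trace.F_norm
    if y.max() - y.min() <= 0:
        return []
    dt = trace.dt
    distance = max(1, int(round((min_period or 0.2) / dt)))
    peaks, _ = signal.find_peaks(y, prominence=min_prominence,
                                 height=min_height, distance=distance)
    if len(peaks) == 0:
        return []

    windows: list[TransientWindow] = []
    starts: list[int] = []
    baseline = float(y.min())
    for b, pk in enumerate(peaks):
        thresh = baseline + threshold_fraction * (y[pk] - baseline)
        lo = starts[-1] if starts else 0
        below = np.nonzero(y[lo:pk] < thresh)[0]
        start = lo + below[-1] + 1 if len(below) else lo
        starts.append(start)
        windows.append(TransientWindow(b, start, len(y), pk, baseline))
    # close windows at the next beat's start, then set per-beat baselines
    # from the tail of the previous window and re-derive starts with them
    for b in range(len(windows) - 1):
        windows[b].stop = windows[b + 1].start
    for b in range(1, len(windows)):
        prev = windows[b - 1]
        tail = max(1, (prev.stop - prev.start) // 10)
        if prev.stop > tail:
            base = float(np.median(y[prev.stop - tail:prev.stop]))
            if np.isfinite(base):
                windows[b].baseline = base
        # re-derive the start with the beat-local baseline
        pk = windows[b].peak
        thresh = windows[b].baseline + threshold_fraction * (y[pk] - windows[b].baseline)
        lo = max(prev.stop - tail, 0)
        below = np.nonzero(y[lo:pk] < thresh)[0]
        if len(below):
            windows[b].start = lo + below[-1] + 1
        windows[b - 1].stop = windows[b].start
    windows = [w for w in windows
               if w.start <= w.peak < w.stop and w.stop - w.start >= 3]
    for b, w in enumerate(windows):
        w.beat = b
    return windows


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where y crosses `level` between i-1 and i."""
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def time_to_peak(window: TransientWindow, trace: CorrectedTrace,
                 threshold_fraction: float = 0.10) -> tuple[float, tuple[str, ...]]:
    """Time from the 10%-above-baseline upward crossing to the peak.

    The crossing is located by linear interpolation between samples. A peak
    at the window start (one-sample rise) returns 0 with a "degenerate"
    flag.
    """
    if window.degenerate:
        return 0.0, ("degenerate",)
    y, t = trace.F_norm, trace.time
    level = window.baseline + threshold_fraction * (y[window.peak] - window.baseline)
    seg = np.nonzero(y[window.start:window.peak + 1] >= level)[0]
    if len(seg) == 0:
        return 0.0, ("no_crossing",)
    i = window.start + seg[0]
    return float(t[window.peak] - _cross_time(t, y, i, level)), ()


def fwhm(window: TransientWindow, trace: CorrectedTrace
         ) -> tuple[float | None, tuple[str, ...]]:
    """Full width at half of the peak-above-baseline amplitude.

    Interpolated crossing of baseline + 0.5*(peak - baseline) on the
    upstroke and downstroke; absent (None) with a flag when the downstroke
    never falls back to half within the window.
    """
    y, t = trace.F_norm, trace.time
    half = window.baseline + 0.5 * (y[window.peak] - window.baseline)
    up = np.nonzero(y[window.start:window.peak + 1] >= half)[0]
    if len(up) == 0:
        return None, ("no_upstroke_crossing",)
    t_up = _cross_time(t, y, window.start + up[0], half)
    down = np.nonzero(y[window.peak:window.stop] <= half)[0]
    if len(down) == 0:
        return None, ("no_downstroke_crossing",)
    j = window.peak + down[0]
    t_down = _cross_time(t, y, j, half)
    return float(t_down - t_up), ()


def fit_decay_tau(window: TransientWindow, trace: CorrectedTrace
                  ) -> tuple[float | None, float | None, float | None, tuple[str, ...]]:
    """Fit ``F(t) = C + A * exp(-t/tau)`` from the peak to the window end.

    t is zeroed at the peak; initial values are A0 = peak - baseline and
    tau0 = observed time to fall to baseline + A0/e. Returns
    (A, tau, r_squared, flags); non-convergence or a nonpositive tau gives
    (None, None, None, flag).
    """
    y, t = trace.F_corrected, trace.time
    seg = slice(window.peak, window.stop)
    ts = t[seg] - t[window.peak]
    ys = y[seg]
    if len(ys) < 5:
        return None, None, None, ("too_few_samples",)
    # baseline on the corrected (unnormalized) scale
    norm_range = trace.F_norm.max() - trace.F_norm.min()
    scale = (y.max() - y.min()) / norm_range if norm_range > 0 else 1.0
    c0 = y.min() + window.baseline * scale
    if not np.isfinite(c0):
        c0 = float(np.median(ys[-max(3, len(ys) // 10):]))
    a0 = max(ys[0] - c0, 1e-12)
    below = np.nonzero(ys <= c0 + a0 / np.e)[0]
    tau0 = float(ts[below[0]]) if len(below) else float(ts[-1] / 3.0)
    tau0 = max(tau0, float(ts[1]))
    if np.ptp(ys) < 1e-12:
        return None, None, None, ("no_decay",)
    try:
        popt, _ = curve_fit(
            lambda tt, c, a, tau: c + a * np.exp(-tt / tau),
            ts, ys, p0=[c0, a0, tau0],
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=5000)
    except RuntimeError:
        return None, None, None, ("non_convergence",)
    c, a, tau = popt
    resid = ys - (c + a * np.exp(-ts / tau))
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = float(1.0 - np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 0.0
    if tau <= 0:
        return None, None, None, ("nonpositive_tau",)
    return float(a), float(tau), r2, ()


def transient_metrics(trace: CorrectedTrace,
                      threshold_fraction: float = 0.10,
                      **segment_kwargs) -> list[TransientMetrics]:
    """Per-beat metrics for every resolvable transient in the trace."""
    out = []
    for w in segment_transients(trace, threshold_fraction, **segment_kwargs):
        ttp, f1 = time_to_peak(w, trace, threshold_fraction)
        width, f2 = fwhm(w, trace)
        a, tau, r2, f3 = fit_decay_tau(w, trace)
        out.append(TransientMetrics(w.beat, ttp, width, tau, a, r2,
                                    flags=f1 + f2 + f3))
    return out
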