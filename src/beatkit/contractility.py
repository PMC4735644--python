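"""Beating-EB video contractility: segmentation, fractional area change,
beat detection and spontaneous beating frequency.

The contracting embryoid body is isolated from the background by intensity
thresholding, its area is traced over time and normalized to its maximum
(fractional area change), and beats are detected as the local minima of
that trace — the extrema of contraction. Frequency is reported both as
beats / duration and as the inverse median inter-beat interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .io import FrameStack

__all__ = [
    "MaskStack", "AreaTrace", "BeatEvents", "FrequencyEstimate",
    "segment_stack", "area_trace", "detect_beats", "beat_frequency",
    "analyze_rois", "analyze_stack",
]


@dataclass
class MaskStack:
    """Per-frame binary object masks plus the threshold used for each frame.

    ``flagged_frames`` lists frame indices where segmentation found no
    object (the mask is left empty rather than silently zero-filled).
    """

    masks: np.ndarray                 # (T, H, W) bool
    thresholds: np.ndarray            # (T,)
    flagged_frames: list[int] = field(default_factory=list)


@dataclass
class AreaTrace:
    time: np.ndarray                  # s
    area: np.ndarray                  # px^2 (or um^2 when pixel_size known)
    fractional: np.ndarray            # area / max(area), in (0, 1]
    area_unit: str = "px^2"


@dataclass
class BeatEvents:
    """Times of maximum contraction (minima of fractional area)."""

    peak_times: np.ndarray            # s, strictly increasing
    depths: np.ndarray                # contraction depth, 1 - fractional at minimum

    @property
    def n_beats(self) -> int:
        return len(self.peak_times)


@dataclass
class FrequencyEstimate:
    frequency: float                  # Hz, by the primary (count) method
    method: str
    n_beats: int
    frequency_interval: float | None = None   # 1 / median inter-beat interval


def segment_stack(stack: FrameStack, policy: str = "otsu", *,
                  user_offset: float = 0.0, fixed_threshold: float | None = None,
                  quantile: float = 0.5, per_frame: bool = False,
                  smooth_sigma: float = 1.0) -> MaskStack:
    """Threshold every frame and keep the largest connected component.

    policy:
      - ``"otsu"`` (default): Otsu's threshold computed on the median frame
        and applied fixed across frames (a deterministic stand-in for
        interactive sliding-scale thresholding), plus ``user_offset``.
      - ``"fixed_threshold"``: use ``fixed_threshold`` directly.
      - ``"quantile"``: the given intensity quantile of the median frame.

    ``per_frame`` recomputes the otsu/quantile threshold on each frame
    (tolerant to slow brightness drift). Frames with an empty mask are
    flagged, not silently zeroed. Ties between equal-size components are
    broken by centroid proximity to the previous frame's component.
    """
    # mild blur suppresses speckle texture and sensor noise so the threshold
    # separates object from background, not bright texture from dark texture
    if smooth_sigma > 0:
        frames = np.stack([ndimage.gaussian_filter(f, smooth_sigma)
                           for f in stack.frames])
    else:
        frames = stack.frames
    median_frame = np.median(frames, axis=0)

    def _threshold(img: np.ndarray) -> float:
        if policy == "fixed_threshold":
            if fixed_threshold is None:
                raise ValueError("fixed_threshold policy requires a value")
            return float(fixed_threshold) + user_offset
        if policy == "otsu":
            if img.max() == img.min():
                return img.max() + 1.0  # uniform frame: nothing above threshold
            return float(threshold_otsu(img)) + user_offset
        if policy == "quantile":
            return float(np.quantile(img, quantile)) + user_offset
        raise ValueError(f"unknown threshold policy {policy!r}")

    global_thr = None if (per_frame or policy == "fixed_threshold") else _threshold(median_frame)

    T = frames.shape[0]
    masks = np.zeros(frames.shape, dtype=bool)
    thresholds = np.empty(T)
    flagged: list[int] = []
    prev_centroid: tuple[float, float] | None = None
    for k in range(T):
        thr = _threshold(frames[k]) if global_thr is None else global_thr
        thresholds[k] = thr
        binary = ndimage.binary_fill_holes(frames[k] > thr)
        if not binary.any():
            flagged.append(k)
            continue
        lab = label(binary)
        props = regionprops(lab)
        best = max(props, key=lambda p: (
            p.area,
            -np.hypot(p.centroid[0] - prev_centroid[0], p.centroid[1] - prev_centroid[1])
            if prev_centroid is not None else 0.0,
        ))
        masks[k] = lab == best.label
        prev_centroid = best.centroid
    if flagged:
        warnings.warn(f"{len(flagged)} frame(s) produced an empty mask", stacklevel=2)
    return MaskStack(masks, thresholds, flagged)


def area_trace(masks: MaskStack, stack: FrameStack) -> AreaTrace:
    """Per-frame object area, normalized to its maximum over the recording."""
    if masks.masks.shape != stack.frames.shape:
        raise ValueError("masks must align with the frame stack")
    areas = masks.masks.sum(axis=(1, 2)).astype(float)
    if areas.max() <= 0:
        raise ValueError("all masks are empty; cannot form an area trace")
    unit = "px^2"
    if stack.pixel_size is not None:
        areas = areas * stack.pixel_size ** 2
        unit = "um^2"
    return AreaTrace(stack.times, areas, areas / areas.max(), unit)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]


def detect_beats(trace: AreaTrace, *, min_depth: float = 0.01,
                 refractory: float | None = None,
                 smoothing_window: float | None = None) -> BeatEvents:
    """Beat events at local minima of the smoothed fractional-area trace.

    A minimum counts as a beat if its contraction depth (prominence of the
    dip) is at least ``min_depth`` and it is at least ``refractory`` seconds
    from the previous beat (deeper dip kept). Defaults: 3-frame moving
    average, refractory 0.125 s (a quarter period at the 2 Hz pacing
    ceiling of the study conditions).
    """
    if len(trace.fractional) < 3:
        raise ValueError("trace too short for beat detection")
    dt = float(np.median(np.diff(trace.time)))
    if smoothing_window is None:
        w = 3
    else:
        w = max(1, int(round(smoothing_window / dt)))
    if refractory is None:
        refractory = 0.125
    sm = _moving_average(trace.fractional, w)
    distance = max(1, int(round(refractory / dt)))
    idx, props = signal.find_peaks(-sm, prominence=min_depth, distance=distance)
    return BeatEvents(trace.time[idx], props["prominences"])


def beat_frequency(events: BeatEvents, duration: float,
                   method: str = "count_over_duration") -> FrequencyEstimate:
    """Spontaneous beating frequency from beat events.

    ``count_over_duration`` (default, robust to single missed beats) is
    n_beats / duration; the inverse-median-interval estimate is reported
    alongside whenever >= 2 events exist.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if method not in ("count_over_duration", "inverse_median_interval"):
        raise ValueError(f"unknown method {method!r}")
    f_count = events.n_beats / duration
    f_interval = None
    if events.n_beats >= 2:
        f_interval = 1.0 / float(np.median(np.diff(events.peak_times)))
    primary = f_count if method == "count_over_duration" else f_interval
    if primary is None:
        primary = f_count
        method = "count_over_duration"
    return FrequencyEstimate(primary, method, events.n_beats, f_interval)


def analyze_stack(stack: FrameStack, *, policy: str = "otsu",
                  min_depth: float = 0.01, refractory: float | None = None,
                  **segment_kwargs) -> tuple[AreaTrace, BeatEvents, FrequencyEstimate]:
    """Whole-field pipeline: segment -> area trace -> beats -> frequency."""
    masks = segment_stack(stack, policy, **segment_kwargs)
    trace = area_trace(masks, stack)
    events = detect_beats(trace, min_depth=min_depth, refractory=refractory)
    return trace, events, beat_frequency(events, stack.duration)


def analyze_rois(stack: FrameStack, roi_masks: list[np.ndarray], **kwargs
                 ) -> list[tuple[AreaTrace, BeatEvents, FrequencyEstimate]]:
    """Independent contractility analysis per region of interest.

    ROIs must be disjoint boolean masks over the frame; each is analysed as
    its own sub-video so independently beating foci report independent
    frequencies.
    """
    total = np.zeros(stack.frames.shape[1:], dtype=int)
    for roi in roi_masks:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != stack.frames.shape[1:]:
            raise ValueError("ROI shape must match frames")
        if not roi.any():
            raise ValueError("empty ROI")
        total += roi
    if (total > 1).any():
        raise ValueError("ROIs overlap")
    results = []
    for roi in roi_masks:
        roi = np.asarray(roi, dtype=bool)
        rs, cs = np.nonzero(roi)
        sub = stack.frames[:, rs.min():rs.max() + 1, cs.min():cs.max() + 1].copy()
        sub_roi = roi[rs.min():rs.max() + 1, cs.min():cs.max() + 1]
        sub[:, ~sub_roi] = stack.frames.min()
        sub_stack = FrameStack(sub, stack.frame_interval, stack.pixel_size)
        results.append(analyze_stack(sub_stack, **kwargs))
    return results
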