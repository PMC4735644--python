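"""Shared containers and file I/O for image stacks and traces.

Videos are exchanged as multipage TIFF (grayscale, 16-bit); time series as
two-column CSV (time, value); structured results as JSON sidecars.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames with a uniform frame interval.

    Parameters
    ----------
    frames : (T, H, W) float array
        Pixel intensities. Internally intensities are kept as floats; the
        nominal full scale is 1.0 but any positive scale is accepted
        (analyses are intensity-scale invariant where the contract says so).
    frame_interval : float
        Seconds between consecutive frames.
    pixel_size : float, optional
        Physical pixel size in micrometres per pixel, when known.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T>=2, H, W) array")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


def write_tiff_stack(path: str | Path, stack: FrameStack, *, full_scale: float | None = None) -> None:
    """Write a FrameStack as a 16-bit grayscale multipage TIFF.

    Intensities are linearly mapped so that ``full_scale`` (default: the
    stack maximum) becomes 65535; negative values clip to zero.
    """
    scale = float(full_scale if full_scale is not None else stack.frames.max())
    if scale <= 0:
        scale = 1.0
    data = np.clip(stack.frames / scale, 0.0, 1.0)
    tifffile.imwrite(str(path), (data * 65535.0 + 0.5).astype(np.uint16))


def read_tiff_stack(path: str | Path, frame_rate: float, pixel_size: float | None = None) -> FrameStack:
    """Read a multipage TIFF into a FrameStack (intensities rescaled to [0, 1])."""
    frames = tifffile.imread(str(path)).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames / 65535.0, frame_interval=1.0 / frame_rate, pixel_size=pixel_size)


def write_trace_csv(path: str | Path, time: np.ndarray, value: np.ndarray,
                    value_name: str = "value") -> None:
    pd.DataFrame({"time_s": np.asarray(time), value_name: np.asarray(value)}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time, value) CSV; extra columns are ignored."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyJSONEncoder) + "\n")
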