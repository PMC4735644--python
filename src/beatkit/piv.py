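"""Particle image velocimetry and strain metrics for beating-tissue videos.

Frame-pair displacements are estimated with a multi-pass FFT
cross-correlation (default interrogation windows 64 -> 32 -> 16 px, 50%
overlap), zero-mean correlation-coefficient normalization, a three-point
Gaussian subpixel peak fit, peak-ratio and median-absolute-deviation vector
validation with local-median replacement, and window offsets carried
between passes. From the velocity field the module derives a
contraction-positive scalar strain rate (negative divergence), its spatial
mean over the beating area per frame pair, and the study's contraction
metrics: cumulative strain (time-integral of the positive mean strain
rate) and strain per beat.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .io import FrameStack

__all__ = [
    "InterrogationPlan", "VelocityField", "StrainRateField", "StrainTrace",
    "ContractionMetrics", "HeatmapRender",
    "compute_displacement", "velocity_to_strain_rate", "strain_trace",
    "contraction_metrics", "render_velocity_heatmap", "analyze_stack_strain",
]


@dataclass(frozen=True)
class InterrogationPlan:
    """Multi-pass interrogation schedule.

    pass_sizes must be strictly decreasing and fit within the image; the
    optional mask (full-image boolean) restricts vectors to the tissue.
    """

    pass_sizes: tuple[int, ...] = (64, 32, 16)
    overlap_fraction: float = 0.5
    mask: np.ndarray | None = None
    peak_ratio_min: float = 1.3

    def __post_init__(self) -> None:
        sizes = tuple(self.pass_sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("pass_sizes must be strictly decreasing")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        object.__setattr__(self, "pass_sizes", sizes)


@dataclass
class VelocityField:
    """Displacement vectors (px per frame interval) on an interrogation grid.

    u is displacement along columns (x), v along rows (y); ``valid`` is
    False where the vector failed validation (such vectors are filled by
    the local median but remain flagged).
    """

    grid_x: np.ndarray          # (nx,) window-centre columns, px
    grid_y: np.ndarray          # (ny,) window-centre rows, px
    u: np.ndarray               # (ny, nx) px/frame
    v: np.ndarray               # (ny, nx) px/frame
    valid: np.ndarray           # (ny, nx) bool
    window: int = 16

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class StrainRateField:
    """Scalar strain rate (1/s, contraction-positive) and the underlying
    velocity-gradient tensor components on the interrogation grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    scalar: np.ndarray          # 1/s
    dudx: np.ndarray
    dudy: np.ndarray
    dvdx: np.ndarray
    dvdy: np.ndarray
    sign_convention: str = "contraction_positive"


@dataclass
class StrainTrace:
    """Spatially averaged strain rate per frame pair (length T-1)."""

    time: np.ndarray            # s, midpoint of each frame pair
    mean_strain_rate: np.ndarray  # 1/s


@dataclass
class ContractionMetrics:
    cumulative_strain: float    # dimensionless; integral of positive rate
    strain_per_beat: float | None
    n_beats: int


# --------------------------------------------------------------------------
# displacement estimation
# --------------------------------------------------------------------------

def _pass_grid(shape: tuple[int, int], win: int, overlap: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Top-left corners of interrogation windows covering the image."""
    h, w = shape
    step = max(1, int(round(win * (1.0 - overlap))))
    ys = np.arange(0, h - win + 1, step)
    xs = np.arange(0, w - win + 1, step)
    return ys, xs


def _subpixel_gaussian(c: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation per axis, parabolic fallback."""
    out = []
    for axis, i in ((0, iy), (1, ix)):
        if axis == 0:
            cm, c0, cp = c[i - 1, ix], c[i, ix], c[i + 1, ix]
        else:
            cm, c0, cp = c[iy, i - 1], c[iy, i], c[iy, i + 1]
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
            denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
            out.append((lm - lp) / denom if denom != 0 else 0.0)
        else:  # parabolic: log undefined for nonpositive correlation values
            denom = 2.0 * (cm - 2.0 * c0 + cp)
            out.append((cm - cp) / denom if denom != 0 else 0.0)
    return out[0], out[1]


def _local_median_fill(u: np.ndarray, v: np.ndarray, good: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Replace bad vectors by the median of valid 3x3 neighbours, iterating
    outward until every vector is filled."""
    u, v = u.copy(), v.copy()
    good = good.copy()
    ny, nx = u.shape
    for _ in range(ny * nx):
        bad = ~good
        if not bad.any():
            break
        progressed = False
        for iy, ix in zip(*np.nonzero(bad)):
            ys = slice(max(iy - 1, 0), min(iy + 2, ny))
            xs = slice(max(ix - 1, 0), min(ix + 2, nx))
            nb = good[ys, xs]
            if nb.any():
                u[iy, ix] = np.median(u[ys, xs][nb])
                v[iy, ix] = np.median(v[ys, xs][nb])
                good[iy, ix] = True
                progressed = True
        if not progressed:  # no valid vector anywhere
            u[bad] = 0.0
            v[bad] = 0.0
            break
    return u, v


def _normalized_median_outliers(u: np.ndarray, v: np.ndarray, good: np.ndarray,
                                threshold: float = 2.0, eps: float = 0.1
                                ) -> np.ndarray:
    """Local normalized-median vector validation (universal outlier test).

    Each vector is compared with the median of its valid 3x3 neighbours,
    normalized by the neighbourhood's median residual plus a noise floor
    ``eps`` (px). Unlike a global filter this keeps the large-but-correct
    vectors of a strained field (e.g. the fast-moving rim of a contracting
    disk) while still catching isolated spurious correlations.
    """
    ny, nx = u.shape
    out = good.copy()
    for iy in range(ny):
        for ix in range(nx):
            if not good[iy, ix]:
                continue
            ys = slice(max(iy - 1, 0), min(iy + 2, ny))
            xs = slice(max(ix - 1, 0), min(ix + 2, nx))
            nb = good[ys, xs].copy()
            nb[iy - ys.start, ix - xs.start] = False
            if nb.sum() < 3:
                continue
            r = 0.0
            for comp in (u, v):
                vals = comp[ys, xs][nb]
                med = np.median(vals)
                resid = np.median(np.abs(vals - med))
                r = max(r, abs(comp[iy, ix] - med) / (resid + eps))
            if r > threshold:
                out[iy, ix] = False
    return out


def compute_displacement(frame_a: np.ndarray, frame_b: np.ndarray,
                         plan: InterrogationPlan = InterrogationPlan()
                         ) -> VelocityField:
    """Estimate the displacement field carrying frame A onto frame B.

    Each interrogation window is zero-meaned and FFT cross-correlated with
    the corresponding (offset) window of frame B; the correlation peak is
    refined by a three-point Gaussian fit per axis. Later passes start from
    the previous pass's field as integer window offsets. Vectors failing
    the peak-ratio test (first/second peak < plan.peak_ratio_min) or the
    global MAD filter are flagged invalid and replaced by the local median.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be equal-shaped 2-D arrays")
    if plan.pass_sizes[0] > min(a.shape):
        raise ValueError("interrogation window larger than image")

    prev: VelocityField | None = None
    for win in plan.pass_sizes:
        ys, xs = _pass_grid(a.shape, win, plan.overlap_fraction)
        cy = ys + (win - 1) / 2.0
        cx = xs + (win - 1) / 2.0
        ny, nx = len(ys), len(xs)
        u = np.zeros((ny, nx))
        v = np.zeros((ny, nx))
        good = np.ones((ny, nx), dtype=bool)
        masked = np.zeros((ny, nx), dtype=bool)

        if prev is not None:
            # nearest-grid-point predictor from the previous pass
            init_u = _interp_to(prev, cy, cx, comp="u")
            init_v = _interp_to(prev, cy, cx, comp="v")
        else:
            init_u = np.zeros((ny, nx))
            init_v = np.zeros((ny, nx))

        search = win // 2  # lag range per pass, +/- search px around the offset
        h_img, w_img = a.shape
        for iy, y0 in enumerate(ys):
            for ix, x0 in enumerate(xs):
                if plan.mask is not None:
                    my, mx = int(round(cy[iy])), int(round(cx[ix]))
                    if not plan.mask[my, mx]:
                        masked[iy, ix] = True
                        good[iy, ix] = False
                        continue
                oy = int(round(init_v[iy, ix]))
                ox = int(round(init_u[iy, ix]))
                wa = a[y0:y0 + win, x0:x0 + win]
                if wa.std() < 1e-12:
                    good[iy, ix] = False
                    continue
                # search region in B around the offset window, clipped
                ry0 = int(np.clip(y0 + oy - search, 0, h_img - win))
                rx0 = int(np.clip(x0 + ox - search, 0, w_img - win))
                ry1 = int(np.clip(y0 + oy + win + search, win, h_img))
                rx1 = int(np.clip(x0 + ox + win + search, win, w_img))
                region = b[ry0:ry1, rx0:rx1]
                if region.std() < 1e-12 or min(region.shape) < win + 2:
                    good[iy, ix] = False
                    continue
                # per-lag normalized cross-correlation (correlation
                # coefficient at every candidate offset)
                c = match_template(region, wa, pad_input=False)
                piy, pix = np.unravel_index(np.argmax(c), c.shape)
                # a peak on the map border means the true displacement may
                # lie outside the searched range — unless the search was
                # already clipped by the image boundary on that side, in
                # which case the border is as far as anything could look
                y_low_clip = y0 + oy - search < 0
                y_high_clip = y0 + oy + win + search > h_img
                x_low_clip = x0 + ox - search < 0
                x_high_clip = x0 + ox + win + search > w_img
                if ((piy == 0 and not y_low_clip)
                        or (piy == c.shape[0] - 1 and not y_high_clip)
                        or (pix == 0 and not x_low_clip)
                        or (pix == c.shape[1] - 1 and not x_high_clip)):
                    good[iy, ix] = False
                    v[iy, ix] = (ry0 + piy) - y0
                    u[iy, ix] = (rx0 + pix) - x0
                    continue
                # peak-ratio validation against the second (detached) peak;
                # a 5x5 exclusion keeps the shoulder of the first peak out
                cmin = c.min()
                c2 = c.copy()
                c2[max(piy - 2, 0):piy + 3, max(pix - 2, 0):pix + 3] = cmin
                p2 = c2.max() - cmin
                p1 = c[piy, pix] - cmin
                if p2 > 0 and p1 / p2 < plan.peak_ratio_min:
                    good[iy, ix] = False
                # a perfect correlation (coefficient 1) is an exact integer
                # match; subpixel refinement would only add window-edge bias
                if (c[piy, pix] >= 1.0 - 1e-9
                        or piy in (0, c.shape[0] - 1)
                        or pix in (0, c.shape[1] - 1)):
                    dsy = dsx = 0.0
                else:
                    dsy, dsx = _subpixel_gaussian(c, piy, pix)
                v[iy, ix] = (ry0 + piy) - y0 + dsy
                u[iy, ix] = (rx0 + pix) - x0 + dsx

        good_val = _normalized_median_outliers(u, v, good)
        u, v = _local_median_fill(u, v, good_val)
        prev = VelocityField(cx, cy, u, v, good_val & ~masked, window=win)
    return prev


def _interp_to(field: VelocityField, cy: np.ndarray, cx: np.ndarray,
               comp: str) -> np.ndarray:
    """Nearest-neighbour interpolation of a field component onto a new grid."""
    data = field.u if comp == "u" else field.v
    iy = np.clip(np.searchsorted(field.grid_y, cy), 0, len(field.grid_y) - 1)
    ix = np.clip(np.searchsorted(field.grid_x, cx), 0, len(field.grid_x) - 1)
    return data[np.ix_(iy, ix)]


# --------------------------------------------------------------------------
# strain
# --------------------------------------------------------------------------

def velocity_to_strain_rate(field: VelocityField, frame_interval: float
                            ) -> StrainRateField:
    """Velocity-gradient tensor and the contraction-positive scalar rate.

    Gradients are central differences on the interrogation grid; the scalar
    is the negative divergence, ``-(du/dx + dv/dy) / frame_interval``, so a
    contracting (inflowing) tissue gives a positive strain rate.
    """
    if field.u.shape[0] < 2 or field.u.shape[1] < 2:
        raise ValueError("need at least a 2x2 vector grid")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    dudy, dudx = np.gradient(field.u, field.grid_y, field.grid_x)
    dvdy, dvdx = np.gradient(field.v, field.grid_y, field.grid_x)
    scalar = -(dudx + dvdy) / frame_interval
    return StrainRateField(field.grid_x, field.grid_y, scalar,
                           dudx / frame_interval, dudy / frame_interval,
                           dvdx / frame_interval, dvdy / frame_interval)


def strain_trace(fields: Sequence[StrainRateField], frame_interval: float, *,
                 mask: np.ndarray | None = None,
                 time_offset: float = 0.0) -> StrainTrace:
    """Spatial mean of the scalar strain rate per frame pair.

    ``mask`` is a full-image boolean sampled at the interrogation-grid
    centres (the beating area); without a mask the whole grid is averaged.
    """
    if not fields:
        raise ValueError("no strain-rate fields")
    means = []
    for f in fields:
        if mask is not None:
            iy = np.clip(np.round(f.grid_y).astype(int), 0, mask.shape[0] - 1)
            ix = np.clip(np.round(f.grid_x).astype(int), 0, mask.shape[1] - 1)
            sel = mask[np.ix_(iy, ix)]
            if not sel.any():
                raise ValueError("mask excludes every grid point")
            means.append(float(f.scalar[sel].mean()))
        else:
            means.append(float(f.scalar.mean()))
    time = time_offset + (np.arange(len(fields)) + 0.5) * frame_interval
    return StrainTrace(time, np.asarray(means))


def contraction_metrics(trace: StrainTrace, n_beats: int) -> ContractionMetrics:
    """Cumulative strain and strain per beat.

    Cumulative strain is the time-integral of the positive part of the mean
    strain rate (sum x frame interval, dimensionless); strain per beat
    divides it by the number of contractions, absent when no beats occurred.
    """
    if len(trace.time) >= 2:
        dt = float(np.median(np.diff(trace.time)))
    else:
        dt = 0.0
    cumulative = float(np.sum(np.clip(trace.mean_strain_rate, 0.0, None)) * dt)
    per_beat = cumulative / n_beats if n_beats > 0 else None
    return ContractionMetrics(cumulative, per_beat, n_beats)


def analyze_stack_strain(stack: FrameStack, plan: InterrogationPlan = InterrogationPlan(),
                         *, mask: np.ndarray | None = None
                         ) -> tuple[list[StrainRateField], StrainTrace]:
    """Run PIV over all consecutive frame pairs and trace the mean rate.

    Without an explicit mask the beating area is derived automatically: the
    tissue is segmented in every frame, the always-tissue region (logical
    AND across frames) is eroded by three quarters of the final
    interrogation window so that averaged vectors sit fully on tissue —
    the analysis window is thereby restricted to the contracting object,
    as strain mapping of an isolated EB requires.
    """
    if mask is None:
        from . import contractility as _con
        seg = _con.segment_stack(stack)
        core = seg.masks.all(axis=0)
        if core.any():
            it = max(1, int(round(plan.pass_sizes[-1] * 0.75)))
            eroded = ndimage.binary_erosion(core, iterations=it)
            mask = eroded if eroded.any() else core
    fields = []
    for k in range(stack.n_frames - 1):
        vf = compute_displacement(stack.frames[k], stack.frames[k + 1], plan)
        fields.append(velocity_to_strain_rate(vf, stack.frame_interval))
    return fields, strain_trace(fields, stack.frame_interval, mask=mask)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass
class HeatmapRender:
    speed_um_s: np.ndarray      # raw speeds, um/s
    clipped: np.ndarray         # speeds clipped to colour_limits
    colour_limits: tuple[float, float]
    clip_fraction: float        # fraction of vectors at/above the upper limit

    def save(self, path, cmap: str = "jet") -> None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.clipped, vmin=self.colour_limits[0],
                       vmax=self.colour_limits[1], cmap=cmap, origin="upper")
        fig.colorbar(im, ax=ax, label="speed (um/s)")
        ax.set_xticks([]), ax.set_yticks([])
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def render_velocity_heatmap(field: VelocityField, pixel_size: float,
                            frame_interval: float,
                            colour_limits: tuple[float, float] = (0.0, 28.0)
                            ) -> HeatmapRender:
    """Speed-magnitude heat map on a fixed colour scale (default 0-28 um/s,
    so maps from different recordings are directly comparable)."""
    if pixel_size is None or pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("physical units (pixel_size, frame_interval) required")
    speed = field.speed * pixel_size / frame_interval
    lo, hi = colour_limits
    clipped = np.clip(speed, lo, hi)
    return HeatmapRender(speed, clipped, (float(lo), float(hi)),
                         float(np.mean(speed >= hi)))
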