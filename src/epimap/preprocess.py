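"""Fluorescence signal conditioning.

The conditioning chain runs in a fixed order — ROI masking, bad-pixel
exclusion (saturation, low variance), per-pixel linear detrend, zero-phase
Butterworth low-pass, background subtraction, 1–100 normalization, and a 5×5
masked spatial mean filter. Reordering these stages changes the result (the
normalization fixes the scale the spatial filter averages on, the detrend must
precede the background estimate, ...), so :func:`preprocess_movie` is the only
supported entry point for the full chain; the individual stages are exposed
for testing and for partial pipelines.

Pixels are excluded, never repaired: each excluded pixel carries the single
reason that first removed it, and no later stage reinstates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage, signal

from .io import MovieStack

__all__ = [
    "Reason",
    "PixelMask",
    "PreprocessConfig",
    "apply_roi",
    "exclude_bad_pixels",
    "detrend",
    "lowpass",
    "subtract_background",
    "normalize",
    "spatial_mean_filter",
    "preprocess_movie",
]


class Reason(IntEnum):
    """Primary exclusion reason per pixel (0 = included)."""

    INCLUDED = 0
    OUT_OF_ROI = 1
    SATURATED = 2
    LOW_VARIANCE = 3
    MANUAL = 4


@dataclass
class PixelMask:
    """Boolean inclusion map plus one primary exclusion reason per pixel."""

    included: np.ndarray  # (H, W) bool
    reason: np.ndarray  # (H, W) uint8, Reason codes

    @classmethod
    def full(cls, grid: tuple[int, int]) -> "PixelMask":
        return cls(np.ones(grid, bool), np.zeros(grid, np.uint8))

    def exclude(self, where: np.ndarray, reason: Reason) -> "PixelMask":
        """Return a new mask with ``where`` pixels (if still included)
        excluded for ``reason``; already-excluded pixels keep their reason."""
        newly = np.asarray(where, bool) & self.included
        inc = self.included & ~newly
        rsn = self.reason.copy()
        rsn[newly] = int(reason)
        return PixelMask(inc, rsn)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass
class PreprocessConfig:
    lowpass_cutoff: float = 40.0  # Hz; the acquisition band allows 40–45
    filter_order: int = 4
    variance_threshold: float | None = None  # counts²; None → adaptive
    off_tissue_mask: np.ndarray | None = None  # optional off-tissue region
    saturation_level: float | None = None  # None → movie metadata
    normalization_range: tuple[float, float] = (1.0, 100.0)
    spatial_kernel: int = 5
    background_percentile: float = 5.0
    motion_registration: object = None  # hook: callable(frames)->frames

    def __post_init__(self) -> None:
        if not 40.0 <= self.lowpass_cutoff <= 45.0:
            raise ValueError("lowpass_cutoff must lie in the 40–45 Hz band")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")


def apply_roi(movie: MovieStack, roi_polygon) -> PixelMask:
    """Mask pixels whose centers fall inside the region-of-interest polygon.

    The polygon is a sequence of (x, y) = (col, row) vertices, drawn to keep
    the chamber of interest and drop neighbouring chambers and curved edges.
    """
    verts = np.asarray(roi_polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("roi_polygon needs at least 3 (x, y) vertices")
    h, w = movie.grid
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    inside = MplPath(verts).contains_points(pts).reshape(h, w)
    mask = PixelMask.full((h, w))
    return mask.exclude(~inside, Reason.OUT_OF_ROI)


def exclude_bad_pixels(
    movie: MovieStack, mask: PixelMask, config: PreprocessConfig | None = None
) -> PixelMask:
    """Drop saturated pixels (any sample at/above the sensor ceiling) and
    pixels with low temporal variance (off-tissue, dead, or unstained).

    The variance threshold is, in order of preference: 4× the median variance
    of a user-marked off-tissue region; an absolute configured value; else
    5 % of the median variance of the currently included pixels.
    """
    config = config or PreprocessConfig()
    sat = config.saturation_level
    if sat is None:
        sat = movie.meta.get("saturation_level", np.inf)
    frames = movie.frames
    saturated = (frames >= sat).any(axis=0)
    mask = mask.exclude(saturated, Reason.SATURATED)

    var = frames.var(axis=0)
    if config.off_tissue_mask is not None:
        thr = 4.0 * np.median(var[np.asarray(config.off_tissue_mask, bool)])
    elif config.variance_threshold is not None:
        thr = config.variance_threshold
    else:
        thr = 0.05 * np.median(var[mask.included]) if mask.n_included else 0.0
    mask = mask.exclude(var < thr, Reason.LOW_VARIANCE)
    if mask.n_included == 0:
        warnings.warn("all pixels excluded", stacklevel=2)
    return mask


def detrend(signal_in: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from each trace (last axis)."""
    x = np.asarray(signal_in, float)
    if x.shape[-1] < 2:
        raise ValueError("traces need at least 2 samples")
    return signal.detrend(x, axis=-1, type="linear")


def lowpass(
    signal_in: np.ndarray,
    frame_rate: float,
    cutoff: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth low-pass along the last axis."""
    nyq = frame_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(signal_in, float), axis=-1)


def subtract_background(signal_in: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Subtract the per-trace background fluorescence, estimated as a low
    percentile of the (detrended) trace — a robust diastolic floor."""
    x = np.asarray(signal_in, float)
    bg = np.percentile(x, percentile, axis=-1, keepdims=True)
    return x - bg


def normalize(signal_in: np.ndarray, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    """Affinely map each trace so min → ``lo`` and max → ``hi`` exactly."""
    x = np.asarray(signal_in, float)
    mn = x.min(axis=-1, keepdims=True)
    mx = x.max(axis=-1, keepdims=True)
    if np.any(mx == mn):
        raise ValueError("constant trace cannot be normalized")
    return lo + (x - mn) * (hi - lo) / (mx - mn)


def spatial_mean_filter(
    frames: np.ndarray, mask: PixelMask, kernel: int = 5
) -> np.ndarray:
    """Replace each included pixel by the mean of the included pixels in its
    ``kernel``×``kernel`` neighbourhood; excluded pixels pass through
    untouched. Edges use the available included neighbours (no padding)."""
    frames = np.asarray(frames, float)
    inc = mask.included.astype(float)
    size = (1, kernel, kernel) if frames.ndim == 3 else (kernel, kernel)
    num = ndimage.uniform_filter(frames * inc, size=size, mode="constant")
    den = ndimage.uniform_filter(inc, size=(kernel, kernel), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den
    out = frames.copy()
    out[..., mask.included] = mean[..., mask.included]
    return out


def preprocess_movie(
    movie: MovieStack,
    roi_polygon=None,
    config: PreprocessConfig | None = None,
    mask: PixelMask | None = None,
) -> tuple[MovieStack, PixelMask]:
    """Run the full conditioning chain in its fixed order and return the
    conditioned movie plus the final pixel mask with reason codes.

    ``roi_polygon`` may be omitted to analyze the whole frame (or pass a
    precomputed ``mask``). ``config.motion_registration`` is an optional hook
    called on the raw frames before any other stage; no registration is
    bundled.
    """
    config = config or PreprocessConfig()
    frames = np.asarray(movie.frames, float)
    if config.motion_registration is not None:
        frames = config.motion_registration(frames)
        movie = MovieStack(frames, movie.frame_rate, movie.pixel_pitch, movie.meta)

    if mask is None:
        if roi_polygon is not None:
            mask = apply_roi(movie, roi_polygon)
        else:
            mask = PixelMask.full(movie.grid)
    mask = exclude_bad_pixels(movie, mask, config)

    t, h, w = frames.shape
    traces = frames.reshape(t, h * w).T  # (H·W, T)
    traces = detrend(traces)
    traces = lowpass(traces, movie.frame_rate, config.lowpass_cutoff, config.filter_order)
    traces = subtract_background(traces, config.background_percentile)

    lo, hi = config.normalization_range
    mn = traces.min(axis=-1)
    mx = traces.max(axis=-1)
    flat = (mx == mn).reshape(h, w)
    mask = mask.exclude(flat, Reason.LOW_VARIANCE)
    ok = ~flat.ravel()
    traces[ok] = lo + (traces[ok] - mn[ok, None]) * (hi - lo) / (mx[ok] - mn[ok])[:, None]

    frames_out = traces.T.reshape(t, h, w)
    frames_out = spatial_mean_filter(frames_out, mask, config.spatial_kernel)
    out = MovieStack(frames_out, movie.frame_rate, movie.pixel_pitch, dict(movie.meta))
    out.meta["conditioned"] = True
    return out, mask
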