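"""Conduction-velocity vectors from activation-time maps.

CV at a pixel is estimated by least-squares fitting a plane t = a·x + b·y + c
to the local spatial distribution (x, y, t) of activation times. The fitted
gradient (a, b) is the slowness vector of the wavefront (ms/µm); the velocity
is its reciprocal vector v = ∇t / |∇t|², pointing in the propagation
direction with speed 1/|∇t| (reported in cm/s; 1 µm/ms = 0.1 cm/s).

Fits are restricted to a square spatial window around each pixel and to
neighbours whose AT lies within a time window that scales with the local AT
gradient — |Δt| ≤ α · r · pitch · |∇t| with the gradient taken from a
first-pass unrestricted fit — which drops across-wavefront discontinuities
while tolerating front curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import N_AVERAGED_BEATS, PclMaps

__all__ = ["CVConfig", "CVResult", "fit_local_plane", "velocity_from_gradient", "cv_maps"]

UM_PER_MS_TO_CM_PER_S = 0.1


@dataclass
class CVConfig:
    spatial_halfwidth: int = 3  # pixels; 3 → a 7×7 window
    time_window_factor: float = 2.0  # α in the gradient-scaled time window
    noise_floor_factor: float = 2.0  # × robust AT noise scale added to the window
    min_points: int = 10

    def __post_init__(self) -> None:
        if self.spatial_halfwidth < 1 or self.min_points < 3:
            raise ValueError("window too small for a plane fit")
        if self.time_window_factor <= 0:
            raise ValueError("time_window_factor must be positive")


#: Gradients below this (ms/µm) are indistinguishable from a flat AT field.
_FLAT_GRADIENT = 1e-12


@dataclass
class CVResult:
    """Per-beat velocity fields and their per-pixel mean for one PCL."""

    pcl: float
    vx: np.ndarray  # (n_beats, H, W) cm/s, x = columns
    vy: np.ndarray  # cm/s, y = rows
    speed: np.ndarray  # (n_beats, H, W) cm/s
    residual_ms: np.ndarray  # RMS plane-fit residual
    n_points: np.ndarray  # neighbours used
    speed_mean: np.ndarray  # (H, W) mean over valid beats
    global_mean: float  # mean of speed_mean over defined pixels


def _plane_lsq(dx: np.ndarray, dy: np.ndarray, t: np.ndarray):
    """LSQ plane t = a·dx + b·dy + c; returns (a, b, rms residual)."""
    g = np.column_stack([dx, dy, np.ones_like(dx)])
    coef, *_ = np.linalg.lstsq(g, t, rcond=None)
    res = t - g @ coef
    return coef[0], coef[1], float(np.sqrt(np.mean(res**2)))


def fit_local_plane(
    at_map: np.ndarray,
    pixel: tuple[int, int],
    pixel_pitch: float,
    config: CVConfig | None = None,
):
    """Fit the local AT plane at ``pixel``.

    Returns ``(gradient, residual_ms, n_points)`` with the gradient in ms/µm
    (x, y) = (columns, rows), or ``(None, reason, n)`` when the fit is
    undefined (``"sparse"`` too few neighbours, ``"flat"`` zero gradient).
    """
    config = config or CVConfig()
    at_map = np.asarray(at_map, float)
    h, w = at_map.shape
    r, c = pixel
    hw = config.spatial_halfwidth
    r0, r1 = max(r - hw, 0), min(r + hw + 1, h)
    c0, c1 = max(c - hw, 0), min(c + hw + 1, w)
    sub = at_map[r0:r1, c0:c1]
    rows, cols = np.nonzero(np.isfinite(sub))
    if rows.size < config.min_points:
        return None, "sparse", int(rows.size)
    t = sub[rows, cols]
    dx = (cols + c0 - c) * pixel_pitch
    dy = (rows + r0 - r) * pixel_pitch
    a, b, _ = _plane_lsq(dx, dy, t)
    gnorm = np.hypot(a, b)
    if gnorm < _FLAT_GRADIENT:
        return None, "flat", int(rows.size)
    # gradient-scaled time window around the center's fitted AT, widened by a
    # robust estimate of the AT noise so that noise alone cannot truncate the
    # local plane (which would bias the slope low); wavefront discontinuities
    # are orders of magnitude above both terms.
    if np.isfinite(at_map[r, c]):
        t_center = at_map[r, c]
    else:
        t_center = float(np.median(t))
    g = np.array([a, b])
    resid = t - (dx * a + dy * b + np.median(t - dx * a - dy * b))
    sigma = 1.4826 * float(np.median(np.abs(resid)))
    tw = config.time_window_factor * (
        hw * pixel_pitch * gnorm + config.noise_floor_factor * sigma
    )
    keep = np.abs(t - t_center) <= tw
    if keep.sum() < config.min_points:
        return None, "sparse", int(keep.sum())
    a, b, rms = _plane_lsq(dx[keep], dy[keep], t[keep])
    if np.hypot(a, b) < _FLAT_GRADIENT:
        return None, "flat", int(keep.sum())
    return np.array([a, b]), rms, int(keep.sum())


def velocity_from_gradient(gradient: np.ndarray) -> tuple[np.ndarray, float]:
    """Velocity vector (cm/s) from an AT gradient (ms/µm): v = ∇t/|∇t|²,
    magnitude 1/|∇t|, pointing down the wavefront's travel direction."""
    g = np.asarray(gradient, float)
    n2 = float(g @ g)
    if n2 == 0:
        raise ValueError("zero gradient has no defined velocity")
    v_um_ms = g / n2
    v = v_um_ms * UM_PER_MS_TO_CM_PER_S
    return v, float(np.hypot(*v))


def cv_maps(
    at_maps: np.ndarray,
    pixel_pitch: float,
    pcl: float = np.nan,
    config: CVConfig | None = None,
    maps: PclMaps | None = None,
) -> CVResult:
    """Per-beat CV fields from a stack of AT maps (n_beats, H, W) — normally
    the last four analyzed beats — plus their per-pixel and global means.

    When ``maps`` is given, its ``cv_mean`` field is filled in place.
    """
    config = config or CVConfig()
    at_maps = np.asarray(at_maps, float)
    if at_maps.ndim == 2:
        at_maps = at_maps[None]
    nb, h, w = at_maps.shape
    vx = np.full((nb, h, w), np.nan)
    vy = np.full((nb, h, w), np.nan)
    speed = np.full((nb, h, w), np.nan)
    resid = np.full((nb, h, w), np.nan)
    npts = np.zeros((nb, h, w), np.int32)
    for i in range(nb):
        at = at_maps[i]
        for r, c in zip(*np.nonzero(np.isfinite(at))):
            grad, info, n = fit_local_plane(at, (r, c), pixel_pitch, config)
            npts[i, r, c] = n
            if grad is None:
                continue
            v, s = velocity_from_gradient(grad)
            vx[i, r, c], vy[i, r, c] = v
            speed[i, r, c] = s
            resid[i, r, c] = info
    with np.errstate(invalid="ignore"):
        speed_mean = np.nanmean(speed, axis=0)
    defined = np.isfinite(speed_mean)
    global_mean = float(speed_mean[defined].mean()) if defined.any() else np.nan
    result = CVResult(pcl, vx, vy, speed, resid, npts, speed_mean, global_mean)
    if maps is not None:
        maps.cv_mean = speed_mean
    return result


def cv_for_pcl(maps: PclMaps, pixel_pitch: float, config: CVConfig | None = None) -> CVResult:
    """CV maps for one PCL's measured beats (the last four of the analyzed
    five), averaging exactly the beats that enter the APD per-pixel mean."""
    nb = maps.at_ms.shape[0]
    at_last4 = maps.at_ms[nb - N_AVERAGED_BEATS :]
    return cv_maps(at_last4, pixel_pitch, maps.pcl, config, maps)
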