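"""APD_60-vs-DI dispersion about the global mean restitution point.

At a single PCL, every pixel's (DI, APD_60) per-pixel mean is located in
restitution space by polar coordinates about the global mean restitution
point: radial distance (ms) and radial angle (degrees CCW from a +DI unit
vector at the mean). Tissue that adapts appropriately to the PCL lies on the
predicted line PCL = APD + DI; points on that line sit at exactly 135° or
315° from the mean (when the mean itself is on the line), so the fraction of
pixels inside 10° segments centered at 135° and 315° quantifies appropriately
adapting epicardium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import PclMaps
from .restitution import RestitutionPoint

__all__ = [
    "SegmentConfig",
    "DispersionResult",
    "radial_coordinates",
    "line_residual",
    "segment_fraction",
    "dispersion_maps",
]


@dataclass
class SegmentConfig:
    centers: tuple[float, float] = (135.0, 315.0)  # degrees
    width: float = 10.0  # full segment width, degrees

    def in_segment(self, angle_deg: np.ndarray) -> np.ndarray:
        """Inclusive membership of angles in any configured segment."""
        a = np.asarray(angle_deg, float) % 360.0
        half = self.width / 2.0
        hit = np.zeros(a.shape, bool)
        for c in self.centers:
            d = np.abs((a - c + 180.0) % 360.0 - 180.0)
            hit |= d <= half
        hit &= np.isfinite(a)
        return hit


def radial_coordinates(
    pixel_point: tuple[float, float], global_mean: tuple[float, float]
) -> tuple[float, float]:
    """(distance_ms, angle_deg) of a pixel's (DI, APD_60) point about the
    global mean restitution point; the angle is NaN at zero distance."""
    ddi = pixel_point[0] - global_mean[0]
    dapd = pixel_point[1] - global_mean[1]
    dist = float(np.hypot(ddi, dapd))
    if dist == 0.0:
        return 0.0, float("nan")
    return dist, float(np.degrees(np.arctan2(dapd, ddi)) % 360.0)


def line_residual(apd_ms: float, di_ms: float, pcl: float) -> float:
    """Signed offset (ms) of a point from the predicted PCL = APD + DI line:
    zero iff the pixel adapted exactly to the pacing cycle length."""
    return (apd_ms + di_ms) - pcl


def segment_fraction(
    angles_deg: np.ndarray, config: SegmentConfig | None = None
) -> float:
    """Percent of defined-angle points inside the configured 10° segments.
    Zero-distance (undefined-angle) points are excluded from the denominator."""
    config = config or SegmentConfig()
    a = np.asarray(angles_deg, float)
    defined = np.isfinite(a)
    if not defined.any():
        raise ValueError("no points with a defined radial angle")
    return 100.0 * config.in_segment(a)[defined].sum() / defined.sum()


@dataclass
class DispersionResult:
    pcl: float
    distance_ms: np.ndarray  # (H, W)
    angle_deg: np.ndarray  # (H, W), NaN where undefined
    line_residual_ms: np.ndarray  # (H, W)
    in_segment: np.ndarray  # (H, W) bool marker mask
    fraction_pct: float
    hist: np.ndarray  # 2-D (DI, APD) histogram counts, display-only
    hist_di_edges: np.ndarray
    hist_apd_edges: np.ndarray


def dispersion_maps(
    maps: PclMaps,
    global_point: RestitutionPoint,
    config: SegmentConfig | None = None,
    hist_bin_ms: float = 1.0,
) -> DispersionResult:
    """Radial distance/angle maps, PCL-line residuals, in-segment marker mask,
    segment fraction, and a display 2-D histogram for one PCL."""
    config = config or SegmentConfig()
    di = maps.di_mean
    apd = maps.apd60_mean
    ok = np.isfinite(di) & np.isfinite(apd)
    ddi = di - global_point.di_ms
    dapd = apd - global_point.apd60_ms
    dist = np.hypot(ddi, dapd)
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(dapd, ddi)) % 360.0
    angle[~ok | (dist == 0)] = np.nan
    dist[~ok] = np.nan
    resid = (apd + di) - maps.pcl
    marker = config.in_segment(angle) & ok
    frac = segment_fraction(angle[ok]) if np.isfinite(angle[ok]).any() else np.nan

    di_v, apd_v = di[ok], apd[ok]
    if di_v.size:
        di_edges = _edges(di_v, hist_bin_ms)
        apd_edges = _edges(apd_v, hist_bin_ms)
        hist, _, _ = np.histogram2d(di_v, apd_v, bins=[di_edges, apd_edges])
    else:
        di_edges = apd_edges = np.array([0.0, 1.0])
        hist = np.zeros((1, 1))
    return DispersionResult(
        maps.pcl, dist, angle, resid, marker, frac, hist, di_edges, apd_edges
    )


def _edges(values: np.ndarray, bin_ms: float) -> np.ndarray:
    lo = np.floor(values.min() / bin_ms) * bin_ms
    hi = np.ceil(values.max() / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    return np.arange(lo, hi + bin_ms / 2, bin_ms)
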