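"""End-to-end per-heart analysis: movie → conditioned signals → per-beat
measurements → per-pixel maps → restitution points and dispersion statistics.

This is the orchestration layer the analysis drivers and the acceptance
script run; every step lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import PclMaps, conduction_loss, infer_capture, measure_pcl, segment_beats
from .cv import CVConfig, CVResult, cv_for_pcl
from .dispersion import DispersionResult, SegmentConfig, dispersion_maps
from .io import MovieStack
from .preprocess import PixelMask, PreprocessConfig, preprocess_movie
from .restitution import (
    RestitutionFit,
    RestitutionPoint,
    global_restitution_points,
    restitution_vector_angle,
)
from .synth import ProtocolSpec

__all__ = ["HeartResult", "analyze_movie"]


@dataclass
class HeartResult:
    """Everything the pipeline measures for one heart."""

    mask: PixelMask
    maps: dict[float, PclMaps]  # per analyzed PCL
    cv: dict[float, CVResult]
    captured: dict[float, bool]
    points: list[RestitutionPoint] = field(default_factory=list)
    vector_angle_deg: float = np.nan
    conduction_loss_pct: float = np.nan
    dispersion: dict[float, DispersionResult] = field(default_factory=dict)

    def point_at(self, pcl: float) -> RestitutionPoint | None:
        for p in self.points:
            if p.pcl == pcl:
                return p
        return None


def analyze_movie(
    movie: MovieStack,
    protocol: ProtocolSpec,
    roi_polygon=None,
    mask: PixelMask | None = None,
    config: PreprocessConfig | None = None,
    cv_config: CVConfig | None = None,
    segment_config: SegmentConfig | None = None,
    compute_cv: bool = True,
    dispersion_pcls: tuple[float, ...] = (250.0, 150.0),
    loss_pcls: tuple[float, float] = (250.0, 150.0),
) -> HeartResult:
    """Run the full analysis chain on one movie.

    PCLs that lost pacing capture are flagged and skipped. Conduction loss is
    computed between ``loss_pcls`` (slow, fast) when both are analyzed, the
    restitution vector angle from the 175→150 ms points when both exist, and
    dispersion maps at each PCL in ``dispersion_pcls``.
    """
    cond, pixmask = preprocess_movie(movie, roi_polygon, config, mask)
    windows = segment_beats(protocol, cond.n_frames)
    by_pcl: dict[float, list] = {}
    for win in windows:
        by_pcl.setdefault(win.pcl, []).append(win)

    maps: dict[float, PclMaps] = {}
    cv_res: dict[float, CVResult] = {}
    captured: dict[float, bool] = {}
    for pcl, wins in by_pcl.items():
        cap = infer_capture(cond, pixmask, wins)
        captured[pcl] = cap
        if not cap:
            continue
        m = measure_pcl(cond, pixmask, wins)
        m.captured = cap
        maps[pcl] = m
        if compute_cv:
            cv_res[pcl] = cv_for_pcl(m, cond.pixel_pitch, cv_config)

    result = HeartResult(mask=pixmask, maps=maps, cv=cv_res, captured=captured)
    result.points = global_restitution_points(maps)

    p175, p150 = result.point_at(175.0), result.point_at(150.0)
    if p175 is not None and p150 is not None:
        result.vector_angle_deg = restitution_vector_angle(p175, p150)

    slow, fast = loss_pcls
    if slow in maps and fast in maps:
        result.conduction_loss_pct = conduction_loss(maps[slow], maps[fast])

    for pcl in dispersion_pcls:
        point = result.point_at(pcl)
        if point is not None:
            result.dispersion[pcl] = dispersion_maps(maps[pcl], point, segment_config)
    return result
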