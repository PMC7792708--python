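"""APD_60 restitution: global points, monoexponential fits, vector angles.

The restitution curve is the monoexponential

    APD_60(DI) = APD_ss * (1 - b * exp(-DI / tau)),

fitted to (DI, APD_60) global-mean points (one per captured PCL) by bounded
nonlinear least squares. Cohorts are fitted in two stages: stage 1 pools every
restitution point of a group for one (APD_ss, b, tau); stage 2 refits APD_ss
for each heart with (b, tau) frozen at the group values — with the shape
factors s_i = 1 - b·exp(-DI_i/tau) fixed, that one-parameter fit is the
closed-form weighted ratio Σ(APD_i·s_i)/Σ(s_i²).

The restitution vector angle measures the transition between the 175 ms and
150 ms PCL points: the four-quadrant angle of (ΔDI, ΔAPD), counterclockwise
from the +DI axis, in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .beats import PclMaps

__all__ = [
    "RestitutionPoint",
    "RestitutionFit",
    "global_restitution_points",
    "fit_monoexponential",
    "two_stage_group_fit",
    "restitution_vector_angle",
    "per_pixel_vector_angle_map",
    "FIT_PCL_RANGE",
    "VECTOR_ANGLE_PCLS",
]

#: PCLs eligible for restitution fitting (the analyzed staircase span).
FIT_PCL_RANGE = (97.0, 250.0)
#: The restitution-vector-angle transition: 175 ms → 150 ms PCL.
VECTOR_ANGLE_PCLS = (175.0, 150.0)


@dataclass(frozen=True)
class RestitutionPoint:
    """Global mean (APD_60, DI, CV) over defined pixels at one PCL."""

    pcl: float
    apd60_ms: float
    di_ms: float
    cv_cm_s: float = np.nan
    n_pixels: int = 0


@dataclass
class RestitutionFit:
    apd_ss: float  # ms
    b: float
    tau: float  # ms
    residual_norm: float
    scope: str = "heart"  # "group" | "heart"
    converged: bool = True
    vector_angle_deg: float = np.nan

    def curve(self, di: np.ndarray) -> np.ndarray:
        return self.apd_ss * (1.0 - self.b * np.exp(-np.asarray(di, float) / self.tau))


def global_restitution_points(
    maps_by_pcl: dict[float, PclMaps], captured_pcls=None
) -> list[RestitutionPoint]:
    """One restitution point per captured PCL: means of the per-pixel mean
    maps over pixels where they are defined. PCLs with no defined pixels are
    omitted."""
    points = []
    for pcl in sorted(maps_by_pcl, reverse=True):
        if captured_pcls is not None and pcl not in captured_pcls:
            continue
        m = maps_by_pcl[pcl]
        ok = np.isfinite(m.apd60_mean) & np.isfinite(m.di_mean)
        if not ok.any():
            continue
        cv = np.nan
        if m.cv_mean is not None:
            cv_ok = np.isfinite(m.cv_mean)
            cv = float(m.cv_mean[cv_ok].mean()) if cv_ok.any() else np.nan
        points.append(
            RestitutionPoint(
                pcl=pcl,
                apd60_ms=float(m.apd60_mean[ok].mean()),
                di_ms=float(m.di_mean[ok].mean()),
                cv_cm_s=cv,
                n_pixels=int(ok.sum()),
            )
        )
    return points


def _apd_ss_closed_form(di, apd, b, tau) -> float:
    s = 1.0 - b * np.exp(-np.asarray(di, float) / tau)
    return float(np.dot(apd, s) / np.dot(s, s))


def fit_monoexponential(
    points,
    fixed_b_tau: tuple[float, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> RestitutionFit:
    """Fit APD_60 = APD_ss·(1 − b·exp(−DI/τ)) to restitution points.

    ``points`` is a sequence of RestitutionPoints or (di, apd) pairs. With
    ``fixed_b_tau`` only APD_ss is estimated (closed form). The free fit uses
    bounded least squares (APD_ss ∈ (0, 2·max APD], b ∈ [0, 1.5],
    τ ∈ (0, 1000] ms) from a fixed start, with jittered restarts if the
    optimizer fails to converge.
    """
    di, apd = _as_di_apd(points)
    if fixed_b_tau is not None:
        b, tau = fixed_b_tau
        if di.size < 1:
            raise ValueError("need at least one point")
        a = _apd_ss_closed_form(di, apd, b, tau)
        res = apd - a * (1.0 - b * np.exp(-di / tau))
        return RestitutionFit(a, b, tau, float(np.linalg.norm(res)))
    if di.size < 3:
        raise ValueError("need at least 3 points for the 3-parameter fit")

    apd_max = float(apd.max())
    lo = [1e-6, 0.0, 1e-3]
    hi = [2.0 * apd_max, 1.5, 1000.0]

    def model(p):
        return p[0] * (1.0 - p[1] * np.exp(-di / p[2])) - apd

    x0 = np.array([apd_max, 0.5, 50.0])
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        try:
            sol = least_squares(model, x0, bounds=(lo, hi))
        except Exception:
            sol = None
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
        if sol is not None and sol.success and sol.cost < 1e-20:
            break
        x0 = np.array(
            [
                apd_max * rng.uniform(0.6, 1.4),
                rng.uniform(0.1, 1.0),
                rng.uniform(10.0, 200.0),
            ]
        )
    if best is None:
        return RestitutionFit(np.nan, np.nan, np.nan, np.inf, converged=False)
    a, b, tau = best.x
    return RestitutionFit(
        float(a),
        float(b),
        float(tau),
        float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def _as_di_apd(points):
    di, apd = [], []
    for p in points:
        if isinstance(p, RestitutionPoint):
            di.append(p.di_ms)
            apd.append(p.apd60_ms)
        else:
            di.append(p[0])
            apd.append(p[1])
    return np.asarray(di, float), np.asarray(apd, float)


def two_stage_group_fit(
    hearts_points: dict[str, list], seed: int = 0
) -> tuple[RestitutionFit, dict[str, RestitutionFit]]:
    """Group-then-per-heart restitution fitting.

    ``hearts_points`` maps heart id → restitution points. Stage 1 pools every
    point for one (APD_ss, b, τ); stage 2 refits APD_ss per heart with (b, τ)
    frozen at the group values.
    """
    pooled = [p for pts in hearts_points.values() for p in pts]
    group = fit_monoexponential(pooled, seed=seed)
    group.scope = "group"
    per_heart = {}
    for heart, pts in hearts_points.items():
        fit = fit_monoexponential(pts, fixed_b_tau=(group.b, group.tau))
        fit.scope = "heart"
        per_heart[heart] = fit
    return group, per_heart


def restitution_vector_angle(
    point_175: RestitutionPoint, point_150: RestitutionPoint
) -> float:
    """Angle (degrees, CCW from the +DI axis, in [0, 360)) of the vector from
    the 175 ms to the 150 ms PCL restitution point in (DI, APD) space."""
    ddi = point_150.di_ms - point_175.di_ms
    dapd = point_150.apd60_ms - point_175.apd60_ms
    if ddi == 0 and dapd == 0:
        raise ValueError("identical restitution points have no defined angle")
    return float(np.degrees(np.arctan2(dapd, ddi)) % 360.0)


def per_pixel_vector_angle_map(maps_175: PclMaps, maps_150: PclMaps) -> np.ndarray:
    """Restitution vector angle at each pixel (same convention as the global
    angle); NaN where either PCL's per-pixel mean is undefined or the two
    points coincide."""
    ddi = maps_150.di_mean - maps_175.di_mean
    dapd = maps_150.apd60_mean - maps_175.apd60_mean
    angle = np.degrees(np.arctan2(dapd, ddi)) % 360.0
    angle[~(np.isfinite(ddi) & np.isfinite(dapd))] = np.nan
    angle[(ddi == 0) & (dapd == 0)] = np.nan
    return angle
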