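"""Synthetic optical-mapping movies with known electrophysiological truth.

The generator emulates a dynamically paced epicardial recording: every pixel
carries a train of optical action potentials whose beat-to-beat APD_60 follows
the monoexponential restitution map of the preceding diastolic interval,

    APD_60(n) = APD_ss * (1 - b * exp(-DI(n-1) / tau)),

activation times are offset across the grid by a kinematic wavefront (planar
or focal at a controlled speed), and camera artifacts (Gaussian noise, linear
baseline drift, exponential photobleaching, sensor saturation, dead pixels)
are layered on last. Ground truth — per-beat activation time and APD_60,
per-pixel steady-state APD and wave speed, capture flags — is recorded before
any artifact is applied, so every downstream stage of the analysis can be
validated against it.

Units: time in ms, space in µm (pixel pitch) with speeds in cm/s
(1 cm/s = 10 µm/ms), fluorescence in arbitrary camera counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MovieStack

__all__ = [
    "DEFAULT_PCLS",
    "ProtocolSpec",
    "APModel",
    "WavePattern",
    "NoiseModel",
    "GroundTruth",
    "build_protocol",
    "ap_waveform",
    "simulate_movie",
    "export_ground_truth",
    "read_ground_truth",
    "steady_state_apd",
]

#: Dynamic pacing staircase: consecutive pacing cycle lengths (ms), 30 pulses
#: each, stepping down from 250 ms to 60 ms.
DEFAULT_PCLS = (250.0, 200.0, 175.0, 150.0, 125.0, 97.0, 80.0, 70.0, 60.0)

_LN_2P5 = math.log(2.5)  # exp decay from peak crosses 40 % after tau * ln 2.5


@dataclass(frozen=True)
class ProtocolSpec:
    """A dynamic pacing protocol: an ordered PCL staircase with fixed pulse
    count per step, plus the acquisition geometry it will be recorded with."""

    pcl_list: tuple[float, ...]
    pulses_per_pcl: int
    frame_rate: float  # Hz
    pixel_pitch: float = 118.0  # µm

    @property
    def n_stimuli(self) -> int:
        return len(self.pcl_list) * self.pulses_per_pcl

    @property
    def stimulus_times(self) -> np.ndarray:
        """Onset time of every pulse (ms); the first pulse is at t = 0 and the
        interval following each pulse equals its block's PCL."""
        intervals = np.repeat(self.pcl_list, self.pulses_per_pcl)
        t = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
        return t

    @property
    def pcl_of_pulse(self) -> np.ndarray:
        """PCL block membership for every pulse."""
        return np.repeat(self.pcl_list, self.pulses_per_pcl)

    @property
    def total_duration_ms(self) -> float:
        return float(sum(p * self.pulses_per_pcl for p in self.pcl_list))

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate


def build_protocol(
    pcl_list=DEFAULT_PCLS,
    pulses_per_pcl: int = 30,
    frame_rate: float = 490.2,
    pixel_pitch: float = 118.0,
) -> ProtocolSpec:
    """Construct a validated pacing protocol.

    Defaults reproduce the dynamic pacing staircase used throughout the
    analysis: 30 pulses at each of 250, 200, 175, 150, 125, 97, 80, 70 and
    60 ms PCL, recorded at 490.2 frames/s with 118 µm pixels.
    """
    pcl_list = tuple(float(p) for p in pcl_list)
    if not pcl_list:
        raise ValueError("pcl_list must be non-empty")
    if any(p <= 0 for p in pcl_list):
        raise ValueError("every PCL must be positive (ms)")
    if any(b <= a for a, b in zip(pcl_list[1:], pcl_list[:-1])):
        raise ValueError("pcl_list must be strictly decreasing")
    if pulses_per_pcl < 1:
        raise ValueError("pulses_per_pcl must be >= 1")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return ProtocolSpec(pcl_list, int(pulses_per_pcl), float(frame_rate), float(pixel_pitch))


@dataclass
class APModel:
    """Parametric optical-AP shape with analytic APD_60 control.

    The upstroke is a linear ramp of ``upstroke_duration`` ms (activation, the
    50 %-amplitude point, sits at its midpoint). Repolarization decays
    exponentially from the peak with the time constant solved per beat so that
    the 40 %-amplitude crossing lands exactly ``target_apd60`` after
    activation; past that crossing a linear terminal phase returns the signal
    to baseline before the next upstroke.

    ``apd_ss_true`` may be a scalar or an (H, W) field for regional
    heterogeneity. ``min_di`` is the shortest diastolic interval that still
    captures: stimuli arriving earlier are skipped (capture failure).
    """

    baseline: float = 2000.0  # counts
    amplitude: float = 500.0  # counts
    upstroke_duration: float = 2.0  # ms
    plateau_duration: float = 3.0  # ms near-peak shoulder before the decay
    apd_ss_true: float | np.ndarray = 58.0  # ms
    b_true: float = 0.6
    tau_true: float = 40.0  # ms
    min_di: float = 12.0  # ms
    repol_terminal_fraction: float = 0.8  # linear tail length / (APD - d/2)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.upstroke_duration <= 0:
            raise ValueError("upstroke_duration must be positive")
        if self.tau_true <= 0:
            raise ValueError("tau_true must be positive")
        if not 0 <= self.b_true < 1:
            raise ValueError("b_true must be in [0, 1)")

    def apd_ss_field(self, grid: tuple[int, int]) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.apd_ss_true, float), grid).copy()


@dataclass
class WavePattern:
    """Kinematic activation geometry: a planar front with a direction, or a
    focal source spreading radially from an origin, at constant speed.

    ``block_mask`` marks a region of 2:1 (or ``block_ratio``:1) conduction
    block; ``block_pcls`` restricts the block to specific PCL steps (None
    blocks at every PCL)."""

    mode: str = "planar"  # "planar" | "focal"
    direction: tuple[float, float] = (1.0, 0.0)  # (x, y) = (col, row)
    origin: tuple[float, float] = (0.0, 0.0)  # (row, col), focal mode
    speed: float = 50.0  # cm/s
    block_mask: np.ndarray | None = None
    block_ratio: int = 2
    block_pcls: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.mode not in ("planar", "focal"):
            raise ValueError("mode must be 'planar' or 'focal'")
        n = math.hypot(*self.direction)
        if n == 0:
            raise ValueError("direction must be non-zero")
        self.direction = (self.direction[0] / n, self.direction[1] / n)

    def at_offsets(self, grid: tuple[int, int], pixel_pitch: float) -> np.ndarray:
        """Activation delay of each pixel relative to the earliest pixel (ms)."""
        h, w = grid
        rows, cols = np.mgrid[0:h, 0:w]
        speed_um_ms = self.speed * 10.0  # 1 cm/s = 10 µm/ms
        if self.mode == "planar":
            dx, dy = self.direction
            proj = (cols * dx + rows * dy) * pixel_pitch
            proj -= proj.min()
            return proj / speed_um_ms
        r0, c0 = self.origin
        dist = np.hypot(rows - r0, cols - c0) * pixel_pitch
        return dist / speed_um_ms

    def blocked_pixels(self, grid: tuple[int, int]) -> np.ndarray:
        if self.block_mask is None:
            return np.zeros(grid, dtype=bool)
        mask = np.asarray(self.block_mask, dtype=bool)
        if mask.shape != grid:
            raise ValueError("block_mask shape must match the grid")
        return mask

    def blocks_at(self, pcl: float) -> bool:
        return self.block_pcls is None or any(
            math.isclose(pcl, p) for p in self.block_pcls
        )


@dataclass
class NoiseModel:
    """Camera/photophysics artifact stack; all effects are optional (zero
    disables). With a fixed ``seed`` the output is bit-reproducible."""

    gaussian_sd: float = 0.0  # counts
    drift_slope: float = 0.0  # counts per second
    bleach_tau: float = 0.0  # seconds; 0 disables photobleaching
    saturation_level: float = 16383.0  # counts (14-bit sensor)
    dead_pixel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gaussian_sd", "drift_slope", "bleach_tau", "dead_pixel_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dead_pixel_fraction <= 1:
            raise ValueError("dead_pixel_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Pre-noise truth for every pixel and stimulus.

    Per stimulus k and pixel: ``captured[k]`` (did the stimulus elicit an AP),
    ``at_ms[k]`` activation time, ``apd60_ms[k]`` the APD_60, and ``di_ms[k]``
    the diastolic interval *following* beat k (NaN when beat k or the next
    captured beat is missing). Per pixel: true steady-state APD and wave speed.
    """

    protocol: ProtocolSpec
    captured: np.ndarray  # (n_stim, H, W) bool
    at_ms: np.ndarray  # (n_stim, H, W)
    apd60_ms: np.ndarray
    di_ms: np.ndarray
    apd_ss_ms: np.ndarray  # (H, W)
    speed_cm_s: np.ndarray  # (H, W)

    @property
    def grid(self) -> tuple[int, int]:
        return self.captured.shape[1:]


def _shape_params(ap_model: APModel, target_apd60: float, interval: float | None):
    """Per-beat waveform geometry: (peak-shoulder end, decay constant,
    40 %-crossing time, terminal-phase length), all from upstroke onset."""
    d = ap_model.upstroke_duration
    if target_apd60 <= d:
        raise ValueError("target_apd60 must exceed the upstroke duration")
    t40 = d / 2.0 + target_apd60  # 40 % crossing, from upstroke onset
    plateau = min(ap_model.plateau_duration, 0.4 * (target_apd60 - d / 2.0))
    t_peak_end = d + plateau
    tau_r = (target_apd60 - d / 2.0 - plateau) / _LN_2P5
    t_lin = ap_model.repol_terminal_fraction * (target_apd60 - d / 2.0)
    if interval is not None:
        t_lin = min(t_lin, interval - t40 - 1.0)
        if t_lin <= 0:
            raise ValueError("interval too short for the requested APD_60")
    return t_peak_end, tau_r, t40, t_lin


def _eval_shape(tr, amplitude, d, t_peak_end, tau_r, t40, t_lin):
    """Waveform above baseline at times ``tr`` after upstroke onset."""
    out = np.zeros_like(tr)
    m = (tr >= 0) & (tr < d)
    out[m] = amplitude * tr[m] / d
    m = (tr >= d) & (tr < t_peak_end)
    out[m] = amplitude
    m = (tr >= t_peak_end) & (tr < t40)
    out[m] = amplitude * np.exp(-(tr[m] - t_peak_end) / tau_r)
    m = (tr >= t40) & (tr < t40 + t_lin)
    out[m] = 0.4 * amplitude * (1.0 - (tr[m] - t40) / t_lin)
    return out


def ap_waveform(
    ap_model: APModel,
    target_apd60: float,
    t: float | np.ndarray,
    interval: float | None = None,
) -> np.ndarray:
    """Evaluate one optical AP at time ``t`` (ms) after its upstroke onset.

    The shape is a linear upstroke (the 50 %-amplitude point sits at d/2,
    d = upstroke duration), a brief near-peak shoulder, an exponential decay
    whose time constant is solved per beat so the 40 %-amplitude
    repolarization crossing lands at d/2 + ``target_apd60`` exactly, and a
    linear terminal phase back to baseline. ``interval`` (time to the next
    upstroke onset) truncates the terminal phase so the trace is at baseline
    before the next beat; omit it for an isolated AP.
    """
    t_peak_end, tau_r, t40, t_lin = _shape_params(ap_model, target_apd60, interval)
    t = np.asarray(t, dtype=float)
    out = _eval_shape(
        t, ap_model.amplitude, ap_model.upstroke_duration, t_peak_end, tau_r, t40, t_lin
    )
    return ap_model.baseline + out


def steady_state_apd(
    pcl: float, apd_ss: float, b: float, tau: float, tol: float = 1e-12
) -> float:
    """Fixed point of the restitution map under steady pacing at ``pcl``:
    APD = APD_ss * (1 - b * exp(-(PCL - APD)/tau)), by iteration."""
    apd = apd_ss * (1.0 - b * math.exp(-max(pcl - apd_ss, 0.0) / tau))
    for _ in range(10_000):
        nxt = apd_ss * (1.0 - b * math.exp(-(pcl - apd) / tau))
        if abs(nxt - apd) < tol:
            return nxt
        apd = nxt
    return apd


def _iterate_beats(
    protocol: ProtocolSpec,
    ap_model: APModel,
    wave: WavePattern,
    grid: tuple[int, int],
):
    """Vectorized beat-train iteration over the whole grid.

    Returns (captured, at, apd) arrays of shape (n_stim, H, W). A stimulus is
    skipped at a pixel when the 2:1 block gates it out or when its diastolic
    interval would fall below ``min_di`` (capture failure); skipped stimuli
    leave the previous AP in place so the DI keeps accumulating.
    """
    offsets = wave.at_offsets(grid, protocol.pixel_pitch)
    apd_ss = ap_model.apd_ss_field(grid)
    b, tau = ap_model.b_true, ap_model.tau_true
    stim = protocol.stimulus_times
    pcls = protocol.pcl_of_pulse
    blocked_px = wave.blocked_pixels(grid)

    n = protocol.n_stimuli
    captured = np.zeros((n,) + grid, dtype=bool)
    at = np.full((n,) + grid, np.nan)
    apd = np.full((n,) + grid, np.nan)

    last_end = None  # last fired onset + APD, per pixel
    block_counter = np.zeros(grid, dtype=np.int64)
    for k in range(n):
        onset = stim[k] + offsets
        if wave.blocks_at(pcls[k]):
            gated = blocked_px & (block_counter % wave.block_ratio != 0)
            block_counter += 1
        else:
            gated = np.zeros(grid, dtype=bool)
            block_counter[:] = 0
        if last_end is None:
            di = np.full(grid, protocol.pcl_list[0]) - apd_ss
            fire = ~gated
        else:
            di = onset - last_end
            fire = ~gated & (di >= ap_model.min_di)
        beat_apd = apd_ss * (1.0 - b * np.exp(-np.maximum(di, 0.0) / tau))
        captured[k] = fire
        at[k][fire] = onset[fire]
        apd[k][fire] = beat_apd[fire]
        if last_end is None:
            last_end = np.where(fire, onset + beat_apd, -np.inf)
        else:
            last_end = np.where(fire, onset + beat_apd, last_end)
    return captured, at, apd


def _following_di(captured, at, apd):
    """DI following each captured beat: next captured onset − onset − APD."""
    n = captured.shape[0]
    di = np.full_like(at, np.nan)
    # next captured onset, scanned backwards
    next_onset = np.full(at.shape[1:], np.nan)
    for k in range(n - 1, -1, -1):
        valid = captured[k] & np.isfinite(next_onset)
        di[k][valid] = next_onset[valid] - at[k][valid] - apd[k][valid]
        next_onset = np.where(captured[k], at[k], next_onset)
    return di


def simulate_movie(
    protocol: ProtocolSpec,
    ap_model: APModel | None = None,
    wave: WavePattern | None = None,
    noise: NoiseModel | None = None,
    grid: tuple[int, int] = (64, 64),
) -> tuple[MovieStack, GroundTruth]:
    """Render a fluorescence movie for the given protocol, AP model, wave
    geometry and artifact stack, together with its ground truth.

    The default 64×64 grid keeps desk-scale runs fast; pass ``grid=(128, 128)``
    for full acquisition geometry.
    """
    ap_model = ap_model if ap_model is not None else APModel()
    wave = wave if wave is not None else WavePattern()
    h, w = grid

    captured, at, apd = _iterate_beats(protocol, ap_model, wave, grid)
    di = _following_di(captured, at, apd)

    n_frames = int(math.ceil(protocol.total_duration_ms / protocol.dt_ms))
    times = np.arange(n_frames) * protocol.dt_ms
    frames = np.zeros((n_frames, h, w), dtype=np.float64)

    total = protocol.total_duration_ms
    d = ap_model.upstroke_duration
    amp = ap_model.amplitude
    rho = ap_model.repol_terminal_fraction
    dt = protocol.dt_ms
    for r in range(h):
        for c in range(w):
            idx = np.flatnonzero(captured[:, r, c])
            onsets = at[idx, r, c]
            apds = apd[idx, r, c]
            nxt = np.append(onsets[1:], total)
            for onset, beat_apd, t_next in zip(onsets, apds, nxt):
                gap = t_next - onset
                t_peak_end, tau_r, t40, t_lin = _shape_params(ap_model, beat_apd, None)
                t_lin = max(min(t_lin, gap - t40 - 1.0), 1e-6)
                i0 = max(int(math.ceil(onset / dt)), 0)
                i1 = min(int(math.ceil((onset + min(gap, t40 + t_lin)) / dt)), n_frames)
                if i1 <= i0:
                    continue
                tr = times[i0:i1] - onset
                frames[i0:i1, r, c] += _eval_shape(
                    tr, amp, d, t_peak_end, tau_r, t40, t_lin
                )

    frames += ap_model.baseline
    meta = {
        "synthetic": True,
        "seed": noise.seed if noise is not None else -1,
        "saturation_level": noise.saturation_level if noise is not None else float("inf"),
    }
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        streams = rng.spawn(3)
        if noise.dead_pixel_fraction > 0:
            n_dead = int(round(noise.dead_pixel_fraction * h * w))
            flat = streams[0].choice(h * w, size=n_dead, replace=False)
            rr, cc = np.unravel_index(flat, (h, w))
            frames[:, rr, cc] = ap_model.baseline
            meta["dead_pixels"] = ";".join(f"{a},{b}" for a, b in zip(rr, cc))
        if noise.bleach_tau > 0:
            frames *= np.exp(-times / (1000.0 * noise.bleach_tau))[:, None, None]
        if noise.drift_slope != 0:
            frames += (noise.drift_slope * times / 1000.0)[:, None, None]
        if noise.gaussian_sd > 0:
            frames += streams[1].normal(0.0, noise.gaussian_sd, size=frames.shape)
        np.clip(frames, 0.0, noise.saturation_level, out=frames)

    movie = MovieStack(frames, protocol.frame_rate, protocol.pixel_pitch, meta)
    gt = GroundTruth(
        protocol=protocol,
        captured=captured,
        at_ms=at,
        apd60_ms=apd,
        di_ms=di,
        apd_ss_ms=ap_model.apd_ss_field(grid),
        speed_cm_s=np.full(grid, wave.speed, dtype=float),
    )
    return movie, gt


def export_ground_truth(gt: GroundTruth, out_dir) -> tuple[Path, Path]:
    """Write ground truth as two CSV tables (per-pixel-per-beat, per-pixel);
    the tables round-trip losslessly through :func:`pandas.read_csv`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n, h, w = gt.at_ms.shape
    pulse, rows, cols = np.meshgrid(
        np.arange(1, n + 1), np.arange(h), np.arange(w), indexing="ij"
    )
    beats = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "pulse": pulse.ravel(),
            "pcl_ms": np.repeat(gt.protocol.pcl_of_pulse, h * w),
            "captured": gt.captured.ravel(),
            "at_ms": gt.at_ms.ravel(),
            "apd60_ms": gt.apd60_ms.ravel(),
            "di_ms": gt.di_ms.ravel(),
        }
    )
    rr, cc = np.mgrid[0:h, 0:w]
    pixels = pd.DataFrame(
        {
            "row": rr.ravel(),
            "col": cc.ravel(),
            "apd_ss_ms": gt.apd_ss_ms.ravel(),
            "speed_cm_s": gt.speed_cm_s.ravel(),
        }
    )
    beat_path = out_dir / "ground_truth_beats.csv"
    pixel_path = out_dir / "ground_truth_pixels.csv"
    beats.to_csv(beat_path, index=False, float_format="%.17g")
    pixels.to_csv(pixel_path, index=False, float_format="%.17g")
    return beat_path, pixel_path


def read_ground_truth(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the tables written by :func:`export_ground_truth` back with
    correctly rounded float parsing, so the round trip is bit-exact."""
    out_dir = Path(out_dir)
    kw = dict(float_precision="round_trip")
    return (
        pd.read_csv(out_dir / "ground_truth_beats.csv", **kw),
        pd.read_csv(out_dir / "ground_truth_pixels.csv", **kw),
    )
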