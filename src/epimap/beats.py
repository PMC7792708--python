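"""Per-beat, per-pixel optical-AP measurement.

For each pacing cycle length the last five beats are analyzed. At every
included pixel and beat window:

* the upstroke base is the maximal second-derivative sample before the
  in-window peak ("maximal inflection point at the base of the upstroke"),
* upstroke amplitude runs from that base to the peak,
* activation time (AT) is the linearly interpolated 50 %-amplitude crossing
  on the rising limb,
* APD_60 is the time from AT to the first interpolated downward crossing of
  40 % amplitude after the peak (i.e. 60 % repolarization),
* the diastolic interval (DI) following a beat is the inter-AT interval minus
  that beat's APD_60 — by this definition the DI includes the final 40 % of
  repolarization.

ATs more than 2.5 sample standard deviations from a beat's grid-wide mean are
discarded in a single pass and excluded from all downstream analysis. Per-pixel
means use the last four beats for APD_60 (and CV), and the DIs *preceding*
those four beats (i.e. the DIs following beats 26–29 at full scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .io import MovieStack
from .preprocess import PixelMask
from .synth import ProtocolSpec

__all__ = [
    "Invalid",
    "BeatWindow",
    "PclMaps",
    "segment_beats",
    "detect_upstroke",
    "measure_apd60",
    "compute_di",
    "remove_at_outliers",
    "measure_pcl",
    "per_pixel_means",
    "infer_capture",
    "conduction_loss",
    "beat_table",
    "N_ANALYZED_BEATS",
    "N_AVERAGED_BEATS",
]

#: Beats analyzed per PCL (the last five) and beats entering per-pixel means
#: (the last four; their preceding DIs come from the first four of the five).
N_ANALYZED_BEATS = 5
N_AVERAGED_BEATS = 4


class Invalid(IntEnum):
    OK = 0
    NO_ACTIVATION = 1
    NO_REPOLARIZATION = 2
    AT_OUTLIER = 3
    EXCLUDED_PIXEL = 4
    NO_NEXT_AT = 5


@dataclass(frozen=True)
class BeatWindow:
    """One paced beat: frame span [start, end) within a PCL block."""

    pcl: float
    beat_index: int  # 1-based within the PCL block
    start_frame: int
    end_frame: int
    start_ms: float
    end_ms: float
    analyze: bool  # one of the last five beats of its block
    complete: bool = True


def segment_beats(protocol: ProtocolSpec, n_frames: int) -> list[BeatWindow]:
    """One window per stimulus, spanning stimulus to next stimulus; the last
    five windows of every PCL block are flagged for analysis."""
    dt = protocol.dt_ms
    stim = protocol.stimulus_times
    pcls = protocol.pcl_of_pulse
    bounds = np.append(stim, protocol.total_duration_ms)
    windows: list[BeatWindow] = []
    per_block = protocol.pulses_per_pcl
    for k, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
        idx_in_block = k % per_block + 1
        analyze = idx_in_block > per_block - N_ANALYZED_BEATS
        f0 = int(np.ceil(t0 / dt - 1e-9))
        f1 = int(np.ceil(t1 / dt - 1e-9))
        windows.append(
            BeatWindow(
                pcl=float(pcls[k]),
                beat_index=idx_in_block,
                start_frame=f0,
                end_frame=min(f1, n_frames),
                start_ms=t0,
                end_ms=t1,
                analyze=analyze,
                complete=f1 <= n_frames,
            )
        )
    return windows


def _subsample_base_value(x: np.ndarray, d2: np.ndarray, base: int) -> float:
    """Signal value at the sub-sample inflection location.

    The discrete second-derivative argmax localizes the upstroke base only to
    the nearest frame; because the signal already rises steeply there, taking
    the sample value directly makes base (and hence amplitude and the 50 %/40 %
    levels) jitter with the sampling phase by several normalized units. A
    quadratic vertex fit around the second-derivative maximum recovers the
    sub-sample location, and the base value is read off the trace by linear
    interpolation there.
    """
    a = base - 1  # index of the d2 maximum within d2
    if a - 1 < 0 or a + 1 >= d2.size:
        return float(x[base])
    y0, y1, y2 = d2[a - 1], d2[a], d2[a + 1]
    den = y0 - 2.0 * y1 + y2
    if den == 0:
        return float(x[base])
    off = float(np.clip(0.5 * (y0 - y2) / den, -1.0, 1.0))
    pos = base + off
    i = int(np.floor(pos))
    i = min(max(i, 0), x.size - 2)
    f = pos - i
    return float(x[i] * (1.0 - f) + x[i + 1] * f)


def detect_upstroke(trace: np.ndarray, dt_ms: float, t0_ms: float = 0.0):
    """Locate one AP upstroke in a beat-window trace.

    Returns ``(at_ms, amplitude, base_value, peak_index, status)``. The base
    is the maximal discrete second-derivative sample strictly before the
    in-window peak; AT interpolates the 50 %-amplitude crossing on the rising
    limb. Flat or peak-first windows carry ``Invalid.NO_ACTIVATION``.
    """
    x = np.asarray(trace, float)
    if x.size < 4:
        return np.nan, np.nan, np.nan, -1, Invalid.NO_ACTIVATION
    peak = int(np.argmax(x))  # earliest maximal sample
    if peak < 2:
        return np.nan, np.nan, np.nan, -1, Invalid.NO_ACTIVATION
    d2 = x[2 : peak + 1] - 2.0 * x[1:peak] + x[: peak - 1]  # f'' at 1..peak-1
    base = 1 + int(np.argmax(d2))
    base_val = _subsample_base_value(x, d2, base)
    amp = x[peak] - base_val
    if amp <= 0 or not np.isfinite(amp):
        return np.nan, np.nan, np.nan, -1, Invalid.NO_ACTIVATION
    level = base_val + 0.5 * amp
    seg = x[base : peak + 1]
    above = np.flatnonzero(seg >= level)
    j = above[0]
    if j == 0:
        frac = 0.0
        at = (base + j) * dt_ms
    else:
        lo, hi = seg[j - 1], seg[j]
        frac = (level - lo) / (hi - lo)
        at = (base + j - 1 + frac) * dt_ms
    return t0_ms + at, amp, base_val, peak, Invalid.OK


def measure_apd60(
    trace: np.ndarray,
    dt_ms: float,
    at_ms: float,
    amplitude: float,
    base_value: float,
    peak_index: int,
    t0_ms: float = 0.0,
):
    """Time from AT to 60 % repolarization (the first interpolated downward
    crossing of base + 0.4·amplitude after the peak), or
    ``Invalid.NO_REPOLARIZATION`` if the trace never crosses in-window."""
    x = np.asarray(trace, float)
    level = base_value + 0.4 * amplitude
    after = x[peak_index:]
    below = np.flatnonzero(after <= level)
    if below.size == 0 or below[0] == 0:
        return np.nan, Invalid.NO_REPOLARIZATION
    j = below[0]
    lo, hi = after[j - 1], after[j]
    frac = (lo - level) / (lo - hi)
    crossing = t0_ms + (peak_index + j - 1 + frac) * dt_ms
    apd = crossing - at_ms
    if apd <= 0:
        return np.nan, Invalid.NO_REPOLARIZATION
    return apd, Invalid.OK


def compute_di(at_n: float, at_next: float, apd60_n: float) -> float:
    """DI following beat n: (next AT − AT) − APD_60. Raises if ATs are not
    increasing."""
    if not at_next > at_n:
        raise ValueError("at_next must exceed at_n")
    return (at_next - at_n) - apd60_n


def remove_at_outliers(at_values: np.ndarray, z_threshold: float = 2.5) -> np.ndarray:
    """Single-pass grid-wide AT outlier rule for one paced beat.

    Returns a boolean array marking ATs with |z| strictly above the threshold
    (sample SD); needs at least 3 finite ATs, and removes nothing when the SD
    is zero. Boundary values (|z| exactly 2.5) are retained.
    """
    at = np.asarray(at_values, float)
    finite = np.isfinite(at)
    out = np.zeros(at.shape, bool)
    if finite.sum() < 3:
        return out
    vals = at[finite]
    sd = vals.std(ddof=1)
    if sd == 0:
        return out
    z = np.abs(at - vals.mean()) / sd
    out[finite] = z[finite] > z_threshold
    return out


@dataclass
class PclMaps:
    """Per-pixel measurement maps for one PCL."""

    pcl: float
    apd60_mean: np.ndarray  # (H, W) ms, NaN where undefined
    di_mean: np.ndarray  # (H, W) ms
    beats_used: np.ndarray  # (H, W) uint8, 0..4 valid APs among last four
    cv_mean: np.ndarray | None = None  # (H, W) cm/s, filled by the CV stage
    captured: bool = True
    # raw per-beat arrays for the analyzed (last five) windows
    at_ms: np.ndarray | None = None  # (5, H, W)
    amplitude: np.ndarray | None = None
    apd60_ms: np.ndarray | None = None
    di_ms: np.ndarray | None = None  # DI following each of the five beats
    status: np.ndarray | None = None  # (5, H, W) Invalid codes


def measure_pcl(
    movie: MovieStack,
    mask: PixelMask,
    windows: list[BeatWindow],
    z_threshold: float = 2.5,
    pre_window_ms: float = 15.0,
) -> PclMaps:
    """Measure the analyzed beats of one PCL block at every included pixel,
    apply the grid-wide AT outlier rule per beat, and build per-pixel means.

    Each beat is measured on its window shifted ``pre_window_ms`` earlier
    (capped at PCL/4): the zero-phase low-pass filter spreads the upstroke
    symmetrically in time, so the upstroke base sits slightly before the
    stimulus and must be inside the searched span.
    """
    wins = [w for w in windows if w.analyze and w.complete]
    if not wins:
        raise ValueError("no complete analysis windows for this PCL")
    pcl = wins[0].pcl
    h, w = movie.grid
    nb = len(wins)
    dt = movie.dt_ms
    pad = int(round(min(pre_window_ms, 0.25 * pcl) / dt))
    at = np.full((nb, h, w), np.nan)
    amp = np.full((nb, h, w), np.nan)
    apd = np.full((nb, h, w), np.nan)
    status = np.full((nb, h, w), int(Invalid.EXCLUDED_PIXEL), np.uint8)

    rows, cols = np.nonzero(mask.included)
    frames = movie.frames
    for i, win in enumerate(wins):
        f0 = max(win.start_frame - pad, 0)
        sl = slice(f0, max(win.end_frame - pad, f0 + 4))
        t0 = f0 * dt
        for r, c in zip(rows, cols):
            tr = frames[sl, r, c]
            at_i, amp_i, base_i, peak_i, st = detect_upstroke(tr, dt, t0)
            if st is not Invalid.OK:
                status[i, r, c] = int(st)
                continue
            apd_i, st = measure_apd60(tr, dt, at_i, amp_i, base_i, peak_i, t0)
            if st is not Invalid.OK:
                status[i, r, c] = int(st)
                continue
            at[i, r, c] = at_i
            amp[i, r, c] = amp_i
            apd[i, r, c] = apd_i
            status[i, r, c] = int(Invalid.OK)
        # grid-wide AT outlier rule, one pass per paced beat
        drop = remove_at_outliers(at[i], z_threshold)
        at[i][drop] = np.nan
        amp[i][drop] = np.nan
        apd[i][drop] = np.nan
        status[i][drop] = int(Invalid.AT_OUTLIER)

    # DI following beat i: time to the next *detected* AT minus APD_60; for a
    # 2:1-blocked pixel that next AT is two windows on, doubling the local
    # cycle length.
    di = np.full((nb, h, w), np.nan)
    next_at = np.full((h, w), np.nan)
    for i in range(nb - 1, -1, -1):
        ok = np.isfinite(at[i]) & np.isfinite(apd[i]) & np.isfinite(next_at)
        di[i][ok] = (next_at - at[i] - apd[i])[ok]
        next_at = np.where(np.isfinite(at[i]), at[i], next_at)

    maps = per_pixel_means(pcl, at, apd, di)
    maps.at_ms, maps.amplitude, maps.apd60_ms, maps.di_ms, maps.status = (
        at,
        amp,
        apd,
        di,
        status,
    )
    return maps


def _nan_safe_mean(stack: np.ndarray) -> np.ndarray:
    """Mean over axis 0 ignoring NaNs; NaN (no warning) where nothing valid."""
    ok = np.isfinite(stack)
    cnt = ok.sum(axis=0)
    total = np.where(ok, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / cnt
    out[cnt == 0] = np.nan
    return out


def per_pixel_means(
    pcl: float, at: np.ndarray, apd: np.ndarray, di: np.ndarray
) -> PclMaps:
    """Average the last four beats' APD_60 and the four preceding DIs at each
    pixel; ``beats_used`` counts valid APs among the last four."""
    nb = at.shape[0]
    last4 = slice(nb - N_AVERAGED_BEATS, nb)
    di4 = slice(nb - N_AVERAGED_BEATS - 1, nb - 1)
    apd_mean = _nan_safe_mean(apd[last4])
    di_mean = _nan_safe_mean(di[di4])
    beats_used = np.isfinite(apd[last4]).sum(axis=0).astype(np.uint8)
    apd_mean[beats_used == 0] = np.nan
    return PclMaps(pcl=pcl, apd60_mean=apd_mean, di_mean=di_mean, beats_used=beats_used)


def infer_capture(
    movie: MovieStack,
    mask: PixelMask,
    windows: list[BeatWindow],
    tolerance: float = 0.10,
    min_detected: float = 0.90,
) -> bool:
    """Decide whether a PCL block held 1:1 capture.

    The ROI-mean trace over the whole block is scanned for rising 50 %-level
    crossings; the block is captured iff the median inter-activation interval
    is within ``tolerance`` of the PCL and at least ``min_detected`` of the
    expected activations are found (a 2:1 block halves the count and doubles
    the median interval).
    """
    block = [w for w in windows if w.complete]
    if not block:
        return False
    pcl = block[0].pcl
    f0, f1 = block[0].start_frame, block[-1].end_frame
    if not mask.included.any():
        return False
    tr = movie.frames[f0:f1][:, mask.included].mean(axis=1)
    lvl = tr.min() + 0.5 * (tr.max() - tr.min())
    above = tr >= lvl
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if onsets.size < max(2, int(np.ceil(min_detected * len(block)))):
        return False
    intervals = np.diff(onsets) * movie.dt_ms
    med = float(np.median(intervals))
    return abs(med - pcl) <= tolerance * pcl and onsets.size >= min_detected * len(block)


def conduction_loss(maps_slow: PclMaps, maps_fast: PclMaps) -> float:
    """Percent change, slow → fast PCL, in the number of pixels whose
    per-pixel mean used all four APs. Negative values mean conduction loss."""
    n_slow = int((maps_slow.beats_used == N_AVERAGED_BEATS).sum())
    n_fast = int((maps_fast.beats_used == N_AVERAGED_BEATS).sum())
    if n_slow == 0:
        raise ValueError("no fully detected pixels at the slow PCL")
    return 100.0 * (n_fast - n_slow) / n_slow


def beat_table(maps: PclMaps, mask: PixelMask) -> pd.DataFrame:
    """Long-format per-beat table (pixel, beat, AT, amplitude, APD_60, DI,
    validity) for one PCL."""
    nb, h, w = maps.at_ms.shape
    beat, rows, cols = np.meshgrid(
        np.arange(1, nb + 1), np.arange(h), np.arange(w), indexing="ij"
    )
    keep = np.broadcast_to(mask.included, (nb, h, w))
    return pd.DataFrame(
        {
            "pcl_ms": maps.pcl,
            "row": rows[keep],
            "col": cols[keep],
            "beat": beat[keep],
            "at_ms": maps.at_ms[keep],
            "amplitude": maps.amplitude[keep],
            "apd60_ms": maps.apd60_ms[keep],
            "di_ms": maps.di_ms[keep],
            "status": maps.status[keep],
        }
    )
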