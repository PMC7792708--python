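"""Cohort statistics: Brown–Forsythe equal-variance test and planned
Fisher's-LSD contrasts with a single pooled variance.

Per-heart scalar outcomes (APD_60 at a PCL, fitted APD_ss, vector angle, CV,
conduction loss, segment percentages, ...) are compared across groups with
planned contrasts, uncorrected for multiplicity: the pooled mean square error
over ALL groups, MSE = Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1), gives each contrast
t = Δmean / √(MSE·(1/n₁+1/n₂)) on df = Σ(nᵢ−1), two-sided. The
Brown–Forsythe test (one-way ANOVA on absolute deviations from group medians)
guards the equal-variance assumption; when it rejects, contrasts on that
outcome are reported as not applicable and the Brown–Forsythe p stands alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "brown_forsythe",
    "fisher_lsd_contrasts",
    "summarize_outcomes",
    "histogram_fixed_centers",
    "ContrastResult",
]


@dataclass(frozen=True)
class ContrastResult:
    group_a: str
    group_b: str
    t: float
    df: int
    p: float


def brown_forsythe(groups) -> tuple[float, float]:
    """Brown–Forsythe equal-variance test over ≥2 groups (each n ≥ 2):
    one-way ANOVA F on |x − group median|, p from the F distribution."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("degenerate: zero within-group deviation everywhere")
    f, p = stats.levene(*groups, center="median")
    return float(f), float(p)


def _pooled_mse(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    num = sum((g.size - 1) * g.var(ddof=1) for g in groups.values())
    df = sum(g.size - 1 for g in groups.values())
    return num / df, df


def fisher_lsd_contrasts(
    groups: dict[str, "np.ndarray | list"],
    contrasts: list[tuple[str, str]],
) -> list[ContrastResult]:
    """Planned pairwise contrasts with the variance pooled over all groups,
    no multiplicity correction. Summary-statistics input is supported through
    :func:`fisher_lsd_from_summaries`."""
    g = {k: np.asarray(v, float) for k, v in groups.items()}
    if any(v.size < 2 for v in g.values()):
        raise ValueError("every group needs n >= 2")
    summaries = {k: (v.mean(), v.std(ddof=1), v.size) for k, v in g.items()}
    return fisher_lsd_from_summaries(summaries, contrasts)


def fisher_lsd_from_summaries(
    summaries: dict[str, tuple[float, float, int]],
    contrasts: list[tuple[str, str]],
) -> list[ContrastResult]:
    """Fisher's-LSD planned contrasts from (mean, SD, n) triples per group —
    the form printed in a summary table. SDs use the n−1 convention."""
    if any(n < 2 for _, _, n in summaries.values()):
        raise ValueError("every group needs n >= 2")
    sse = sum((n - 1) * sd**2 for _, sd, n in summaries.values())
    df = sum(n - 1 for _, _, n in summaries.values())
    mse = sse / df
    if mse <= 0:
        raise ValueError("pooled variance is zero; contrasts undefined")
    out = []
    for a, b in contrasts:
        if a not in summaries or b not in summaries:
            raise KeyError(f"unknown group in contrast ({a}, {b})")
        ma, _, na = summaries[a]
        mb, _, nb = summaries[b]
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se
        p = 2.0 * stats.t.sf(abs(t), df)
        out.append(ContrastResult(a, b, float(t), int(df), float(p)))
    return out


def summarize_outcomes(
    per_heart: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summary-table rows from a long per-heart table with columns
    ``outcome``, ``group``, ``value``.

    Each outcome row carries mean (SD) and n per group, the Brown–Forsythe p,
    and the planned-contrast p-values — reported as NaN (not applicable) when
    the equal-variance test rejects at ``alpha``, in which case the
    Brown–Forsythe p itself is the reported comparison.
    """
    rows = []
    for outcome, sub in per_heart.groupby("outcome", sort=False):
        groups = {g: s["value"].to_numpy(float) for g, s in sub.groupby("group", sort=False)}
        row: dict = {"outcome": outcome}
        for gname, vals in groups.items():
            row[f"{gname}_mean"] = vals.mean()
            row[f"{gname}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"{gname}_n"] = vals.size
        bf_ok = all(v.size >= 2 for v in groups.values()) and len(groups) >= 2
        try:
            _, bf_p = brown_forsythe(list(groups.values())) if bf_ok else (np.nan, np.nan)
        except ValueError:
            bf_p = np.nan
        row["brown_forsythe_p"] = bf_p
        for a, b in contrasts or []:
            key = f"p_{a}_vs_{b}"
            if np.isfinite(bf_p) and bf_p < alpha:
                row[key] = np.nan  # unequal variances: contrast not applicable
            else:
                try:
                    (res,) = fisher_lsd_contrasts(groups, [(a, b)])
                    row[key] = res.p
                except (ValueError, KeyError):
                    row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def histogram_fixed_centers(values, centers) -> np.ndarray:
    """Histogram counts over bins with fixed, uniformly spaced centers; edges
    sit at midpoints between centers and out-of-span values accumulate in the
    end bins."""
    centers = np.asarray(centers, float)
    if centers.size < 2:
        raise ValueError("need at least 2 centers")
    d = np.diff(centers)
    if np.any(d <= 0) or not np.allclose(d, d[0]):
        raise ValueError("centers must be strictly increasing and uniform")
    mids = (centers[:-1] + centers[1:]) / 2.0
    edges = np.concatenate([[-np.inf], mids, [np.inf]])
    counts, _ = np.histogram(np.asarray(values, float), bins=edges)
    return counts
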