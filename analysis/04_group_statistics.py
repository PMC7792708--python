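#!/usr/bin/env python
"""Cohort summary table with planned contrasts.

Assembles the per-heart outcomes (APD_60 at 250/150 ms, fitted APD_ss,
restitution vector angle, CV at 250 ms, conduction loss, dispersion segment
percentages) into one row per outcome with group mean (SD) n, the
Brown–Forsythe equal-variance p, and Fisher's-LSD planned contrasts
(Sham vs TAC, TAC vs TAC+CNO) on a single pooled variance — contrasts are
reported N/A when the equal-variance test rejects. Writes
results/group_summary.csv.
"""

from pathlib import Path

import pandas as pd

from epimap.groupstats import summarize_outcomes

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

OUTCOMES = [
    "apd60_250",
    "apd60_150",
    "apd_ss_ms",
    "vector_angle_deg",
    "cv_250",
    "conduction_loss_pct",
    "segment_pct_250",
    "segment_pct_150",
]


def main() -> None:
    outcomes = pd.read_csv(RESULTS / "heart_outcomes.csv")
    fits = pd.read_csv(RESULTS / "restitution_fits.csv")
    merged = outcomes.merge(fits[["heart", "apd_ss_ms"]], on="heart")
    long = merged.melt(
        id_vars=["heart", "group"],
        value_vars=OUTCOMES,
        var_name="outcome",
        value_name="value",
    ).dropna(subset=["value"])
    table = summarize_outcomes(
        long, contrasts=[("Sham", "TAC"), ("TAC", "TAC+CNO")]
    )
    table.to_csv(RESULTS / "group_summary.csv", index=False)
    with pd.option_context("display.width", 200, "display.max_columns", 30):
        print(table.round(4).to_string(index=False))
    print(f"\nwrote {RESULTS / 'group_summary.csv'}")


if __name__ == "__main__":
    main()
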