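#!/usr/bin/env python
"""Cohort statistics on the per-subject metrics table.

Reproduces the analysis battery on the simulated cohort: normality
screen, mixed 2x2x2 repeated-measures ANOVA (condition x hemisphere
within, group between) on the HbO window means, group comparisons of
metrics (two-sample t) and outcomes (Mann-Whitney U), the 4x4 metric x
outcome Spearman grid with a Bonferroni family of 16, and the
slope-homogeneity test of the group-by-laterality interaction on
phonological short-term memory.
"""

import argparse
from pathlib import Path

import pandas as pd

from nirspeech.pipeline import (group_comparison_table,
                                metric_outcome_correlations)
from nirspeech.stats import ks_normality, mixed_anova_2x2x2, slope_homogeneity

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--family", type=int, default=16)
    ap.parse_args()

    results = ROOT / "results"
    table = pd.read_csv(results / "metrics.csv")
    inc = table[table["included"]].copy()
    print(f"{len(inc)} analysed subjects "
          f"({(inc.group == 'preterm').sum()} preterm, "
          f"{(inc.group == 'term').sum()} term)\n")

    stat, p = ks_normality(inc["sp"])
    print(f"KS normality of SP: D = {stat:.3f}, p = {p:.3f}")

    cells = inc.rename(columns={"subject_id": "subject"})[
        ["subject", "group", "FL", "FR", "RL", "RR"]]
    anova = mixed_anova_2x2x2(cells)
    anova.to_csv(results / "anova.csv", index=False)
    print("\nMixed 2x2x2 ANOVA on HbO window means:")
    print(anova.round(4).to_string(index=False))

    groups = group_comparison_table(inc)
    groups.to_csv(results / "group_comparisons.csv", index=False)
    print("\nGroup comparisons (metrics: t; outcomes: Mann-Whitney):")
    print(groups.round(4).to_string(index=False))

    corr = metric_outcome_correlations(inc, family_size=16)
    corr.to_csv(results / "metric_outcome_correlations.csv", index=False)
    print("\nMetric x outcome Spearman grid (Bonferroni family 16):")
    print(corr.round(4).to_string(index=False))
    hits = corr[corr["bonferroni_significant"]]
    for r in hits.itertuples():
        print(f"  surviving correction: {r.metric} x {r.outcome} "
              f"(r_s = {r.r_s:.2f}, p = {r.p:.2g})")

    sub = inc.dropna(subset=["li_sp", "z_phonological_stm"])
    f, p = slope_homogeneity(sub["z_phonological_stm"], sub["li_sp"],
                             sub["group"])
    print(f"\nslope homogeneity, group x LI on phonological STM: "
          f"F = {f:.2f}, p = {p:.3f}")
    with open(results / "report.txt", "w") as fh:
        fh.write(anova.round(4).to_string(index=False) + "\n\n")
        fh.write(groups.round(4).to_string(index=False) + "\n\n")
        fh.write(corr.round(4).to_string(index=False) + "\n")
    print(f"\ntables -> {results}")


if __name__ == "__main__":
    main()
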