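"""Run orchestration: simulate -> preprocess -> metrics -> statistics.

A run is fully determined by its configuration and seed; the config is
serialised into the output directory together with a machine-parseable
exclusion log, and subject bookkeeping is asserted (subjects in =
excluded + analysed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import save_config, write_schedule_csv, write_snirf
from .metrics import compute_subject_metrics
from .preprocess import PreprocessConfig, preprocess_subject
from .probe import default_layout
from .simulate import NoiseConfig, OutcomeModel, simulate_cohort
from .stats import (bonferroni_family, mann_whitney_u, mixed_anova_2x2x2,
                    pearson, spearman, two_sample_t)

logger = logging.getLogger(__name__)

OUTCOMES = ["z_comprehension", "z_sentence_production",
            "z_morphological_rules", "z_phonological_stm"]
METRICS = ["sp", "sp_l", "sp_r", "li_sp"]


@dataclass
class RunConfig:
    seed: int = 0
    n_preterm: int = 46
    n_term: int = 46
    fs: float = 10.0
    n_per_condition: int = 10
    block_dur_s: float = 15.0
    isi_range_s: tuple = (15.0, 30.0)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    response_window_s: tuple = (0.0, 25.0)
    abs_first: bool = False
    bonferroni_family_size: int = 16
    write_recordings: bool = False   # SNIRF output is bulky; opt in

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def metrics_table(subjects, cohort: pd.DataFrame, cfg: RunConfig,
                  return_results: bool = False):
    """Preprocess every subject and compute the per-subject metrics CSV
    (the analogue of the descriptive block of the cohort table)."""
    rows = []
    results = {}
    for rec in subjects:
        res = preprocess_subject(rec.recording, rec.schedule, cfg.preprocess)
        results[rec.truth.subject_id] = res
        m = compute_subject_metrics(res.epochs, included=res.inclusion.included,
                                    response_window_s=cfg.response_window_s,
                                    abs_first=cfg.abs_first,
                                    subject_id=rec.truth.subject_id)
        rows.append({
            "subject_id": m.subject_id,
            "included": bool(res.inclusion.included),
            "retained_channels": res.inclusion.retained_channels,
            "retained_trial_fraction": res.inclusion.retained_trial_fraction,
            "exclusion_reasons": "; ".join(res.inclusion.reasons),
            "sp": m.sp, "sp_l": m.sp_l, "sp_r": m.sp_r, "li_sp": m.li_sp,
            "est_sign": m.sign, "signed_sp": m.signed_sp,
            "signed_sp_l": m.signed_sp_l, "signed_sp_r": m.signed_sp_r,
        })
    mt = pd.DataFrame(rows)
    merged = cohort.merge(mt, on="subject_id")
    return (merged, results) if return_results else merged


def group_comparison_table(table: pd.DataFrame) -> pd.DataFrame:
    """Group descriptives and tests per metric/outcome (cohort-table style).

    Metrics are compared with two-sample t (both tails reported);
    outcome z-scores with the Mann-Whitney U test."""
    rows = []
    pre = table[table["group"] == "preterm"]
    term = table[table["group"] == "term"]
    for col in METRICS:
        a, b = term[col].dropna(), pre[col].dropna()
        t, p2 = two_sample_t(a, b, tails="two")
        _, p1 = two_sample_t(a, b, tails="one")
        rows.append({"variable": col, "test": "t",
                     "preterm_mean": b.mean(), "preterm_sd": b.std(ddof=1),
                     "term_mean": a.mean(), "term_sd": a.std(ddof=1),
                     "statistic": t, "p_two_sided": p2, "p_one_sided": p1,
                     "n_preterm": len(b), "n_term": len(a)})
    for col in OUTCOMES:
        a, b = term[col].dropna(), pre[col].dropna()
        res = mann_whitney_u(a, b, tails="two")
        rows.append({"variable": col, "test": "mann-whitney",
                     "preterm_mean": b.mean(), "preterm_sd": b.std(ddof=1),
                     "term_mean": a.mean(), "term_sd": a.std(ddof=1),
                     "statistic": res["z"], "p_two_sided": res["p"],
                     "p_one_sided": np.nan,
                     "n_preterm": len(b), "n_term": len(a)})
    return pd.DataFrame(rows)


def metric_outcome_correlations(table: pd.DataFrame,
                                family_size: int | None = None) -> pd.DataFrame:
    """Spearman grid of discrimination metrics x language outcomes with
    Bonferroni flags (the metric-outcome correlation table)."""
    rows = []
    for m in METRICS:
        for o in OUTCOMES:
            sub = table[[m, o]].dropna()
            try:
                rho, p = spearman(sub[m], sub[o])
            except ValueError as exc:   # too few pairs / zero variance
                logger.warning("correlation %s x %s skipped: %s", m, o, exc)
                rho, p = np.nan, np.nan
            rows.append({"metric": m, "outcome": o, "r_s": rho, "p": p,
                         "n": len(sub)})
    grid = pd.DataFrame(rows)
    return bonferroni_family(grid, family_size or len(grid))


def anova_cells_from_epochs(subjects, cfg: RunConfig,
                            results=None) -> pd.DataFrame:
    """Condition x hemisphere window means per subject, for the mixed ANOVA."""
    from .metrics import condition_mean, _hemi_positions
    rows = []
    for rec in subjects:
        res = results.get(rec.truth.subject_id) if results else \
            preprocess_subject(rec.recording, rec.schedule, cfg.preprocess)
        ep = res.epochs
        if not res.inclusion.included:
            continue
        row = {"subject": rec.truth.subject_id, "group": rec.truth.group}
        for hemi, tag in (("L", "L"), ("R", "R")):
            pos = _hemi_positions(ep, ep.layout, hemi)
            if pos.size == 0:
                row = None
                break
            means = condition_mean(ep, pos, cfg.response_window_s)
            row[f"F{tag}"] = float(means["forward"].mean()) \
                if means["forward"] is not None else np.nan
            row[f"R{tag}"] = float(means["reverse"].mean()) \
                if means["reverse"] is not None else np.nan
        if row:
            rows.append(row)
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Execute the full chain and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(out / "config.yaml", {"version": __version__,
                                      "fingerprint": cfg.fingerprint(),
                                      **cfg.to_dict()})
    subjects, cohort = simulate_cohort(
        cfg.n_preterm, cfg.n_term, outcome_model=cfg.outcome, noise=cfg.noise,
        seed=cfg.seed, raw=True, n_per_condition=cfg.n_per_condition,
        block_dur=cfg.block_dur_s, isi_range=cfg.isi_range_s, fs=cfg.fs)
    if cfg.write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in subjects:
            write_snirf(rec_dir / f"{rec.truth.subject_id}.snirf",
                        rec.recording, rec.schedule)
            write_schedule_csv(rec_dir / f"{rec.truth.subject_id}_schedule.csv",
                               rec.schedule)
    table, results = metrics_table(subjects, cohort, cfg, return_results=True)
    table.to_csv(out / "metrics.csv", index=False)

    n_in = len(table)
    excluded = table[~table["included"]]
    analysed = table[table["included"]]
    assert n_in == len(excluded) + len(analysed), "subject bookkeeping violated"
    excl_log = excluded[["subject_id", "retained_channels",
                         "retained_trial_fraction", "exclusion_reasons"]]
    excl_log.to_csv(out / "exclusion_log.csv", index=False)

    cells = anova_cells_from_epochs(subjects, cfg, results=results)
    cells = cells[cells["subject"].isin(analysed["subject_id"])]
    try:
        anova = mixed_anova_2x2x2(cells)
    except ValueError as exc:
        logger.warning("mixed ANOVA skipped: %s", exc)
        anova = pd.DataFrame(columns=["effect", "df1", "df2", "F", "p",
                                      "partial_eta_sq"])
    anova.to_csv(out / "anova.csv", index=False)
    groups = group_comparison_table(analysed)
    groups.to_csv(out / "group_comparisons.csv", index=False)
    corr = metric_outcome_correlations(analysed, cfg.bonferroni_family_size)
    corr.to_csv(out / "metric_outcome_correlations.csv", index=False)

    report = _text_report(cfg, table, anova, groups, corr)
    (out / "report.txt").write_text(report, encoding="utf-8")
    logger.info("run complete: %d subjects, %d analysed, %d excluded",
                n_in, len(analysed), len(excluded))
    return {"table": table, "anova": anova, "groups": groups, "corr": corr,
            "out_dir": out}


def _text_report(cfg, table, anova, groups, corr) -> str:
    lines = [
        f"nirspeech {__version__}  (config fingerprint {cfg.fingerprint()})",
        f"subjects: {len(table)} total, {int(table['included'].sum())} analysed,"
        f" {int((~table['included']).sum())} excluded",
        "",
        "Mixed 2x2x2 ANOVA (condition x hemisphere x group), HbO window means:",
        anova.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
        "Group comparisons (t on metrics, Mann-Whitney on z-scores;"
        " both tail conventions printed for t):",
        groups.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
        f"Metric x outcome Spearman grid (Bonferroni family ="
        f" {int(corr['family_size'].iloc[0])}):",
        corr.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
    ]
    return "\n".join(lines)
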