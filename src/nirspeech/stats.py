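"""Cohort-level statistical battery.

Normality screening, the mixed 2x2x2 repeated-measures ANOVA with
partial eta squared, post-hoc t-tests, Mann-Whitney U, Pearson and
Spearman correlation with Bonferroni families, slope-homogeneity
(group-by-covariate interaction) tests, the socioeconomic composite and
z-score classification.

The mixed ANOVA (two 2-level within-subject factors, one 2-level
between-subjects factor) is computed from subject-level contrast
variables, which for 2-level factors is algebraically identical to the
standard Type-III sums-of-squares partition: each within effect is
tested against its effect-by-subject error term with df (1, N-2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def ks_normality(sample) -> tuple:
    """One-sample KS test against a normal with estimated mean/sd
    (Lilliefors-corrected p-value).

    Returns (statistic, p).  Raises on constant samples (degenerate).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test degenerate")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# mixed 2x2x2 ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaEffect:
    name: str
    F: float
    df: tuple
    p: float
    partial_eta_sq: float


def _f_from_t(t: float, df2: int):
    f = t * t
    p = sps.f.sf(f, 1, df2)
    pes = f / (f + df2) if np.isfinite(f) else 1.0
    return f, p, pes


def _pooled_test(values: np.ndarray, groups: np.ndarray, kind: str, df2: int):
    """t statistic for a within-subject contrast variable.

    kind="main": unweighted grand mean vs 0 (Type III);
    kind="interaction": group difference of means.
    """
    g1, g2 = values[groups == 0], values[groups == 1]
    n1, n2 = len(g1), len(g2)
    ss_err = np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2)
    if ss_err == 0:
        # degenerate: no subject variability around group means
        s2 = 0.0
    else:
        s2 = ss_err / df2
    if kind == "main":
        theta = 0.5 * (g1.mean() + g2.mean())
        var = s2 * 0.25 * (1.0 / n1 + 1.0 / n2)
    else:
        theta = g1.mean() - g2.mean()
        var = s2 * (1.0 / n1 + 1.0 / n2)
    if theta == 0:
        return 0.0
    if var == 0:
        return np.inf if theta > 0 else -np.inf
    return theta / np.sqrt(var)


def mixed_anova_2x2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA: condition x hemisphere within,
    group between.

    ``cells`` needs columns subject, group and the four cell means FL,
    FR, RL, RR (forward/reverse x left/right).  Subjects with missing
    cells are dropped (logged in the returned attrs).  Returns a
    DataFrame with F, df1, df2, p and partial eta squared per effect.
    """
    req = {"subject", "group", "FL", "FR", "RL", "RR"}
    if not req.issubset(cells.columns):
        raise ValueError(f"cells table must contain {sorted(req)}")
    complete = cells.dropna(subset=["FL", "FR", "RL", "RR"])
    dropped = sorted(set(cells["subject"]) - set(complete["subject"]))
    glabels = sorted(complete["group"].unique())
    if len(glabels) != 2:
        raise ValueError("exactly two groups required")
    groups = (complete["group"] == glabels[1]).to_numpy().astype(int)
    if min((groups == 0).sum(), (groups == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 subjects")
    fl, fr = complete["FL"].to_numpy(), complete["FR"].to_numpy()
    rl, rr = complete["RL"].to_numpy(), complete["RR"].to_numpy()
    n = len(complete)
    df2 = n - 2

    m = (fl + fr + rl + rr) / 4.0                  # subject mean
    c = (fl + fr - rl - rr) / 2.0                  # condition contrast
    h = (fl - fr + rl - rr) / 2.0                  # hemisphere contrast
    x = (fl - fr) - (rl - rr)                      # cond x hemi contrast

    rows = []
    t = _pooled_test(m, groups, "interaction", df2)  # group diff of means
    f, p, pes = _f_from_t(t, df2)
    rows.append(("group", f, p, pes))
    for name, v in (("condition", c), ("hemisphere", h),
                    ("condition*hemisphere", x)):
        t = _pooled_test(v, groups, "main", df2)
        f, p, pes = _f_from_t(t, df2)
        rows.append((name, f, p, pes))
        t = _pooled_test(v, groups, "interaction", df2)
        f, p, pes = _f_from_t(t, df2)
        rows.append((f"{name}*group", f, p, pes))
    out = pd.DataFrame(rows, columns=["effect", "F", "p", "partial_eta_sq"])
    out.insert(1, "df1", 1)
    out.insert(2, "df2", df2)
    out.attrs["dropped_subjects"] = dropped
    return out


# ---------------------------------------------------------------------------
# t tests, U test, correlations
# ---------------------------------------------------------------------------

def _tailed_p(t: float, p_two: float, tails: str) -> float:
    if tails == "two":
        return p_two
    if tails == "one":
        return p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    raise ValueError("tails must be 'one' or 'two'")


def paired_t(x, y, tails: str = "two") -> tuple:
    """Paired t-test; one-sided alternative is mean(x) > mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    if np.ptp(d) == 0 and d[0] == 0:
        return 0.0, 1.0 if tails == "two" else 0.5
    res = sps.ttest_rel(x, y)
    return float(res.statistic), _tailed_p(res.statistic, float(res.pvalue), tails)


def two_sample_t(x, y, tails: str = "two") -> tuple:
    """Pooled-variance two-sample t-test; one-sided is mean(x) > mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(len(x), len(y)) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), _tailed_p(res.statistic, float(res.pvalue), tails)


def mann_whitney_u(x, y, tails: str = "two") -> dict:
    """Mann-Whitney U with tie-corrected normal approximation and exact
    enumeration for min(n) <= 8 (tie-free samples).

    Returns dict with U, z and p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 1:
        raise ValueError("each group needs at least one observation")
    alternative = "two-sided" if tails == "two" else "greater"
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (min(n1, n2) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    u = float(res.statistic)
    # tie-corrected normal approximation z (no continuity correction)
    allv = np.concatenate([x, y])
    _, counts = np.unique(allv, return_counts=True)
    nn = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = np.sum(counts ** 3 - counts) / (nn * (nn - 1)) if nn > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (nn + 1 - tie_term)
    z = 0.0 if sigma2 == 0 else (u - mu) / np.sqrt(sigma2)
    return {"U": u, "z": float(z), "p": float(res.pvalue), "method": method}


def pearson(x, y) -> tuple:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y, exact_below: int = 10) -> tuple:
    """Spearman rank correlation (average ranks for ties).

    For n < ``exact_below`` the two-sided p is computed by exhaustive
    permutation of one margin; otherwise the t approximation is used.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(sps.pearsonr(rx, ry).statistic)
    if n < exact_below:
        # permutation null: rho is monotone in sum(rx * ry_perm), so
        # enumerate dot products vectorised
        perms = np.array(list(itertools.permutations(ry)))
        dots = perms @ rx
        denom = np.sqrt(np.sum((rx - rx.mean()) ** 2) *
                        np.sum((ry - ry.mean()) ** 2))
        rhos = (dots - n * rx.mean() * ry.mean()) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(sps.spearmanr(x, y).pvalue)


def bonferroni_family(results: pd.DataFrame, family_size: int | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Flag correlations significant under Bonferroni correction.

    ``results`` needs a ``p`` column; the family defaults to the number
    of rows (all cells of the metric-by-outcome table)."""
    if family_size is None:
        family_size = len(results)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = results.copy()
    out["family_size"] = family_size
    out["bonferroni_significant"] = out["p"] < alpha / family_size
    return out


def slope_homogeneity(outcome, covariate, group) -> tuple:
    """F-test of the group-by-covariate interaction in
    outcome ~ group + covariate + group:covariate.

    Returns (F, p)."""
    df = pd.DataFrame({"y": np.asarray(outcome, float),
                       "x": np.asarray(covariate, float),
                       "g": np.asarray(group)})
    counts = df.groupby("g").size()
    if len(counts) != 2 or counts.min() < 3:
        raise ValueError("need two groups with n >= 3 each")
    full = ols("y ~ C(g) * x", data=df).fit()
    reduced = ols("y ~ C(g) + x", data=df).fit()
    if full.df_resid < 1 or not np.isfinite(full.ssr):
        raise ValueError("collinear design: interaction not estimable")
    tab = anova_lm(reduced, full)
    return float(tab["F"].iloc[1]), float(tab["Pr(>F)"].iloc[1])


# ---------------------------------------------------------------------------
# composites and classification
# ---------------------------------------------------------------------------

def ses_composite(edu_mother: float, edu_father: float, income: float) -> float:
    """Socioeconomic composite on a 1-5 scale: arithmetic mean of
    maternal education (1-5), paternal education (1-5) and household
    income rescaled from its 8-point scale as (income - 1)*4/7 + 1."""
    for name, v, hi in (("edu_mother", edu_mother, 5),
                        ("edu_father", edu_father, 5),
                        ("income", income, 8)):
        if not 1 <= v <= hi:
            raise ValueError(f"{name}={v} outside scale 1..{hi}")
    income_5 = (income - 1) * 4.0 / 7.0 + 1.0
    return (edu_mother + edu_father + income_5) / 3.0


def classify_z(z: float) -> str:
    """Clinical z-score bands: >1 above average, [-1, 1] average,
    [-2, -1) below average, < -2 reduced (a score of exactly -2 counts
    as below average)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z > 1:
        return "above_average"
    if z >= -1:
        return "average"
    if z >= -2:
        return "below_average"
    return "reduced"
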