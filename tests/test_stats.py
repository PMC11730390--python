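import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nirspeech.stats import (bonferroni_family, classify_z, ks_normality,
                             mann_whitney_u, mixed_anova_2x2x2, paired_t,
                             pearson, ses_composite, slope_homogeneity,
                             spearman, two_sample_t)


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

class TestKSNormality:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(ks_normality(rng.normal(size=200))[1] > 0.05
                     for _ in range(100))
        assert passes >= 90

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(1)
        _, p = ks_normality(rng.uniform(0, 1, 500))
        assert p < 0.05

    def test_statistic_is_max_ecdf_distance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2.0, 3.0, 60)
        stat, _ = ks_normality(x)
        xs = np.sort(x)
        z = (xs - x.mean()) / x.std(ddof=1)
        cdf = sps.norm.cdf(z)
        n = len(x)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert stat == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_constant_sample_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def random_cells(rng, n1=6, n2=6):
    rows = []
    for gi, (gr, n) in enumerate((("preterm", n1), ("term", n2))):
        for s in range(n):
            rows.append({"subject": f"{gr}{s}", "group": gr,
                         "FL": rng.normal(), "FR": rng.normal(),
                         "RL": rng.normal(), "RR": rng.normal()})
    return pd.DataFrame(rows)


def brute_force_anova(cells):
    """Loop-based sums-of-squares partition of the balanced mixed design."""
    data = [(r.group, r.subject, {"FL": r.FL, "FR": r.FR,
                                  "RL": r.RL, "RR": r.RR})
            for r in cells.itertuples()]
    groups = sorted({d[0] for d in data})
    N = len(data)
    GM = np.mean([v for _, _, c in data for v in c.values()])
    A = {g: np.mean([v for g_, _, c in data if g_ == g
                     for v in c.values()]) for g in groups}
    n = {g: sum(1 for d in data if d[0] == g) for g in groups}
    S = {(g, s): np.mean(list(c.values())) for g, s, c in data}

    out = {}
    SS_G = 4 * sum(n[g] * (A[g] - GM) ** 2 for g in groups)
    SS_sub = 4 * sum((S[(g, s)] - A[g]) ** 2 for g, s, _ in data)
    out["group"] = SS_G / (SS_sub / (N - 2))

    def within(cellsets, label):
        # cellsets: dict level -> list of cell keys averaged at that level
        M = {lv: np.mean([c[k] for _, _, c in data for k in ks])
             for lv, ks in cellsets.items()}
        GL = {(g, lv): np.mean([c[k] for g_, _, c in data if g_ == g
                                for k in ks])
              for g in groups for lv, ks in cellsets.items()}
        SL = {(g, s, lv): np.mean([c[k] for k in ks])
              for g, s, c in data for lv, ks in cellsets.items()}
        SS_W = 2 * N * sum((M[lv] - GM) ** 2 for lv in cellsets)
        SS_WG = 2 * sum(n[g] * (GL[(g, lv)] - A[g] - M[lv] + GM) ** 2
                        for g in groups for lv in cellsets)
        SS_Ws = 2 * sum((SL[(g, s, lv)] - S[(g, s)] - GL[(g, lv)] + A[g]) ** 2
                        for g, s, _ in data for lv in cellsets)
        err = SS_Ws / (N - 2)
        out[label] = SS_W / err
        out[f"{label}*group"] = SS_WG / err

    within({"F": ["FL", "FR"], "R": ["RL", "RR"]}, "condition")
    within({"L": ["FL", "RL"], "R": ["FR", "RR"]}, "hemisphere")
    # interaction contrast treated as a two-level factor of recombined cells
    within({"same": ["FL", "RR"], "cross": ["FR", "RL"]},
           "condition*hemisphere")
    return out


class TestMixedAnova:
    def test_all_identical_cells_give_zero_f(self):
        cells = random_cells(np.random.default_rng(0))
        for c in ("FL", "FR", "RL", "RR"):
            cells[c] = 1.0
        tab = mixed_anova_2x2x2(cells)
        assert (tab["F"] == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_partition(self, seed):
        cells = random_cells(np.random.default_rng(seed))
        tab = mixed_anova_2x2x2(cells).set_index("effect")
        oracle = brute_force_anova(cells)
        for effect, f in oracle.items():
            assert tab.loc[effect, "F"] == pytest.approx(f, abs=1e-8), effect

    @pytest.mark.parametrize("seed", range(10))
    def test_one_df_effects_equal_contrast_t_squared(self, seed):
        cells = random_cells(np.random.default_rng(100 + seed), n1=7, n2=5)
        tab = mixed_anova_2x2x2(cells).set_index("effect")
        x = (cells.FL - cells.FR) - (cells.RL - cells.RR)
        t = sps.ttest_ind(x[cells.group == "preterm"],
                          x[cells.group == "term"]).statistic
        assert tab.loc["condition*hemisphere*group", "F"] == \
            pytest.approx(t * t, abs=1e-8)
        m = (cells.FL + cells.FR + cells.RL + cells.RR) / 4
        t = sps.ttest_ind(m[cells.group == "preterm"],
                          m[cells.group == "term"]).statistic
        assert tab.loc["group", "F"] == pytest.approx(t * t, abs=1e-8)

    def test_partial_eta_squared_definition(self):
        cells = random_cells(np.random.default_rng(3))
        tab = mixed_anova_2x2x2(cells)
        df2 = tab["df2"].iloc[0]
        for r in tab.itertuples():
            assert r.partial_eta_sq == pytest.approx(r.F / (r.F + df2))

    def test_missing_cell_drops_subject(self):
        cells = random_cells(np.random.default_rng(4))
        cells.loc[0, "FL"] = np.nan
        tab = mixed_anova_2x2x2(cells)
        assert tab["df2"].iloc[0] == len(cells) - 1 - 2
        assert tab.attrs["dropped_subjects"] == ["preterm0"]


# ---------------------------------------------------------------------------
# t tests / U test
# ---------------------------------------------------------------------------

class TestTTests:
    def test_identical_paired_samples(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_two_sample_textbook_example(self):
        # pooled t for x={1..5}, y={2,4,6}: sp^2 = 3, t = -1/sqrt(8/5)
        t, _ = two_sample_t([1, 2, 3, 4, 5], [2, 4, 6])
        assert t == pytest.approx(-1 / np.sqrt(1.6), abs=1e-12)

    def test_one_sided_is_half_two_sided_for_positive_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 20)
        y = rng.normal(0.0, 1.0, 20)
        t, p2 = two_sample_t(x, y, "two")
        _, p1 = two_sample_t(x, y, "one")
        assert t > 0 and p1 == pytest.approx(p2 / 2)


class TestMannWhitney:
    def test_fully_tied_samples_give_central_u(self):
        res = mann_whitney_u([1, 1, 1], [1, 1, 1, 1])
        assert res["U"] == pytest.approx(6.0)  # n1*n2/2
        assert res["z"] == 0.0

    def test_complete_separation_gives_extreme_u(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res["U"] in (0.0, 9.0)

    def test_small_sample_exact_p_matches_enumeration(self):
        x = [1.2, 3.4, 0.5, 2.2]
        y = [4.1, 2.9, 5.0, 3.8]
        res = mann_whitney_u(x, y)
        assert res["method"] == "exact"
        # enumerate all assignments of ranks to group x
        allv = np.array(x + y)
        ranks = sps.rankdata(allv)
        n1 = len(x)
        u_obs = res["U"]
        mu = n1 * len(y) / 2
        count = total = 0
        for comb in itertools.combinations(range(len(allv)), n1):
            r1 = ranks[list(comb)].sum()
            u = r1 - n1 * (n1 + 1) / 2
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        assert res["p"] == pytest.approx(count / total, abs=1e-12)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

class TestCorrelations:
    def test_monotone_pair_gives_rs_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        rs, _ = spearman(x, np.exp(x))
        assert rs == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        x = np.array([0.3, 1.2, 2.2, 5.0])
        rs, _ = spearman(x, -x)
        assert rs == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 9.0, 10.0, 4.0,
                      6.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 6.0, 8.0, 7.0, 7.0, 12.0, 5.0,
                      9.0, 4.0])
        rs, _ = spearman(x, y)
        # explicit average-rank + covariance loop
        def avranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks
        rx, ry = avranks(x), avranks(y)
        num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
        den = np.sqrt(np.sum((rx - rx.mean()) ** 2) *
                      np.sum((ry - ry.mean()) ** 2))
        assert rs == pytest.approx(num / den, abs=1e-12)

    def test_small_n_exact_permutation_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rs, p = spearman(x, y)
        # brute force over all 120 permutations
        count = total = 0
        for perm in itertools.permutations(y):
            r = sps.spearmanr(x, perm).statistic
            if abs(r) >= abs(rs) - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestBonferroni:
    def test_family_of_one_keeps_nominal_level(self):
        df = pd.DataFrame({"p": [0.04]})
        out = bonferroni_family(df, 1)
        assert out["bonferroni_significant"].iloc[0]

    def test_family_of_sixteen_raises_bar(self):
        df = pd.DataFrame({"p": [0.04, 0.003, 0.0032]})
        out = bonferroni_family(df, 16)
        # threshold is 0.05/16 = 0.003125
        assert list(out["bonferroni_significant"]) == [False, True, False]


# ---------------------------------------------------------------------------
# slope homogeneity
# ---------------------------------------------------------------------------

class TestSlopeHomogeneity:
    def test_matches_nested_model_sse_oracle(self):
        rng = np.random.default_rng(0)
        n = 40
        g = np.repeat(["a", "b"], n // 2)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + (g == "b") * 0.3 + rng.normal(size=n)
        f, p = slope_homogeneity(y, x, g)
        # brute force: SSE of models with and without separate slopes
        X_full = np.column_stack([np.ones(n), g == "b", x, (g == "b") * x])
        X_red = X_full[:, :3]
        def sse(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r
        f_oracle = (sse(X_red) - sse(X_full)) / (sse(X_full) / (n - 4))
        assert f == pytest.approx(f_oracle, abs=1e-8)

    def test_opposite_designed_slopes_detected(self):
        rng = np.random.default_rng(1)
        n = 200
        g = np.repeat(["a", "b"], n // 2)
        x = rng.normal(size=n)
        slope = np.where(g == "a", 1.0, -1.0)
        y = slope * x + rng.normal(0, 0.5, n)
        _, p = slope_homogeneity(y, x, g)
        assert p < 0.001

    def test_null_rejection_rate_controlled(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            n = 60
            g = np.repeat(["a", "b"], n // 2)
            x = rng.normal(size=n)
            y = 0.8 * x + rng.normal(size=n)   # identical slopes
            _, p = slope_homogeneity(y, x, g)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_sim <= 0.12


# ---------------------------------------------------------------------------
# composites and classification
# ---------------------------------------------------------------------------

class TestSES:
    def test_scale_endpoints(self):
        assert ses_composite(5, 5, 8) == pytest.approx(5.0)
        assert ses_composite(1, 1, 1) == pytest.approx(1.0)

    def test_hand_computed_midpoint(self):
        # (3 + 4 + ((5-1)*4/7 + 1)) / 3 = 24/7
        assert ses_composite(3, 4, 5) == pytest.approx(24 / 7)

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            ses_composite(0, 3, 4)
        with pytest.raises(ValueError):
            ses_composite(3, 3, 9)


class TestClassifyZ:
    @pytest.mark.parametrize("z,expected", [
        (0.0, "average"), (1.0, "average"), (-1.0, "average"),
        (1.5, "above_average"),
        (-1.2, "below_average"),
        (-2.0, "below_average"),   # a score of exactly -2 is not "reduced"
        (-2.89, "reduced"),
    ])
    def test_band_assignment(self, z, expected):
        assert classify_z(z) == expected

    @settings(max_examples=200, deadline=None)
    @given(z=st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_partition_is_total_and_ordered(self, z):
        band = classify_z(z)
        assert band in {"above_average", "average", "below_average",
                        "reduced"}
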