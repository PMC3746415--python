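"""Statistical battery: split-plot ANOVA, paired t, lag-advanced F, trends."""

import numpy as np
import pandas as pd
import pytest

from cilithermo import (
    fit_poly2_trend,
    lag_advanced_f,
    oneway_between,
    paired_t,
    rm_factorial_anova,
    simple_effects,
    trend_f,
)
from cilithermo.errors import DesignError, InsufficientDataError


def make_design(rng, n_per_group=4, groups=("a", "b", "c"), within=("m1", "m2"),
                group_shift=0.0):
    rows = []
    for gi, g in enumerate(groups):
        for s in range(n_per_group):
            subj = f"{g}{s}"
            base = rng.normal(gi * group_shift, 1.0)
            for wi, w in enumerate(within):
                rows.append(
                    {"subject": subj, "group": g, "cond": w,
                     "value": base + 0.5 * wi + rng.normal(0, 0.3)}
                )
    return pd.DataFrame(rows)


def split_plot_oracle(df):
    """Brute-force textbook sums-of-squares for the balanced split-plot design."""
    y = df["value"].to_numpy()
    gm = y.mean()
    c = df["cond"].nunique()
    subj = df.groupby("subject")["value"].mean()
    subj_group = df.groupby("subject")["group"].first()
    ss_bs = c * ((subj - gm) ** 2).sum()
    ss_g = 0.0
    for g, grp in df.groupby("group"):
        ss_g += len(grp) * (grp["value"].mean() - gm) ** 2
    ss_w = 0.0
    for w, grp in df.groupby("cond"):
        ss_w += len(grp) * (grp["value"].mean() - gm) ** 2
    ss_cells = 0.0
    for _, grp in df.groupby(["group", "cond"]):
        ss_cells += len(grp) * (grp["value"].mean() - gm) ** 2
    ss_total = ((y - gm) ** 2).sum()
    ss_int = ss_cells - ss_g - ss_w
    ss_serr = ss_bs - ss_g
    ss_resid = ss_total - ss_bs - ss_w - ss_int
    n_subj, n_g = subj.shape[0], df["group"].nunique()
    f_g = (ss_g / (n_g - 1)) / (ss_serr / (n_subj - n_g))
    f_w = (ss_w / (c - 1)) / (ss_resid / ((n_subj - n_g) * (c - 1)))
    f_i = (ss_int / ((n_g - 1) * (c - 1))) / (ss_resid / ((n_subj - n_g) * (c - 1)))
    return f_g, f_w, f_i


class TestPairedT:
    def test_identical_series_zero_difference_rule(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.flag == "zero_difference"
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_constant_nonzero_difference_flagged(self):
        r = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.flag == "degenerate_constant_difference"
        assert r.p_value == 0.0 and np.isinf(r.statistic)

    def test_hand_computation_zero_mean_difference(self):
        r = paired_t([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.df == (2,)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy import stats as sps

        x, y = rng.normal(size=20), rng.normal(size=20)
        r = paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert r.statistic == pytest.approx(t)
        assert r.p_value == pytest.approx(p)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestSplitPlotAnova:
    def test_null_design_all_identical(self, rng):
        df = make_design(rng)
        df["value"] = 1.0
        out = rm_factorial_anova(df, "value", "subject", "group", "cond")
        assert (out["F"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()

    def test_complete_separation(self, rng):
        df = make_design(rng)
        df["value"] = np.where(df["group"] == "a", 0.0, 1.0)
        out = rm_factorial_anova(df, "value", "subject", "group", "cond")
        grp = out.set_index("effect").loc["group"]
        assert np.isposinf(grp["F"]) and grp["p_value"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        df = make_design(rng, n_per_group=5, group_shift=0.8)
        out = rm_factorial_anova(df, "value", "subject", "group", "cond")
        f_g, f_w, f_i = split_plot_oracle(df)
        got = out.set_index("effect")["F"]
        assert got["group"] == pytest.approx(f_g, abs=1e-8)
        assert got["cond"] == pytest.approx(f_w, abs=1e-8)
        assert got["group*cond"] == pytest.approx(f_i, abs=1e-8)

    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = make_design(rng, n_per_group=6, group_shift=0.5)
        out = rm_factorial_anova(df, "value", "subject", "group", "cond")
        pg = pingouin.mixed_anova(
            df, dv="value", within="cond", between="group", subject="subject"
        ).set_index("Source")
        got = out.set_index("effect")
        assert got.loc["group", "F"] == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert got.loc["cond", "F"] == pytest.approx(pg.loc["cond", "F"], rel=1e-6)
        assert got.loc["group*cond", "F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6
        )

    def test_weighted_analysis_scales_values(self, rng):
        df = make_design(rng)
        df["w"] = 2.0
        out_w = rm_factorial_anova(df, "value", "subject", "group", "cond", weights="w")
        df2 = df.assign(value=df["value"] * 2.0)
        out_2 = rm_factorial_anova(df2, "value", "subject", "group", "cond")
        assert np.allclose(out_w["F"], out_2["F"], equal_nan=True)

    def test_empty_cell_raises_named_error(self, rng):
        df = make_design(rng)
        df = df[~((df["group"] == "b") & (df["cond"] == "m2"))]
        with pytest.raises(DesignError):
            rm_factorial_anova(df, "value", "subject", "group", "cond")

    def test_simple_effects_cover_all_pairs(self, rng):
        df = make_design(rng)
        out = simple_effects(df, "value", "subject", "group", "cond")
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_oneway_reports_group_means(self, rng):
        df = make_design(rng, group_shift=1.0)
        r = oneway_between(df, "value", "subject", "group")
        assert set(r.group_means) == {"a", "b", "c"}
        assert r.df == (2, 9)


class TestLagAdvancedF:
    def test_constant_series_degenerate(self):
        r = lag_advanced_f(np.ones(58))
        assert r.flag == "degenerate_variance"

    def test_expected_degrees_of_freedom(self, rng):
        r = lag_advanced_f(rng.normal(size=58))
        assert r.df == (56, 57)

    def test_detects_dominant_leading_outlier(self, rng):
        series = np.concatenate([[100.0], rng.normal(0, 1, 57)])
        r = lag_advanced_f(series)
        assert r.statistic < 0.2
        assert r.p_value < 0.05

    def test_trend_alternative_detects_linear_improvement(self, rng):
        y = np.linspace(0, 1, 58) + rng.normal(0, 0.05, 58)
        r = trend_f(y)
        assert r.p_value < 1e-6
        assert r.mean_difference > 0  # slope

    def test_trend_alternative_null(self, rng):
        rejections = sum(
            trend_f(rng.normal(size=58)).p_value < 0.05 for _ in range(400)
        )
        assert abs(rejections / 400 - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 400)


class TestPoly2Trend:
    def test_exact_square(self):
        x = np.array([0.0, 1.0, 2.0])
        fit = fit_poly2_trend(x, x**2)
        assert fit["a0"] == pytest.approx(0.0, abs=1e-10)
        assert fit["a1"] == pytest.approx(0.0, abs=1e-10)
        assert fit["a2"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_series(self):
        fit = fit_poly2_trend(np.arange(5.0), np.full(5, 3.0))
        assert fit["a0"] == pytest.approx(3.0, abs=1e-10)
        assert fit["a1"] == pytest.approx(0.0, abs=1e-10)
        assert fit["a2"] == pytest.approx(0.0, abs=1e-10)

    def test_four_points_on_parabola(self):
        fit = fit_poly2_trend([1, 2, 3, 4], [1, 4, 9, 16])
        assert fit["a2"] == pytest.approx(1.0, abs=1e-10)
        assert fit["a1"] == pytest.approx(0.0, abs=1e-10)
        assert fit["a0"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 40)
        y = rng.normal(size=40)
        fit = fit_poly2_trend(x, y)
        X = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit["a0"] == pytest.approx(beta[0], abs=1e-8)
        assert fit["a1"] == pytest.approx(beta[1], abs=1e-8)
        assert fit["a2"] == pytest.approx(beta[2], abs=1e-8)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_poly2_trend([1, 2], [1, 2])
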