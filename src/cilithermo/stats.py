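"""Statistical battery: split-plot ANOVAs, paired t-tests, lag-advanced F
comparisons, and quadratic trend fits.

The group analyses mirror a repeated-measures factorial design with one
between-subjects factor (initial responsiveness stratum) and one
within-subjects factor (engine metric, or strategy for the weighted
difference-score analysis).  Sums of squares are computed explicitly
(classic split-plot decomposition) so the machinery is transparent and
testable against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, InsufficientDataError


@dataclass
class TestResult:
    """One inferential test: statistic, degrees of freedom, p, summaries."""

    name: str
    statistic: float
    df: tuple
    p_value: float
    mean_difference: float = np.nan
    group_means: dict = field(default_factory=dict)
    group_sems: dict = field(default_factory=dict)
    flag: str | None = None


def paired_t(x, y) -> TestResult:
    """Two-tailed paired t-test with explicit degenerate handling.

    All-zero differences resolve by the zero-difference rule (statistic 0,
    p = 1, flag ``zero_difference``); a constant non-zero difference with
    zero variance is flagged ``degenerate_constant_difference`` with an
    infinite statistic and p = 0 rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.shape[0] < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    d = x - y
    n = d.shape[0]
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return TestResult("t", 0.0, (n - 1,), 1.0, 0.0, flag="zero_difference")
        return TestResult(
            "t",
            float(np.sign(md)) * np.inf,
            (n - 1,),
            0.0,
            md,
            flag="degenerate_constant_difference",
        )
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult("t", float(t), (n - 1,), float(p), md)


def lag_advanced_f(series) -> TestResult:
    """Variance-ratio comparison of a series against its one-frame-advanced self.

    F = Var(x_2..x_m) / Var(x_1..x_m) with df (m - 2, m - 1), two-tailed p
    from the F distribution; for the 58-window sessions this yields df
    (56, 57).  Degenerate (zero-variance) series are flagged rather than
    divided.  Note the two arms share m - 1 observations, which the
    reference F distribution ignores; see also :func:`trend_f` for a
    calibrated trend test.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    m = x.shape[0]
    if m < 3:
        raise InsufficientDataError("need at least 3 finite values")
    v_full = float(x.var(ddof=1))
    v_adv = float(x[1:].var(ddof=1))
    if v_full == 0.0:
        return TestResult("F", np.nan, (m - 2, m - 1), np.nan, flag="degenerate_variance")
    F = v_adv / v_full
    p = 2.0 * min(sps.f.cdf(F, m - 2, m - 1), sps.f.sf(F, m - 2, m - 1))
    return TestResult("F", float(F), (m - 2, m - 1), float(min(p, 1.0)))


def trend_f(series) -> TestResult:
    """Calibrated alternative reading of "improvement with time".

    Regression F-test (df (1, m - 2)) for a non-zero linear trend of the
    per-window scores on window index; equivalent to the squared slope t.
    """
    y = np.asarray(series, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    m = y.shape[0]
    if m < 3:
        raise InsufficientDataError("need at least 3 finite values")
    x = np.flatnonzero(keep).astype(float)
    slope, intercept, r, p, se = sps.linregress(x, y)
    if se == 0.0:
        return TestResult("F", np.nan, (1, m - 2), np.nan, flag="degenerate_variance")
    t = slope / se
    return TestResult("F", float(t**2), (1, m - 2), float(p), mean_difference=float(slope))


def fit_poly2_trend(windows, values) -> dict:
    """Least-squares quadratic trend y = a0 + a1 x + a2 x^2.

    Returns coefficients in ascending order plus fit diagnostics; exact
    interpolation when given exactly three points.
    """
    x = np.asarray(windows, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.shape[0] < 3:
        raise InsufficientDataError("quadratic fit needs at least 3 finite points")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)
    return {
        "a0": float(coeffs[0]),
        "a1": float(coeffs[1]),
        "a2": float(coeffs[2]),
        "r_squared": r2,
        "rss": ss_res,
        "n": int(x.shape[0]),
    }


def _check_design(data: pd.DataFrame, subject: str, between: str, within: str) -> None:
    counts = data.groupby([between, within], observed=True)[subject].nunique().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        bad = [
            (g, w)
            for g in counts.index
            for w in counts.columns
            if pd.isna(counts.loc[g, w]) or counts.loc[g, w] == 0
        ]
        raise DesignError(f"empty design cell(s): {bad}")
    per_subj = data.groupby(subject, observed=True)[within].nunique()
    n_within = data[within].nunique()
    if (per_subj != n_within).any():
        bad_subjects = per_subj.index[per_subj != n_within].tolist()
        raise DesignError(f"incomplete within-factor for subject(s): {bad_subjects}")
    if (data.groupby(between, observed=True)[subject].nunique() < 2).any():
        raise DesignError("each between-group needs at least 2 subjects")


def rm_factorial_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    weights: str | None = None,
) -> pd.DataFrame:
    """Split-plot (mixed) factorial ANOVA by explicit sums of squares.

    One observation per subject x within-level; the between factor nests
    subjects.  Effects returned: between main effect (tested against
    subjects-within-groups), within main effect and interaction (tested
    against the within-subjects residual).  When ``weights`` names a
    column, each observation is first multiplied by its weight (used for
    the occurrence-weighted difference-score analysis).
    """
    df = data[[subject, between, within, dv] + ([weights] if weights else [])].copy()
    df = df.dropna(subset=[dv])
    if weights:
        df[dv] = df[dv] * df[weights]
    _check_design(df, subject, between, within)

    y = df[dv].to_numpy(dtype=float)
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())

    n_within = df[within].nunique()
    subj_means = df.groupby(subject, observed=True)[dv].mean()
    subj_group = df.groupby(subject, observed=True)[between].first()
    ss_between_subj = float(n_within * ((subj_means - gm) ** 2).sum())

    group_means = df.groupby(between, observed=True)[dv].mean()
    group_sizes = subj_group.value_counts()
    ss_group = float(
        sum(
            n_within * group_sizes[g] * (group_means[g] - gm) ** 2
            for g in group_means.index
        )
    )
    ss_subj_error = ss_between_subj - ss_group

    cell = df.groupby([between, within], observed=True)[dv].agg(["mean", "count"])
    ss_cells = float((cell["count"] * (cell["mean"] - gm) ** 2).sum())
    within_means = df.groupby(within, observed=True)[dv].agg(["mean", "count"])
    ss_within_effect = float(
        (within_means["count"] * (within_means["mean"] - gm) ** 2).sum()
    )
    ss_inter = ss_cells - ss_group - ss_within_effect
    ss_within_resid = ss_total - ss_between_subj - ss_within_effect - ss_inter

    n_subj = subj_means.shape[0]
    n_groups = group_means.shape[0]
    df_group = n_groups - 1
    df_subj_err = n_subj - n_groups
    df_within = n_within - 1
    df_inter = df_group * df_within
    df_resid = df_subj_err * df_within

    def row(effect, ss, dfn, ss_err, dfe):
        msn = ss / dfn if dfn > 0 else np.nan
        mse = ss_err / dfe if dfe > 0 else np.nan
        if dfn <= 0 or dfe <= 0:
            F = np.nan
        elif msn == 0.0:  # no effect variance at all: null by construction
            F = 0.0
        elif mse == 0.0:
            F = np.inf
        else:
            F = msn / mse
        if np.isfinite(F):
            p = float(sps.f.sf(F, dfn, dfe))
        elif np.isposinf(F):
            p = 0.0
        else:
            p = np.nan
        return {
            "effect": effect, "ss": ss, "df1": dfn, "df2": dfe,
            "ms": msn, "F": F, "p_value": p,
        }

    out = pd.DataFrame(
        [
            row(between, ss_group, df_group, ss_subj_error, df_subj_err),
            row(within, ss_within_effect, df_within, ss_within_resid, df_resid),
            row(f"{between}*{within}", ss_inter, df_inter, ss_within_resid, df_resid),
        ]
    )
    out.attrs["ss_subject_error"] = ss_subj_error
    out.attrs["ss_residual"] = ss_within_resid
    out.attrs["group_means"] = group_means.to_dict()
    return out


def simple_effects(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    weights: str | None = None,
) -> dict[tuple, pd.DataFrame]:
    """Pairwise between-group contrasts: the full split-plot ANOVA rerun on
    every pair of between-factor levels (the paper's partial comparisons)."""
    levels = sorted(data[between].unique())
    out = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            sub = data[data[between].isin([a, b])]
            out[(a, b)] = rm_factorial_anova(
                sub, dv=dv, subject=subject, between=between, within=within,
                weights=weights,
            )
    return out


def oneway_between(data: pd.DataFrame, dv: str, subject: str, between: str) -> TestResult:
    """One-way between-groups ANOVA on per-subject means (simple comparisons)."""
    per_subj = (
        data.dropna(subset=[dv])
        .groupby([subject, between], observed=True)[dv]
        .mean()
        .reset_index()
    )
    groups = [g[dv].to_numpy() for _, g in per_subj.groupby(between, observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DesignError("one-way ANOVA needs >= 2 groups with >= 2 subjects each")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    means = {
        str(k): float(g[dv].mean()) for k, g in per_subj.groupby(between, observed=True)
    }
    sems = {
        str(k): float(g[dv].std(ddof=1) / np.sqrt(len(g)))
        for k, g in per_subj.groupby(between, observed=True)
    }
    return TestResult("F", float(F), (df1, df2), float(p), group_means=means, group_sems=sems)
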