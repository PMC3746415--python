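"""End-to-end analysis: series -> strategies -> distributions -> engine
metrics -> error thresholds -> group statistics.

``analyze_series`` carries one cell x behavior series through every stage;
``analyze_cohort`` applies it to a long-format response table and attaches
responsiveness strata; ``study_statistics`` runs the group-level battery;
``run_pipeline`` ties the stages into a reproducible run directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .coding import flip_threshold_series, threshold_comparison
from .constants import ISI_S, K_B, LN2
from .engine import (
    boltzmann_entropy,
    channel_capacity,
    engine_metrics,
    fidelity,
    shannon_term,
)
from .errors import CilithermoError
from .probability import (
    estimate_position_probabilities,
    executed_distribution,
    planned_distribution,
)
from .stats import (
    fit_poly2_trend,
    lag_advanced_f,
    oneway_between,
    rm_factorial_anova,
    simple_effects,
    trend_f,
)
from .strategies import embed_sequential_series, find_modal
from .synthetic import CohortConfig, classify_initial_responsiveness, simulate_cohort

ENGINE_METRIC_NAMES = ("W", "eff", "P", "cop", "fidelity")


def analyze_series(
    bits: np.ndarray,
    d: int = 3,
    isi_s: float = ISI_S,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
    smoothing: float = 1.0,
    dt_mode: str = "step",
) -> pd.DataFrame:
    """Full per-window analysis of one binary response series.

    Returns one row per window with the executed strategy, its planned and
    executed probabilities, per-strategy Shannon/Boltzmann entropies,
    Szilard-engine indices, fidelity, the flip-averaged threshold entropy
    S_sn of the window's strategy, and the difference score
    S_threshold - S_executed.  The per-prefix channel-capacity estimate is
    attached in ``DataFrame.attrs["channel_capacity"]``.
    """
    bits = np.asarray(bits)
    series = embed_sequential_series(bits, d=d)
    catalog = find_modal(series)
    q = estimate_position_probabilities(bits, prior_a, prior_b)
    planned = planned_distribution(q, d=d)
    executed = executed_distribution(series, smoothing=smoothing)

    m = series.m
    idx = np.arange(m)
    sids = series.strategy_ids
    p_p = planned[idx, sids]
    p_e = executed[idx, sids]
    h_p = shannon_term(p_p)
    h_e = shannon_term(p_e)
    s_p = boltzmann_entropy(h_p)
    s_e = boltzmann_entropy(h_e)

    if dt_mode == "step":
        dt_s = isi_s
    elif dt_mode == "period":
        dt_s = d * isi_s
    else:
        raise CilithermoError(f"unknown dt_mode {dt_mode!r}")
    em = engine_metrics(s_p, s_e, dt_s=dt_s)

    # Per-position expected probabilities of the executed strategy's bits,
    # used both for its planned probability and for the flip thresholds.
    from numpy.lib.stride_tricks import sliding_window_view

    Q = sliding_window_view(q, d)
    x = np.where(series.windows == 1, Q, 1.0 - Q)
    s_thr = flip_threshold_series(x)

    cap = channel_capacity(planned.argmax(axis=1), sids, k=2**d)

    df = pd.DataFrame(
        {
            "window": idx + 1,
            **{f"b{k + 1}": series.windows[:, k] for k in range(d)},
            "strategy_id": sids,
            "omega": series.omega,
            "is_modal": catalog.is_modal,
            "p_planned": p_p,
            "p_executed": p_e,
            "H_planned": h_p,
            "H_executed": h_e,
            "S_planned": s_p,
            "S_executed": s_e,
            "W": em.W,
            "P": em.P,
            "eff": em.eff,
            "cop": em.cop,
            "fidelity": fidelity(p_p, p_e),
            "cycle": em.cycle,
            "S_threshold": s_thr,
            "diff_score": s_thr - s_e,
        }
    )
    df.attrs["channel_capacity"] = cap
    df.attrs["modal_strategy_id"] = catalog.modal_id
    return df


def analyze_cohort(responses: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-window metrics for every cell x behavior in a response table.

    Adds ``cell_id``, ``behavior`` and the initial-responsiveness ``group``
    (classified from the first five realized responses, exactly as the
    recorded cohorts were stratified).
    """
    parts = []
    for (cell, behavior), grp in responses.groupby(["cell_id", "behavior"]):
        bits = grp.sort_values("trial")["response"].to_numpy()
        df = analyze_series(bits, **kwargs)
        df.insert(0, "cell_id", cell)
        df.insert(1, "behavior", behavior)
        df.insert(2, "group", classify_initial_responsiveness(bits))
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def _metric_long(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean of each engine metric, long format for the RM ANOVA."""
    per_cell = (
        metrics.groupby(["cell_id", "group"], observed=True)[list(ENGINE_METRIC_NAMES)]
        .mean()
        .reset_index()
    )
    return per_cell.melt(
        id_vars=["cell_id", "group"], var_name="metric", value_name="value"
    )


def _difference_long(metrics: pd.DataFrame, d: int = 3) -> pd.DataFrame:
    """Per-cell per-strategy mean difference score with occurrence weights."""
    agg = (
        metrics.groupby(["cell_id", "group", "strategy_id"], observed=True)
        .agg(value=("diff_score", "mean"), weight=("diff_score", "size"))
        .reset_index()
    )
    # Complete the within factor: strategies a cell never executed enter
    # with weight 0 (and hence contribute 0 to the weighted analysis).
    cells = agg[["cell_id", "group"]].drop_duplicates()
    full = cells.merge(pd.DataFrame({"strategy_id": np.arange(2**d)}), how="cross")
    out = full.merge(agg, on=["cell_id", "group", "strategy_id"], how="left")
    out["weight"] = out["weight"].fillna(0.0)
    out["value"] = out["value"].fillna(0.0)
    return out


def _series_by_window(sub: pd.DataFrame, metric: str) -> np.ndarray:
    """Group-mean per-window series of one metric (windows 1..m)."""
    return sub.groupby("window", observed=True)[metric].mean().to_numpy()


def study_statistics(metrics: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The full group-level statistical battery, per behavior.

    * engine-metric RM factorial ANOVA (responsiveness groups x 5 metrics)
      with pairwise simple effects and a one-way fidelity comparison;
    * occurrence-weighted RM factorial ANOVA of threshold difference
      scores (groups x 8 strategies);
    * per-group paired comparisons of executed entropies against bit-flip
      thresholds, with verdicts;
    * per-group, per-strategy-class lag-advanced F and slope-trend tests of
      each engine index over windows;
    * quadratic trend fits of the same series.
    """
    out: dict = {}
    for behavior, beh in metrics.groupby("behavior"):
        res: dict = {}
        n_groups = beh["group"].nunique()

        long = _metric_long(beh)
        if n_groups >= 2:
            res["metric_anova"] = rm_factorial_anova(
                long, dv="value", subject="cell_id", between="group", within="metric"
            )
            if n_groups > 2:
                res["metric_anova_simple_effects"] = simple_effects(
                    long, dv="value", subject="cell_id", between="group", within="metric"
                )
            res["fidelity_oneway"] = oneway_between(
                beh, dv="fidelity", subject="cell_id", between="group"
            )
            diffs = _difference_long(beh)
            res["difference_anova"] = rm_factorial_anova(
                diffs,
                dv="value",
                subject="cell_id",
                between="group",
                within="strategy_id",
                weights="weight",
            )

        res["threshold_comparisons"] = threshold_comparison(
            beh, by=("group", "strategy_id"), alpha=alpha
        )

        lag_rows = []
        trends = []
        for (group, modal), sub in beh.groupby(["group", "is_modal"]):
            klass = "modal" if modal else "non_modal"
            for metric in ENGINE_METRIC_NAMES:
                series = _series_by_window(sub, metric)
                if np.isfinite(series).sum() < 3:
                    continue
                lag = lag_advanced_f(series)
                tr = trend_f(series)
                lag_rows.append(
                    {
                        "group": group,
                        "strategy_class": klass,
                        "metric": metric,
                        "F_lag": lag.statistic,
                        "df_lag": lag.df,
                        "p_lag": lag.p_value,
                        "F_trend": tr.statistic,
                        "df_trend": tr.df,
                        "p_trend": tr.p_value,
                        "slope": tr.mean_difference,
                    }
                )
                fit = fit_poly2_trend(
                    np.arange(1, series.shape[0] + 1), series
                )
                fit.update(group=group, strategy_class=klass, metric=metric)
                trends.append(fit)
        res["lag_advanced"] = pd.DataFrame(lag_rows)
        res["poly2_trends"] = pd.DataFrame(trends)
        out[behavior] = res
    return out


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(config: dict, out_dir: str | Path, responses: pd.DataFrame | None = None) -> Path:
    """Execute simulate -> embed -> distributions -> metrics -> statistics.

    Writes responses, ground truth (when simulated), per-window metrics,
    threshold comparisons and the statistics report into ``out_dir``, every
    file stamped with the configuration hash.  Bit-identical on rerun with
    the same config.
    """
    cfg = dict(cio.DEFAULT_CONFIG)
    cfg.update(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = cio.config_hash(cfg)
    cio.dump_config({**cfg, "config_hash": h}, out_dir / "config.yaml")

    if responses is None:
        if not cfg.get("simulate", True):
            raise CilithermoError("no input table given and simulation disabled")
        cohort = CohortConfig(
            n_trials=int(cfg["n_trials"]),
            isi_s=float(cfg["isi_s"]),
            master_seed=int(cfg["master_seed"]),
        )
        responses, truth = simulate_cohort(cohort)
        cio.write_table(truth, out_dir / "ground_truth.tsv", h)
    cio.write_table(responses, out_dir / "responses.tsv", h)

    metrics = analyze_cohort(
        responses,
        d=int(cfg["d"]),
        isi_s=float(cfg["isi_s"]),
        prior_a=float(cfg["prior_a"]),
        prior_b=float(cfg["prior_b"]),
        smoothing=float(cfg["smoothing"]),
        dt_mode=cfg["dt_mode"],
    )
    table = metrics.copy()
    if cfg.get("entropy_unit") == "bits":
        for col in ("S_planned", "S_executed", "W", "P", "S_threshold", "diff_score"):
            table[col] = table[col] / (K_B * LN2)
    cio.write_table(table, out_dir / "window_metrics.tsv", h)

    stats = study_statistics(metrics)
    for behavior, res in stats.items():
        cio.write_table(
            res["threshold_comparisons"],
            out_dir / f"threshold_comparison_{behavior}.tsv",
            h,
        )
    report = {"config_hash": h, "n_windows_per_cell": int(cfg["n_trials"]) - int(cfg["d"]) + 1}
    report["statistics"] = _jsonable(stats)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return out_dir
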