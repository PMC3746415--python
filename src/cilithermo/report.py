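"""Figures summarizing one analyzed cohort.

Panel layout per behavior x responsiveness group: executed vs flip-threshold
entropies per strategy (bars), and window trends of engine work, efficiency,
COP and fidelity for modal vs non-modal strategies with quadratic fits.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import fit_poly2_trend

_TREND_METRICS = ("W", "eff", "cop", "fidelity")


def _trend_panel(ax, sub: pd.DataFrame, metric: str) -> None:
    for modal, color, label in ((True, "tab:red", "modal"), (False, "tab:green", "non-modal")):
        part = sub[sub["is_modal"] == modal]
        if part.empty:
            continue
        series = part.groupby("window")[metric].mean()
        x = series.index.to_numpy(dtype=float)
        y = series.to_numpy()
        ax.plot(x, y, ".", ms=3, color=color, alpha=0.5, label=label)
        if np.isfinite(y).sum() >= 3:
            fit = fit_poly2_trend(x, y)
            xx = np.linspace(x.min(), x.max(), 100)
            ax.plot(xx, fit["a0"] + fit["a1"] * xx + fit["a2"] * xx**2, "-", color=color)
    ax.set_xlabel("window")
    ax.set_ylabel(metric)


def cohort_figures(metrics: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one summary figure per behavior x group; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (behavior, group), sub in metrics.groupby(["behavior", "group"]):
        fig, axes = plt.subplots(1, 5, figsize=(20, 3.6))
        per_strategy = sub.groupby("strategy_id")[["S_executed", "S_threshold"]].mean()
        ids = per_strategy.index.to_numpy()
        axes[0].bar(ids - 0.2, per_strategy["S_executed"], width=0.4, label="executed")
        axes[0].bar(ids + 0.2, per_strategy["S_threshold"], width=0.4, label="flip threshold")
        axes[0].set_xlabel("strategy id")
        axes[0].set_ylabel("S (J/K)")
        axes[0].legend(fontsize=7)
        for ax, metric in zip(axes[1:], _TREND_METRICS):
            _trend_panel(ax, sub, metric)
        axes[1].legend(fontsize=7)
        fig.suptitle(f"{behavior} / initial {group} responsiveness")
        fig.tight_layout()
        path = out_dir / f"summary_{behavior}_{group}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
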