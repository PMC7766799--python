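"""Figure helpers: per-hemisphere ranking bars and the group-level fit."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mixed_model import MixedModelResult
from .selection_eval import HemisphereRanking

__all__ = ["plot_contact_ranking", "plot_mixed_model_fit"]


def plot_contact_ranking(rankings: list[HemisphereRanking], out: str | Path) -> Path:
    """Bar plot per hemisphere: improvement vs contacts ordered by
    descending tract overlap; the best clinical contact is highlighted."""
    n = len(rankings)
    ncols = min(4, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    for ax, ranking in zip(axes.ravel(), rankings):
        entries = ranking.entries  # already rank-ordered
        colors = ["#2e8b57" if e.is_best_clinical else "#778899" for e in entries]
        ax.bar(
            range(len(entries)),
            [e.improvement_pct for e in entries],
            color=colors,
        )
        ax.set_xticks(range(len(entries)))
        ax.set_xticklabels([str(e.contact_id) for e in entries], fontsize=7)
        ax.set_title(f"{ranking.patient_id} {ranking.hemisphere}", fontsize=9)
        ax.set_xlabel("contact (high→low overlap)", fontsize=7)
        ax.set_ylabel("improvement %", fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_mixed_model_fit(
    result: MixedModelResult, data: pd.DataFrame, out: str | Path
) -> Path:
    """Scatter of improvement vs overlap, fixed-effect line with a 95%
    Wald band, and dashed per-lead lines (shared slope, shifted
    intercepts)."""
    fig, ax = plt.subplots(figsize=(5.5, 4.2))
    x = data["overlap_mm3"].to_numpy(float)
    y = data["improvement_pct"].to_numpy(float)
    ax.scatter(x, y, s=14, alpha=0.6, color="#445566")
    xs = np.linspace(x.min(), x.max(), 100)
    yhat = result.beta0 + result.beta1 * xs
    band = 1.96 * result.se_beta1 * np.abs(xs - x.mean())
    ax.fill_between(xs, yhat - band, yhat + band, color="0.8", alpha=0.6)
    ax.plot(xs, yhat, color="black", lw=2, label="fixed effect")
    for lead, u in result.random_intercepts.items():
        ax.plot(xs, yhat + u, ls="--", color="0.6", lw=0.8)
    ax.set_xlabel("tract overlap (mm$^3$)")
    ax.set_ylabel("tremor improvement (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)
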