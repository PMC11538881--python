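"""Figure exports: trace/rank/energy diagnostics, model comparison, forecasts.

All functions write PNG files and return the path; they use the Agg backend
so they run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import arviz as az
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .prediction import PredictiveDistribution

__all__ = [
    "plot_trace",
    "plot_rank",
    "plot_energy",
    "plot_comparison",
    "plot_predictive",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_trace(draws: PosteriorDraws, path: str | Path) -> Path:
    axes = az.plot_trace(draws.to_inference_data(), compact=True)
    return _save(axes.ravel()[0].figure, path)


def plot_rank(draws: PosteriorDraws, path: str | Path) -> Path:
    axes = az.plot_rank(draws.to_inference_data())
    return _save(np.ravel(axes)[0].figure, path)


def plot_energy(draws: PosteriorDraws, path: str | Path) -> Path:
    ax = az.plot_energy(draws.to_inference_data())
    return _save(ax.figure, path)


def plot_comparison(table: pd.DataFrame, path: str | Path) -> Path:
    """Dot-whisker deviance plot: filled = in-sample, empty = out-of-sample
    with its 89% interval, vertical line at the best model's deviance."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1))
    y = np.arange(len(table))[::-1]
    ax.axvline(table["deviance"].min(), color="0.6", lw=1)
    ax.errorbar(
        table["deviance"], y,
        xerr=np.vstack([
            table["deviance"] - table["deviance_lo89"],
            table["deviance_hi89"] - table["deviance"],
        ]),
        fmt="o", mfc="white", color="C0", label="out-of-sample (89% CI)",
    )
    ax.plot(table["deviance_in_sample"], y, "o", color="C0", label="in-sample")
    ax.set_yticks(y)
    ax.set_yticklabels(table.index)
    ax.set_xlabel("deviance (-2 elpd)")
    ax.legend(loc="best", fontsize=8)
    return _save(fig, path)


def plot_predictive(pred: PredictiveDistribution, path: str | Path, max_k: int | None = None) -> Path:
    if max_k is None:
        cdf = pred.cdf()
        max_k = int(pred.support[min(np.searchsorted(cdf, 0.999), len(cdf) - 1)]) + 2
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(pred.support[:max_k], pred.pmf[:max_k], color="C0", width=0.9)
    lo, hi = pred.modal_band
    ax.axvspan(lo - 0.5, hi + 0.5, color="C1", alpha=0.2,
               label=f"most probable counts {lo}-{hi}")
    ax.set_xlabel("specimen mitotic count / 5 mm$^2$")
    ax.set_ylabel("predictive probability")
    ax.legend()
    return _save(fig, path)
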