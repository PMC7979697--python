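"""Plotting hooks for fitted curves, rankings and projections."""

from __future__ import annotations

import numpy as np

from .growth import ChapmanRichardsResults
from .importance import ImportanceResult
from .scenarios import ScenarioProjection


def plot_growth_fit(results: ChapmanRichardsResults, ax=None, max_age: int = 40):
    """Fitted curve with 95% band and the median data points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, max_age, 200)
    y = results.predict(t)
    lo, hi = results.prediction_band(t, seed=0)
    ax.fill_between(t, lo, hi, alpha=0.25, linewidth=0)
    ax.plot(t, y)
    ax.plot(results.model.age, results.model.agc, "o", ms=4)
    ax.set_xlabel("stand age (yr)")
    ax.set_ylabel("AGC, bias-corrected (Mg C ha$^{-1}$)")
    if results.group:
        ax.set_title(results.group)
    return ax


def plot_importance(result: ImportanceResult, ax=None):
    """Bar chart of mean importance ranks with 95% CI."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = result.summary()
    err = np.vstack(
        [s["mean_rank"] - s["ci95_lower"], s["ci95_upper"] - s["mean_rank"]]
    )
    ax.bar(s.index, s["mean_rank"], yerr=err, capsize=3)
    ax.set_ylabel("mean importance rank")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_projection(projections: dict[str, ScenarioProjection], ax=None):
    """Stock trajectories per preservation scenario."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, p in projections.items():
        ax.plot(p.years, p.stock_TgC, label=name)
        if p.ci_lower is not None:
            ax.fill_between(p.years, p.ci_lower, p.ci_upper, alpha=0.15, linewidth=0)
    ax.set_xlabel("year")
    ax.set_ylabel("carbon stock (Tg C)")
    ax.legend()
    return ax
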