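"""Optional plotting convenience: observed points with fitted curves overlaid."""

from __future__ import annotations

import numpy as np

from .model import GrowthFitResults
from .series import GrowthSeries

__all__ = ["plot_fit"]


def plot_fit(series: GrowthSeries, *fits: GrowthFitResults, ax=None,
             n_curve_points: int = 300):
    """Scatter the observations and overlay one or more fitted trajectories.

    Requires matplotlib (an optional dependency).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.times, series.biomass, "o", mfc="none", color="0.3",
            label="observed")
    grid = np.linspace(series.times[0], series.times[-1], n_curve_points)
    styles = {"NSG": dict(color="tab:red", ls="-"),
              "BSG": dict(color="black", ls="--")}
    for fit in fits:
        ax.plot(grid, fit.predict(grid),
                label=f"{fit.model_id} (R$^2$={fit.rsquared:.3f})",
                **styles.get(fit.model_id, {}))
    ax.set_xlabel("time (d)")
    ax.set_ylabel("biomass (g)")
    if series.label:
        ax.set_title(series.label)
    ax.legend()
    return ax
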