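"""Generic plotting helpers for performance surfaces and fit maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .simulate import FitResult, PerformanceSurface

__all__ = ["plot_surface", "plot_fit_map"]


def plot_surface(surface: PerformanceSurface, ax=None, contour: bool = True):
    """Heatmap of proportion correct over the (cross, within) design triangle."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    withins = sorted({k[0] for k in surface.keys()})
    crosses = sorted({k[1] for k in surface.keys()})
    img = np.full((len(withins), len(crosses)), np.nan)
    for (w, c), pc in surface.entries.items():
        img[withins.index(w), crosses.index(c)] = pc
    mesh = ax.imshow(img, origin="lower", cmap="Reds", vmin=0.4, vmax=1.0,
                     extent=(min(crosses), max(crosses), min(withins), max(withins)),
                     aspect="auto")
    if contour and img.shape[0] > 1 and img.shape[1] > 1:
        masked = np.ma.masked_invalid(img)
        ax.contour(crosses, withins, masked, levels=[0.6, 0.75, 0.9], colors="k",
                   linewidths=0.7)
    ax.set_xlabel("cross-area correlation")
    ax.set_ylabel("within-area correlation")
    plt.colorbar(mesh, ax=ax, label="proportion correct")
    return ax


def plot_fit_map(fit: FitResult, ax=None):
    """Heatmap of fit R^2 over the (signal rate, sigma_delta) grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    mesh = ax.imshow(fit.r2_map, origin="lower", cmap="viridis",
                     extent=(fit.sigma_deltas[0], fit.sigma_deltas[-1],
                             fit.signal_rates[0], fit.signal_rates[-1]),
                     aspect="auto")
    best = fit.best_params
    ax.plot(best.sigma_delta, best.signal_rate, "r.", markersize=10)
    ax.set_xlabel("position-embedding sigma (elements)")
    ax.set_ylabel("signal rate s")
    plt.colorbar(mesh, ax=ax, label="fit $R^2$")
    return ax
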