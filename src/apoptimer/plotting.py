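"""Minimal plotting helpers: grid heat maps and survival curves."""
from __future__ import annotations

import numpy as np

from .timer_screen import GridScreenResult

__all__ = ["plot_grid_heatmap", "plot_survival_curves"]


def plot_grid_heatmap(result: GridScreenResult, metric: str = "max_activity", ax=None):
    """Heat map of one grid-screen metric over the APAF1 x PC9 plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = getattr(result, metric)
    finite = m[np.isfinite(m)]
    im = ax.pcolormesh(
        result.pc9,
        result.apaf1,
        m,
        shading="nearest",
        vmin=finite.min() if finite.size else None,
        vmax=finite.max() if finite.size else None,
    )
    ax.set_xlabel("PC9 (uM)")
    ax.set_ylabel("APAF1 (uM)")
    ax.set_title(f"{metric} (MOMP fraction {result.momp_fraction:g})")
    ax.figure.colorbar(im, ax=ax, label=metric)
    return ax


def plot_survival_curves(kmfs, ax=None):
    """Overlay fitted Kaplan-Meier curves (lifelines fitters)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for kmf in kmfs:
        if kmf is not None:
            kmf.plot_survival_function(ax=ax)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time")
    ax.set_ylabel("surviving fraction")
    return ax
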