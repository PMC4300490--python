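"""Basic visualization helpers for co-stimulation surfaces and curves."""

from __future__ import annotations

import numpy as np

from .core import MeanSurface

__all__ = ["surface_heatmap", "time_curves"]


def surface_heatmap(surface: MeanSurface, ppep: str, ax=None, log_scale: bool = True):
    """6x6 intensity heatmap (rows = NaCl time, columns = pheromone time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    grid = surface.grid(ppep)
    data = np.log10(grid) if log_scale else grid
    im = ax.imshow(data, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(surface.design.phe_times)), surface.design.phe_times)
    ax.set_yticks(range(len(surface.design.nacl_times)), surface.design.nacl_times)
    ax.set_xlabel("pheromone stimulation (min)")
    ax.set_ylabel("NaCl stimulation (min)")
    ax.set_title(ppep)
    ax.figure.colorbar(im, ax=ax, label="log10 intensity" if log_scale else "intensity")
    return ax


def time_curves(surface: MeanSurface, ppep: str, axis: str = "nacl", ax=None):
    """One curve per duration of the other stimulus along the chosen axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    design = surface.design
    grid = surface.grid(ppep)
    axis_times = design.nacl_times if axis == "nacl" else design.phe_times
    other_times = design.phe_times if axis == "nacl" else design.nacl_times
    for k, fixed in enumerate(other_times):
        curve = grid[:, k] if axis == "nacl" else grid[k, :]
        ax.plot(axis_times, curve, marker="o", label=f"{fixed}'")
    other = "pheromone" if axis == "nacl" else "NaCl"
    ax.set_xlabel(f"{'NaCl' if axis == 'nacl' else 'pheromone'} stimulation (min)")
    ax.set_ylabel("intensity")
    ax.set_title(ppep)
    ax.legend(title=f"{other} (min)", fontsize="small")
    return ax
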