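"""Figure helpers: trajectories, depletion curves, essentiality heatmaps.

Every figure-producing function has a CSV twin elsewhere in the package;
plots are a convenience view, never the only record of a value.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .simulate import SimulationResult

__all__ = ["plot_trajectories", "plot_depletion_curve", "plot_essentiality"]


def plot_trajectories(result: SimulationResult,
                      species: Sequence[str] = ("MPF", "Cdc25P", "Wee1",
                                                "APC/CP:Cdc20", "APC/CT:Cdh1",
                                                "Mad2:Cdc20P"),
                      ax=None, t0: float = 0.0):
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    mask = result.times >= t0
    for name in species:
        ax.plot(result.times[mask], result.species(name)[mask], label=name)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (rel. CDK1)")
    ax.legend(fontsize=8, ncol=2)
    return ax


def plot_depletion_curve(table, ax=None, label: Optional[str] = None):
    """Normalized period vs depletion level; arrested levels marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    viable = table[table["viable"] == True]          # noqa: E712
    arrested = table[table["viable"] == False]       # noqa: E712
    ax.plot(viable["level"], viable["normalized_period"], "o-", label=label)
    for _, row in arrested.iterrows():
        ax.axvline(row["level"], color="0.8", ls="--", lw=0.8)
    ax.set_xlabel("Plk1 synthesis reduction (%)")
    ax.set_ylabel("normalized period $T_m/T$")
    if label:
        ax.legend()
    return ax


def plot_essentiality(matrix, ax=None):
    """Black = arrest (essential), red = cycling, matching the in-silico
    knockout convention."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    data = matrix.essential.to_numpy().astype(float)
    cmap = matplotlib.colors.ListedColormap(["#cc2222", "#111111"])
    ax.imshow(data, cmap=cmap, vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(np.arange(len(matrix.groups)), matrix.groups,
                  rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(matrix.targets)), matrix.targets, fontsize=7)
    ax.set_xlabel("cell-line group (mutated gene)")
    ax.set_ylabel("knocked-out gene")
    return ax
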