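"""Basic plots: evolutionary fitness traces and competition-experiment
panels (mean target biomass against neighbour count, per species)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_fitness_traces", "plot_experiment_panels"]


def plot_fitness_traces(traces: Mapping[str, Sequence], path) -> None:
    """Mean survivor fitness per generation, one line per replicate run."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, runs in traces.items():
        for i, trace in enumerate(runs):
            ax.plot(trace.mean_fitness, label=label if i == 0 else None, alpha=0.7)
    ax.set_xlabel("generation")
    ax.set_ylabel("mean shoot biomass (g)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_experiment_panels(summary: pd.DataFrame, path) -> None:
    """Target biomass vs. neighbour count, one panel per target species,
    one line per neighbour species, with the 25-75% band."""
    targets = sorted(summary["target"].unique())
    fig, axes = plt.subplots(1, len(targets), figsize=(3 * len(targets), 3),
                             sharey=True, squeeze=False)
    for ax, target in zip(axes[0], targets):
        sub = summary[summary["target"] == target]
        alone = sub[sub["neighbour"] == "none"]
        for neighbour, grp in sub[sub["neighbour"] != "none"].groupby("neighbour"):
            grp = pd.concat([alone.assign(neighbour=neighbour), grp])
            grp = grp.sort_values("n_neighbours")
            ax.plot(grp["n_neighbours"], grp["mean_biomass"], marker="o", label=neighbour)
            ax.fill_between(grp["n_neighbours"], grp["q25"], grp["q75"], alpha=0.2)
        ax.set_title(f"target {target}")
        ax.set_xlabel("neighbours")
    axes[0][0].set_ylabel("shoot biomass (g)")
    axes[0][-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
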