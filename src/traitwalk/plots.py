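"""Minimal diagnostic plots from tabular outputs (styling is not a contract)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_fitness(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean fitness trajectory with a +/- 1 sd band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    g = summary["generation"]
    m = summary["mean_fitness"]
    s = summary["sd_fitness"]
    ax.fill_between(g, m - s, m + s, alpha=0.3, color="grey")
    ax.plot(g, m)
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_walk(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean population coordinates in the retained-axis plane over time."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(summary["pc1"], summary["pc2"], c=summary["generation"],
                    s=8, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="generation")
    ax.set_xlabel("pc1")
    ax.set_ylabel("pc2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_census(census: pd.DataFrame, path: str | Path) -> None:
    """Bubble chart: accessibility (size) vs adaptation rate (colour)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = range(len(census))
    sc = ax.scatter(x, census["accessibility"],
                    s=2000 * census["accessibility"], c=census["rate"],
                    cmap="plasma", alpha=0.8)
    ax.set_xticks(list(x))
    ax.set_xticklabels(census["type"])
    ax.set_ylabel("accessibility")
    fig.colorbar(sc, ax=ax, label="adaptation rate (1/generations)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
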