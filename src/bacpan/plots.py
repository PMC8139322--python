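"""Cosmetic figures: rarefaction curves and a flower plot.

These are presentation helpers; numeric results come from
:mod:`bacpan.profile`.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profile import CurveFit, PanPartition, PanProfile


def plot_rarefaction(
    profile: PanProfile,
    pan_fit: CurveFit | None = None,
    core_fit: CurveFit | None = None,
    path: str | Path = "rarefaction.svg",
) -> Path:
    """Pan/core rarefaction means with fitted curves overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    n = profile.n
    ax.plot(n, profile.mean_pan, "o", ms=3, color="tab:blue", label="pan genome")
    ax.plot(n, profile.mean_core, "o", ms=3, color="tab:red", label="core genome")
    dense = np.linspace(n[0], n[-1], 200)
    for fit, color in ((pan_fit, "tab:blue"), (core_fit, "tab:red")):
        if fit is not None and fit.success:
            ax.plot(dense, fit.predict(dense), "-", color=color, lw=1)
    ax.set_xlabel("number of genomes")
    ax.set_ylabel("gene families")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_flower(
    part: PanPartition, genome_order: list[str] | None = None,
    path: str | Path = "flower.svg",
) -> Path:
    """Flower plot: shared core in the center, per-genome unique counts
    on the petals."""
    unique = part.per_genome_unique_count
    if unique is None:
        raise ValueError("partition lacks per-genome unique counts")
    genomes = genome_order or list(unique.index)
    n = len(genomes)
    fig, ax = plt.subplots(figsize=(7, 7))
    for i, g in enumerate(genomes):
        angle = 2 * math.pi * i / n
        x, y = 2.2 * math.cos(angle), 2.2 * math.sin(angle)
        ax.add_patch(
            plt.matplotlib.patches.Ellipse(
                (x, y), 3.2, 1.1, angle=math.degrees(angle),
                alpha=0.25, color=plt.get_cmap("tab20")(i % 20),
            )
        )
        lx, ly = 4.1 * math.cos(angle), 4.1 * math.sin(angle)
        ax.text(lx, ly, f"{g}\n{int(unique[g])}", ha="center", va="center", fontsize=6)
    ax.add_patch(plt.Circle((0, 0), 1.0, color="lightyellow", ec="goldenrod"))
    ax.text(0, 0, f"core\n{part.core}", ha="center", va="center", fontsize=10)
    ax.set_xlim(-5.5, 5.5)
    ax.set_ylim(-5.5, 5.5)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
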