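"""Static landscape figures (3-D surface and top view) and stage energies."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .containers import EnergyProfile, StageAnnotation  # noqa: E402
from .landscape import LandscapeSurface  # noqa: E402

__all__ = ["plot_landscape", "plot_stage_energies"]


def plot_landscape(surface: LandscapeSurface, trajectory=None, *,
                   path=None, view: str = "3d"):
    """Render the energy surface from one of the published perspectives.

    ``view="3d"`` shows the side elevation of the landscape;
    ``view="top"`` the (PC1, PC2) plane with the trajectory.
    """
    xx, yy = np.meshgrid(surface.grid_x, surface.grid_y, indexing="ij")
    points = surface.sample_points
    stages = points["stage"].unique() if "stage" in points else [None]
    cmap = plt.get_cmap("viridis")
    colors = {s: cmap(i / max(1, len(stages) - 1))
              for i, s in enumerate(stages)}

    if view == "3d":
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(projection="3d")
        ax.plot_surface(xx, yy, surface.grid_energy, cmap="terrain",
                        alpha=0.7, linewidth=0)
        for stage in stages:
            sub = points if stage is None else points[points["stage"] == stage]
            ax.scatter(sub["pc1"], sub["pc2"], sub["energy"],
                       color=colors[stage], label=stage, s=25,
                       depthshade=False)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_zlabel("energy E")
        if stages[0] is not None:
            ax.legend(title="stage", loc="upper left", fontsize=8)
    elif view == "top":
        fig, ax = plt.subplots(figsize=(6, 5))
        pcm = ax.pcolormesh(xx, yy, surface.grid_energy, cmap="terrain",
                            shading="auto")
        fig.colorbar(pcm, ax=ax, label="energy E")
        for stage in stages:
            sub = points if stage is None else points[points["stage"] == stage]
            ax.scatter(sub["pc1"], sub["pc2"], color=colors[stage],
                       label=stage, s=25, edgecolor="k", linewidth=0.3)
        if trajectory is not None:
            ax.plot(trajectory["pc1"], trajectory["pc2"], "r-o",
                    linewidth=1.5, markersize=4, label="trajectory")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        if stages[0] is not None:
            ax.legend(fontsize=8)
    else:
        raise ValueError(f"unknown view {view!r}")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_stage_energies(profile: EnergyProfile,
                        annotation: StageAnnotation, *, path=None):
    """Bar chart of per-stage mean energies with per-sample points."""
    fig, ax = plt.subplots(figsize=(6, 4))
    order = profile.stage_order
    means = [profile.per_stage[s] for s in order]
    ax.bar(range(len(order)), means, color="steelblue", alpha=0.7)
    for i, stage in enumerate(order):
        vals = profile.per_sample[annotation.samples_of(stage)]
        ax.plot(np.full(len(vals), i), vals, "k.", alpha=0.6, markersize=4)
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("energy E")
    ax.set_xlabel("stage")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
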