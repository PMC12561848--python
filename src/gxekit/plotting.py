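"""Rendering of the four GGE biplot views (optional; analyses never need it)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def _scatter_biplot(ax, model, title):
    g = model.genotype_coords_
    e = model.environment_coords_
    for label, (x, y) in g.iterrows():
        ax.plot(x, y, "o", color="tab:blue")
        ax.annotate(str(label), (x, y), fontsize=8, color="tab:blue")
    for label, (x, y) in e.iterrows():
        ax.annotate("", (x, y), (0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:red", lw=0.8))
        ax.annotate(str(label), (x, y), fontsize=8, color="tab:red")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    v = model.var_explained_
    ax.set_xlabel(f"PC1 ({100 * v[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * (v[1] if len(v) > 1 else 0):.1f}%)")
    ax.set_title(title, fontsize=10)
    ax.set_aspect("equal", adjustable="datalim")


def plot_views(model, prefix: str) -> list[str]:
    """Render the four views as ``<prefix>_A.png`` … ``<prefix>_D.png``.

    A: environment relationships, B: which-won-where, C: mean vs.
    stability (AEC axis), D: ideal-entry concentric circles.  Returns the
    written paths.
    """
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    _scatter_biplot(ax, model, "A: relationship among environments")
    paths.append(f"{prefix}_A.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    _scatter_biplot(ax, model, "B: which-won-where")
    hull, _ = model.which_won_where()
    if hull:
        pts = model.genotype_coords_.loc[hull + hull[:1]].to_numpy()
        ax.plot(pts[:, 0], pts[:, 1], "-", color="tab:green", lw=1)
    paths.append(f"{prefix}_B.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    _scatter_biplot(ax, model, "C: mean performance vs. stability")
    mean_env = model.environment_coords_.to_numpy().mean(axis=0)
    axis = mean_env / np.linalg.norm(mean_env)
    span = np.abs(model.genotype_coords_.to_numpy()).max() * 1.5
    ax.plot([-span * axis[0], span * axis[0]],
            [-span * axis[1], span * axis[1]], "--", color="tab:purple", lw=1)
    paths.append(f"{prefix}_C.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    _scatter_biplot(ax, model, "D: ranking against the ideal entry")
    proj, _ = model.mean_vs_stability()
    ideal = axis * proj.max()
    dists, _ = model.ideal_entry()
    for radius in np.linspace(0, dists.max(), 5)[1:]:
        ax.add_patch(plt.Circle(ideal, radius, fill=False, lw=0.6,
                                color="tab:orange"))
    ax.plot(*ideal, "*", color="tab:orange", markersize=12)
    paths.append(f"{prefix}_D.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths
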