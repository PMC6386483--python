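"""Figure rendering for CLI exports (PNG/SVG, timestamp-free)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .layouts import LayoutResult


def _save(fig, path: Path) -> None:
    # suppress embedded timestamps so repeated runs are byte-comparable
    meta = {"Date": None} if path.suffix.lower() == ".svg" else {}
    fig.savefig(path, metadata=meta)
    plt.close(fig)


def plot_network(layout: LayoutResult, path: str | Path, node_size: float = 30.0) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 7))
    cmap = plt.get_cmap("RdBu_r")  # +1 red, -1 blue, 0 neutral
    for (a, b), r in layout.edge_color.items():
        if a in layout.coordinates and b in layout.coordinates:
            xa, ya = layout.coordinates[a]
            xb, yb = layout.coordinates[b]
            ax.plot([xa, xb], [ya, yb], color=cmap((r + 1.0) / 2.0), lw=0.8, zorder=1)
    border_color = {"up": "green", "down": "red", "neutral": "none"}
    xs, ys, edgecolors = [], [], []
    for node, (x, y) in layout.coordinates.items():
        xs.append(x)
        ys.append(y)
        edgecolors.append(border_color.get(layout.node_border.get(node, "neutral"), "none"))
    ax.scatter(xs, ys, s=node_size, c="lightgray", edgecolors=edgecolors, zorder=2)
    ax.set_aspect("equal")
    ax.axis("off")
    _save(fig, path)
    return path


def plot_heatmap(matrix: np.ndarray, ordering: list[str], path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(matrix)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.9")  # neutral background for filtered-out cells
    im = ax.imshow(masked, cmap=cmap, vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="correlation")
    ax.set_xticks([])
    ax.set_yticks([])
    _save(fig, path)
    return path


def plot_trajectories(trajectory, path: str | Path) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 5))
    x = np.arange(len(trajectory.sample_order))
    for ci, vals in sorted(trajectory.trajectories.items()):
        ax.plot(x, vals, marker="o", ms=3, label=f"cluster {ci} (n={len(trajectory.members[ci])})")
    ax.set_xticks(x)
    ax.set_xticklabels(trajectory.sample_order, rotation=90, fontsize=6)
    ax.set_ylabel(f"{trajectory.aggregate} concentration")
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save(fig, path)
    return path


def plot_distribution_panel(panel, path: str | Path) -> Path:
    path = Path(path)
    labels = list(panel.groups)
    fig, axes = plt.subplots(1, len(labels), figsize=(5 * len(labels), 4), squeeze=False)
    for ax, label in zip(axes[0], labels):
        stats = panel.groups[label]
        times = sorted(stats)
        bxp = [
            {
                "med": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whislo": s.whisker_low,
                "whishi": s.whisker_high,
                "fliers": s.outliers,
            }
            for s in (stats[t] for t in times)
        ]
        ax.bxp(bxp, positions=times, widths=0.5)
        if label in panel.fits:
            fit = panel.fits[label]
            tline = np.linspace(min(times), max(times), 50)
            ax.plot(tline, fit.predict(tline), "r-", lw=1,
                    label=f"{fit.method}: slope={fit.slope:.3g}")
            ax.legend(fontsize=7)
        ax.set_title(f"{panel.molecule} — {label}", fontsize=9)
        ax.set_xlabel("time")
    fig.tight_layout()
    _save(fig, path)
    return path
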