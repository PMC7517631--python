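"""Optional diagnostic figures: hex module panel, cluster trajectories, volcano.

All functions write a PNG and return the path; matplotlib's Agg backend is
forced so the pipeline can run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import RegularPolygon

from irsom.som import HexSOM


def hex_panel(
    model: HexSOM,
    sizes: np.ndarray,
    path: str | Path,
) -> Path:
    """Hexagonal grid colored by U-matrix value, annotated with module sizes."""
    umatrix = model.u_matrix()
    fig, ax = plt.subplots(figsize=(7, 6))
    values = umatrix.module_values
    vmax = values.max() if values.max() > 0 else 1.0
    cmap = plt.get_cmap("cividis_r")
    for k, (x, y) in enumerate(model.grid_coords_):
        ax.add_patch(
            RegularPolygon(
                (x, y), numVertices=6, radius=0.57, orientation=np.pi / 6,
                facecolor=cmap(values[k] / vmax), edgecolor="white",
            )
        )
        ax.text(x, y, f"{k + 1}\n{int(sizes[k])}", ha="center", va="center",
                fontsize=6, color="white")
    ax.set_xlim(-1, model.cols + 1)
    ax.set_ylim(-1, model.rows * np.sqrt(3) / 2 + 1)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("SOM modules (id / size); darker = more distinct neighborhood")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def trajectory_panel(trajectories: pd.DataFrame, path: str | Path) -> Path:
    """Relative mean trajectory of each cluster across the three conditions."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = [0, 1, 2]
    for _, row in trajectories.iterrows():
        ax.plot(x, [row["pre_ischemia"], row["ischemia"], row["reperfusion"]],
                marker="o", label=row["cluster"])
    ax.set_xticks(x, ["pre-ischemia", "ischemia", "reperfusion"])
    ax.set_ylabel("mean TPM relative to pre-ischemia")
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def volcano(results: pd.DataFrame, title: str, path: str | Path) -> Path:
    """log2 fold-change vs -log10 p with the significance thresholds drawn."""
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(results["p_value"], 1e-300))
    sig = results["significant"].astype(bool)
    ax.scatter(results.loc[~sig, "log2_fc"], neglog[~sig], s=4, c="grey", alpha=0.4)
    ax.scatter(results.loc[sig, "log2_fc"], neglog[sig], s=4, c="crimson", alpha=0.6)
    ax.axvline(1, ls="--", lw=0.5, c="black")
    ax.axvline(-1, ls="--", lw=0.5, c="black")
    ax.axhline(-np.log10(0.05), ls="--", lw=0.5, c="black")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
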