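"""Basic shadow plots: 2D projections of the occupied colour space."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gamut import DEFAULT_CELL_SIZE, project_2d


def shadow_plot(points: pd.DataFrame, plane: str = "yz",
                cell_size: float = DEFAULT_CELL_SIZE, path=None,
                hue: str | None = None):
    """Occupancy "shadow" of the colour cloud on the yz or yx plane.

    Cells of the locus grid are shaded by patch count; optionally points
    are overdrawn coloured by a metadata column (e.g. sex or mechanism).
    """
    grid = project_2d(points, plane, cell_size)
    fig, ax = plt.subplots(figsize=(5, 5))
    if grid:
        idx = np.array(list(grid.keys()))
        counts = np.array(list(grid.values()))
        ax.scatter(idx[:, 0] * cell_size, idx[:, 1] * cell_size,
                   c=counts, cmap="viridis", marker="s", s=14,
                   linewidths=0)
    if hue is not None and hue in points.columns:
        first, second = plane[0], plane[1]
        for label, sub in points.groupby(hue, sort=True):
            ax.scatter(sub[first], sub[second], s=4, alpha=0.5, label=str(label))
        ax.legend(fontsize=7, markerscale=2)
    ax.set_xlabel(plane[0])
    ax.set_ylabel(plane[1])
    ax.set_title(f"{plane} shadow ({len(points)} patches, "
                 f"{len(grid)} occupied 2D cells)")
    ax.set_aspect("equal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
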