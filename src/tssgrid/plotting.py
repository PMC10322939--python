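"""Rendering of density grids as heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def read_grid_tsv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a density matrix written by the CLI: first row x, first column y."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.columns.to_numpy(int), df.index.to_numpy(int), df.to_numpy(float)


def density_heatmap(path_tsv, out_png, log: bool = True, title: str | None = None) -> None:
    """Render a grid TSV as a pcolormesh heatmap (log10 color scale by default)."""
    x, y, values = read_grid_tsv(path_tsv)
    plot_vals = values.copy()
    if log:
        with np.errstate(divide="ignore", invalid="ignore"):
            plot_vals = np.log10(plot_vals)
        plot_vals[~np.isfinite(plot_vals)] = np.nan
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(x, y, np.ma.masked_invalid(plot_vals), shading="nearest", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="log10 density" if log else "density")
    ax.set_xlabel("x = z − z_U (bp)")
    ax.set_ylabel("y = z − z_D (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
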