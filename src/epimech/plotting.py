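"""Quick-look figures for vector and stress fields."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import StressField, VectorField

__all__ = ["plot_vector_field", "plot_stress_field"]


def plot_vector_field(field: VectorField, path: str | None = None,
                      title: str | None = None):
    """Magnitude heatmap with a quiver overlay; saves PNG when ``path`` given."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = (field.grid_x[0], field.grid_x[-1],
              field.grid_y[-1], field.grid_y[0])
    im = ax.imshow(field.magnitude, extent=extent, cmap="inferno")
    stride = max(1, field.vx.shape[0] // 16)
    xx, yy = np.meshgrid(field.grid_x[::stride], field.grid_y[::stride])
    ax.quiver(xx, yy, field.vx[::stride, ::stride],
              -field.vy[::stride, ::stride], color="w", scale_units="xy")
    unit = "µm" if field.role == "displacement" else "Pa"
    fig.colorbar(im, ax=ax, label=f"|{field.role}| ({unit})")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_stress_field(stress: StressField, path: str | None = None):
    """Average-normal-stress heatmap (Pa); saves PNG when ``path`` given."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = (stress.grid_x[0], stress.grid_x[-1],
              stress.grid_y[-1], stress.grid_y[0])
    s = stress.sigma_avg
    lim = np.max(np.abs(s)) or 1.0
    im = ax.imshow(s, extent=extent, cmap="RdBu_r", vmin=-lim, vmax=lim)
    fig.colorbar(im, ax=ax, label="average normal stress (Pa)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
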