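"""Readers and writers for the pipeline's on-disk formats.

Label masks and particle stacks travel as TIFF, force curves as two-column
CSV (z_um, F_N), vector fields as tidy CSV (x_um, y_um, vx, vy), and
generator ground truth as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import ForceCurve, VectorField

__all__ = [
    "write_label_mask",
    "write_stack",
    "write_force_curve",
    "read_force_curve",
    "write_vector_field",
    "read_vector_field",
    "write_json",
]


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Multi-page TIFF, pages along the leading (z or channel) axis."""
    tifffile.imwrite(str(path), np.asarray(stack))


def write_force_curve(path: str | Path, curve: ForceCurve) -> None:
    df = pd.DataFrame(dict(z_um=curve.z, F_N=curve.F))
    with open(path, "w") as fh:
        fh.write(f"# probe_radius_um={curve.probe_radius} "
                 f"poisson={curve.poisson}\n")
        df.to_csv(fh, index=False)


def read_force_curve(path: str | Path, probe_radius: float | None = None,
                     poisson: float | None = None) -> ForceCurve:
    """Two-column (z_um, F_N) CSV; probe parameters from the header comment
    unless overridden."""
    header = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    R = probe_radius if probe_radius is not None else header.get("probe_radius_um")
    nu = poisson if poisson is not None else header.get("poisson")
    if R is None or nu is None:
        raise ValueError("probe radius and Poisson ratio must come from the "
                         "file header or the caller")
    cols = list(df.columns[:2])
    return ForceCurve(z=df[cols[0]].to_numpy(), F=df[cols[1]].to_numpy(),
                      probe_radius=R, poisson=nu, meta=str(path))


def write_vector_field(path: str | Path, field: VectorField) -> None:
    field.to_dataframe().to_csv(path, index=False)


def read_vector_field(path: str | Path, role: str = "displacement"
                      ) -> VectorField:
    df = pd.read_csv(path)
    xs = np.unique(df.x_um.to_numpy())
    ys = np.unique(df.y_um.to_numpy())
    nx, ny = len(xs), len(ys)
    vx = df.vx.to_numpy().reshape(ny, nx)
    vy = df.vy.to_numpy().reshape(ny, nx)
    spacing = float(xs[1] - xs[0]) if nx > 1 else 1.0
    return VectorField(grid_x=xs, grid_y=ys, vx=vx, vy=vy,
                       spacing=spacing, role=role)


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
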