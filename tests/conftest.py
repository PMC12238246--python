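"""Shared fixtures: synthetic monolayers and hand-built tessellations."""

from __future__ import annotations

import numpy as np
import pytest

from epimech.containers import CellRecord, CellTessellation
from epimech.synthetic import SyntheticMonolayerSpec, generate_monolayer
from epimech.tessellation import analyze_mask

# closed form for a regular hexagon: p = P/sqrt(A) = 6 / (3*sqrt(3)/2)**0.5
HEX_SHAPE_INDEX = 6.0 / np.sqrt(3.0 * np.sqrt(3.0) / 2.0)


@pytest.fixture(scope="session")
def hex_monolayer():
    """Disorder-0 honeycomb: (mask, truth tessellation)."""
    spec = SyntheticMonolayerSpec(n_cells=64, disorder=0.0,
                                  image_size_px=1024, pixel_size_um=0.5,
                                  seed=11)
    return generate_monolayer(spec)


@pytest.fixture(scope="session")
def hex_analyzed(hex_monolayer):
    """Measured tessellation of the honeycomb mask (no border strip: the
    synthetic mask has no damaged frame)."""
    mask, _ = hex_monolayer
    t, trimmed = analyze_mask(mask, pixel_size_um=0.5, trim_px=0)
    return t, trimmed


@pytest.fixture(scope="session")
def disordered_monolayer():
    """Default-disorder monolayer with truth (mask, truth)."""
    spec = SyntheticMonolayerSpec(n_cells=100, disorder=0.2,
                                  image_size_px=1024, pixel_size_um=0.5,
                                  seed=5)
    return generate_monolayer(spec)


@pytest.fixture(scope="session")
def disordered_analyzed(disordered_monolayer):
    mask, _ = disordered_monolayer
    t, trimmed = analyze_mask(mask, pixel_size_um=0.5, trim_px=0)
    return t, trimmed


def make_tessellation(n_values, rescaled=None, perimeters=None,
                      neighbor_n=None):
    """Hand-built tessellation for topology-law arithmetic.

    ``n_values``: neighbor count per kept cell; ``neighbor_n``: optional list
    (per kept cell) of that cell's neighbors' own neighbor counts — realised
    through auxiliary non-kept cells.  Areas are chosen so that rescaled
    areas equal ``rescaled`` (default all 1).
    """
    n_values = list(n_values)
    k = len(n_values)
    rescaled = list(rescaled) if rescaled is not None else [1.0] * k
    perimeters = list(perimeters) if perimeters is not None else [10.0] * k
    cells: list[CellRecord] = []
    aux_label = 1000
    for i, (n, ra, p) in enumerate(zip(n_values, rescaled, perimeters)):
        nbr_counts = (neighbor_n[i] if neighbor_n is not None
                      else [6] * n)
        assert len(nbr_counts) == n
        nbrs = []
        for m in nbr_counts:
            cells.append(CellRecord(label=aux_label, area=100.0, perimeter=10.0,
                                    centroid=(0.0, 0.0),
                                    neighbor_labels=tuple(range(1, m + 1)),
                                    is_edge=False, kept=False,
                                    rescaled_area=1.0))
            nbrs.append(aux_label)
            aux_label += 1
        cells.append(CellRecord(label=i + 1, area=100.0 * ra, perimeter=p,
                                centroid=(float(i), 0.0),
                                neighbor_labels=tuple(nbrs),
                                is_edge=False, kept=True,
                                rescaled_area=ra))
    return CellTessellation(cells=cells, pixel_size_um=1.0,
                            image_shape=(64, 64), source_id="toy")
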