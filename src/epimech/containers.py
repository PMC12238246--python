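"""Shared data containers for the epithelial-mechanics pipeline.

Conventions
-----------
* Coordinates are 0-based pixel indices with a pixel-center convention;
  ``x`` is the column axis and ``y`` the row axis.  Physical coordinates
  are micrometres (``pixel_size_um`` converts).
* Forces are newtons, pressures/stresses pascals, lengths micrometres
  unless a field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "CellTessellation",
    "NuclearShape",
    "ForceCurve",
    "HertzFit",
    "VectorField",
    "StressField",
    "GelSpec",
    "ParticleStack",
    "CurveBin",
    "AboavBin",
    "TopologyCurves",
    "DistributionPDF",
    "RegionBins",
]


@dataclass
class CellRecord:
    """Morphometric record of a single cell in a monolayer tessellation."""

    label: int
    area: float                      # µm²
    perimeter: float                 # µm
    centroid: tuple[float, float]    # (x, y) in µm
    neighbor_labels: tuple[int, ...] = ()
    is_edge: bool = False
    rescaled_area: float = np.nan    # A_i / <A>, <A> = per-image mean (non-edge, pre-filter)
    elongation: float = np.nan       # major/minor axis of best-fit ellipse
    kept: bool = True                # survives the analysis-set filters

    @property
    def n_neighbors(self) -> int:
        return len(self.neighbor_labels)

    @property
    def shape_index(self) -> float:
        """p = P / sqrt(A), the dimensionless cell shape factor."""
        return self.perimeter / np.sqrt(self.area)


@dataclass
class CellTessellation:
    """A segmented monolayer: labelled cells with geometry and topology.

    ``cells`` preserves every measured cell; the *analysis set* is the
    subset with ``kept=True`` after edge flagging and outlier filtering.
    """

    cells: list[CellRecord]
    pixel_size_um: float
    image_shape: tuple[int, int]
    source_id: str = ""

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cells]
        if len(labels) != len(set(labels)):
            raise ValueError("cell labels must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def by_label(self) -> dict[int, CellRecord]:
        return {c.label: c for c in self.cells}

    @property
    def analysis_set(self) -> list[CellRecord]:
        return [c for c in self.cells if c.kept]

    @property
    def bulk_cells(self) -> list[CellRecord]:
        return [c for c in self.cells if not c.is_edge]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-cell table (one row per cell, µm units)."""
        rows = []
        for c in self.cells:
            rows.append(
                dict(
                    label=c.label,
                    A_um2=c.area,
                    P_um=c.perimeter,
                    x_um=c.centroid[0],
                    y_um=c.centroid[1],
                    n=c.n_neighbors,
                    p=c.shape_index,
                    rescaled_area=c.rescaled_area,
                    elongation=c.elongation,
                    is_edge=c.is_edge,
                    kept=c.kept,
                )
            )
        df = pd.DataFrame(rows)
        df.attrs["pixel_size_um"] = self.pixel_size_um
        df.attrs["source_id"] = self.source_id
        return df


@dataclass
class NuclearShape:
    """ImageJ-convention shape descriptors of one nucleus."""

    label: int
    area: float          # µm²
    perimeter: float     # µm
    major_axis: float    # µm
    minor_axis: float    # µm
    roundness: float     # 4A / (π major²)
    circularity: float   # 4πA / P², clipped to (0, 1]
    aspect_ratio: float  # major / minor, ≥ 1


@dataclass
class ForceCurve:
    """Approach part of a force–distance record.

    ``z`` is the piezo/displacement axis in µm, strictly monotone and
    oriented so that larger ``z`` means deeper indentation (far-from-surface
    first).  ``F`` is the measured force in newtons.
    """

    z: np.ndarray
    F: np.ndarray
    probe_radius: float      # µm
    poisson: float
    meta: str = ""
    background: tuple[float, float] | None = None  # removed line (slope N/µm, intercept N)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.z.shape != self.F.shape or self.z.ndim != 1:
            raise ValueError("z and F must be 1-D arrays of equal length")
        if len(self.z) < 20:
            raise ValueError("force curve needs at least 20 points")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")

    def copy(self) -> "ForceCurve":
        return ForceCurve(self.z.copy(), self.F.copy(), self.probe_radius,
                          self.poisson, self.meta, self.background)


@dataclass
class HertzFit:
    """Result of a Hertz-model fit to one force curve."""

    E: float                     # Pa
    contact_point: float         # µm
    r_squared: float
    background: tuple[float, float] = (0.0, 0.0)   # (slope N/µm, intercept N)
    depth_window: tuple[float, float] | None = None  # µm past contact
    converged: bool = True

    @property
    def accepted(self) -> bool:
        return self.converged and np.isfinite(self.E) and self.E > 0


@dataclass
class VectorField:
    """2-D vector data on a regular square grid.

    ``vx``/``vy`` are (ny, nx) component arrays; ``grid_x``/``grid_y`` are
    the 1-D axis coordinates in µm.  Units of the components depend on
    ``role``: µm for displacement, Pa for traction.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    spacing: float           # µm
    role: str = "displacement"   # displacement | traction

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy shapes differ")
        if self.vx.shape != (len(self.grid_y), len(self.grid_x)):
            raise ValueError("component arrays must be (ny, nx)")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def net_force(self, cell_area: float | None = None) -> tuple[float, float]:
        """Sum of vectors × grid-cell area (meaningful for traction fields)."""
        a = self.spacing ** 2 if cell_area is None else cell_area
        return float(self.vx.sum() * a), float(self.vy.sum() * a)

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            dict(x_um=xx.ravel(), y_um=yy.ravel(),
                 vx=self.vx.ravel(), vy=self.vy.ravel())
        )


@dataclass
class StressField:
    """In-plane monolayer stress on a regular grid (plane-stress tensor, Pa).

    ``sigma_avg`` is the average normal stress (σxx + σyy)/2 per point — the
    scalar monolayer-stress-microscopy readout; the full tensor components
    are kept for diagnostics.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    spacing: float

    @property
    def sigma_avg(self) -> np.ndarray:
        return 0.5 * (self.sxx + self.syy)

    def summary(self) -> dict[str, float]:
        s = self.sigma_avg
        return dict(
            mean_abs_normal_stress=float(np.mean(np.abs(s))),
            mean_signed_normal_stress=float(np.mean(s)),
            max_normal_stress=float(np.max(s)),
        )


@dataclass
class GelSpec:
    """Elastic substrate and monolayer geometry for traction/stress work."""

    E_gel: float                  # Pa
    nu_gel: float = 0.5           # incompressible polyacrylamide by default
    monolayer_height: float = 10.0  # µm, from live F-actin z-profiles

    def __post_init__(self) -> None:
        if self.E_gel <= 0:
            raise ValueError("E_gel must be positive")
        if not 0 < self.nu_gel <= 0.5:
            raise ValueError("nu_gel must lie in (0, 0.5]")
        if self.monolayer_height <= 0:
            raise ValueError("monolayer height must be positive")


@dataclass
class ParticleStack:
    """3-D labelled particles plus the apical reference surface.

    ``particle_labels`` is a (nz, ny, nx) integer stack; ``reference_surface``
    a (ny, nx) height map z(x, y) in µm (the apical F-actin surface); a
    particle below the surface is internalized, above it apically bound.
    """

    particle_labels: np.ndarray
    reference_surface: np.ndarray
    voxel_size: tuple[float, float, float]   # (z, y, x) µm

    def __post_init__(self) -> None:
        self.particle_labels = np.asarray(self.particle_labels)
        if self.particle_labels.ndim != 3:
            raise ValueError("particle_labels must be 3-D (z, y, x)")
        if self.reference_surface.shape != self.particle_labels.shape[1:]:
            raise ValueError("reference surface must match stack (y, x) shape")


@dataclass
class CurveBin:
    mean: float
    sem: float      # NaN when count < 2
    count: int


@dataclass
class AboavBin:
    mu_m: float     # mean neighbor-count among neighbors of n-sided cells
    b: float        # (n − 6)·µ_m(n) − σ_n²
    count: int


@dataclass
class TopologyCurves:
    """Binned monolayer-topology statistics of one sample (image or animal)."""

    lewis: dict[int, CurveBin] = field(default_factory=dict)
    desch: dict[int, CurveBin] = field(default_factory=dict)
    aboav: dict[int, AboavBin] = field(default_factory=dict)
    sigma2: float = np.nan       # population variance of the neighbor-count distribution
    n_cells: int = 0
    sample_id: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for n, b in sorted(self.lewis.items()):
            rows.append(dict(curve="lewis", n=n, value=b.mean, sem=b.sem,
                             count=b.count, sample_id=self.sample_id))
        for n, b in sorted(self.desch.items()):
            rows.append(dict(curve="desch", n=n, value=b.mean, sem=b.sem,
                             count=b.count, sample_id=self.sample_id))
        for n, b in sorted(self.aboav.items()):
            rows.append(dict(curve="aboav_b", n=n, value=b.b, sem=np.nan,
                             count=b.count, sample_id=self.sample_id))
        return pd.DataFrame(rows)


@dataclass
class DistributionPDF:
    """Normalized histogram density with its interpolated mode."""

    bin_centers: np.ndarray
    density: np.ndarray
    bin_width: float | np.ndarray
    mode: float

    def integral(self) -> float:
        return float(np.sum(self.density * self.bin_width))


@dataclass(frozen=True)
class RegionBins:
    """Retinal eccentricity bins (distance from the optic nerve, µm)."""

    centre: tuple[float, float] = (300.0, 1200.0)
    mid_periphery: tuple[float, float] = (1200.0, 2000.0)
    far_periphery: tuple[float, float] = (2000.0, 3000.0)

    def __post_init__(self) -> None:
        seq = [self.centre, self.mid_periphery, self.far_periphery]
        for (a, b), (c, d) in zip(seq, seq[1:]):
            if b != c:
                raise ValueError("region bins must be contiguous")
        if any(a >= b for a, b in seq):
            raise ValueError("region bins must be increasing intervals")
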