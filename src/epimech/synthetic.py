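"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's raw data so that the tessellation,
indentation, traction and functional modules can be exercised end-to-end
without microscopy: a Voronoi monolayer of tunable disorder, Hertzian
force–distance curves with a linear background, bead-displacement fields
forward-computed from known traction patterns, and 3-D particle stacks
with a known internalized fraction.  All generators are deterministic for
a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .containers import CellRecord, CellTessellation, ForceCurve, ParticleStack, VectorField
from .elastic import forward_displacement
from .hertz import hertz_force

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticMonolayerSpec",
    "SyntheticForceCurveSpec",
    "SyntheticTractionSpec",
    "SyntheticPOSSpec",
    "generate_monolayer",
    "generate_force_curve",
    "generate_traction_scene",
    "generate_equilibrated_traction",
    "generate_pos_stack",
    "render_bead_images",
]


# ---------------------------------------------------------------- monolayer

@dataclass(frozen=True)
class SyntheticMonolayerSpec:
    """Voronoi monolayer of a jittered hexagonal lattice.

    ``disorder`` is the jitter standard deviation relative to the lattice
    pitch: 0 gives a perfect honeycomb, values near 1 a fully disordered
    tessellation.  The default 0.2 puts the mean cell shape index near 3.9,
    the middle of the range epithelial monolayers such as the RPE span
    between ordered (≈3.8) and disordered (≈4.0) states.  ``n_cells`` sets
    the lattice density so that roughly that many cells tile the image
    (cells straddling the border add a few more).
    """

    n_cells: int = 100
    disorder: float = 0.2
    image_size_px: int = 512
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        if not 0.0 <= self.disorder <= 1.0:
            raise ValueError("disorder must lie in [0, 1]")
        if self.image_size_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image size and pixel size must be positive")


def _hex_lattice(size: float, pitch: float, margin: float) -> np.ndarray:
    """Offset-row triangular lattice covering [-margin, size+margin]²."""
    row_gap = pitch * np.sqrt(3.0) / 2.0
    ys = np.arange(-margin, size + margin, row_gap)
    pts = []
    for j, y in enumerate(ys):
        off = 0.5 * pitch if j % 2 else 0.0
        xs = np.arange(-margin + off, size + margin, pitch)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(pts)


def generate_monolayer(spec: SyntheticMonolayerSpec,
                       _retry: int = 0) -> tuple[np.ndarray, CellTessellation]:
    """Render a labelled monolayer mask and its exact ground-truth tessellation.

    Returns ``(label_mask, truth)``: the mask carries one positive integer
    per cell with 0 on the 1-px boundaries; the truth tessellation holds the
    exact polygon area, perimeter, centroid and neighbor list of each cell
    whose Voronoi region intersects the image.
    """
    size = float(spec.image_size_px)
    # hexagonal Voronoi cell of a triangular lattice with pitch a has area (√3/2)a²
    pitch = np.sqrt(2.0 * size * size / (np.sqrt(3.0) * spec.n_cells))
    margin = 5.0 * pitch
    pts = _hex_lattice(size, pitch, margin)

    rng = np.random.default_rng(spec.seed + 7919 * _retry)
    pts = pts + rng.normal(0.0, spec.disorder * pitch, size=pts.shape)

    # coincident generators make the tessellation degenerate → perturbed retry
    tree = cKDTree(pts)
    dd, _ = tree.query(pts, k=2)
    if np.min(dd[:, 1]) < 1e-9 * pitch:
        if _retry >= 5:
            raise RuntimeError("could not generate a non-degenerate tessellation")
        log.warning("degenerate tessellation (coincident points); retrying "
                    "with perturbed seed")
        return generate_monolayer(spec, _retry=_retry + 1)

    vor = Voronoi(pts)
    frame = box(-0.5, -0.5, size - 0.5, size - 0.5)

    polys: dict[int, Polygon] = {}
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue  # unbounded region: generator lies in the outer margin
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(frame)
        if clipped.is_empty or clipped.area <= 0:
            continue
        polys[i] = clipped

    labels = {i: lab for lab, i in enumerate(sorted(polys), start=1)}

    # neighbors: Voronoi ridge partners whose clipped polygons share an edge of
    # at least one pixel — sub-pixel contacts cannot exist in the rendered mask
    neighbor_sets: dict[int, set[int]] = {i: set() for i in polys}
    for i, j in vor.ridge_points:
        if i in polys and j in polys:
            shared = polys[i].intersection(polys[j])
            if shared.length >= 1.0:
                neighbor_sets[i].add(j)
                neighbor_sets[j].add(i)

    px = spec.pixel_size_um
    cells = []
    for i in sorted(polys):
        poly = polys[i]
        full_region = Polygon(vor.vertices[vor.regions[vor.point_region[i]]])
        is_edge = poly.area < full_region.area - 1e-9  # clipped by the frame
        cells.append(CellRecord(
            label=labels[i],
            area=poly.area * px * px,
            perimeter=poly.exterior.length * px,
            centroid=(poly.centroid.x * px, poly.centroid.y * px),
            neighbor_labels=tuple(sorted(labels[j] for j in neighbor_sets[i])),
            is_edge=is_edge,
        ))
    truth = CellTessellation(cells=cells, pixel_size_um=px,
                             image_shape=(spec.image_size_px, spec.image_size_px),
                             source_id=f"synthetic(seed={spec.seed})")

    # raster: nearest generator per pixel center, boundary pixels zeroed
    coords = np.arange(spec.image_size_px, dtype=float)
    xx, yy = np.meshgrid(coords, coords)
    _, owner = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
    owner = owner.reshape(spec.image_size_px, spec.image_size_px)
    lut = np.zeros(len(pts) + 1, dtype=np.uint16)
    for i, lab in labels.items():
        lut[i] = lab
    mask = lut[owner]

    # one-sided 1-px boundary, so mutually dilated neighbors still touch
    boundary = np.zeros_like(mask, dtype=bool)
    boundary[:-1, :] |= owner[:-1, :] != owner[1:, :]
    boundary[:, :-1] |= owner[:, :-1] != owner[:, 1:]
    mask[boundary] = 0
    return mask, truth


# --------------------------------------------------------------- force curve

@dataclass(frozen=True)
class SyntheticForceCurveSpec:
    """Hertzian approach curve with a linear background and Gaussian noise.

    Defaults emulate the cell-monolayer nanoindentation protocol: a soft
    monolayer (1.5 kPa), a 10 µm spherical probe and an incompressible
    sample (ν = 0.5).
    """

    E_true: float = 1500.0          # Pa
    contact_point: float = 2.0      # µm along the z axis
    probe_radius: float = 10.0      # µm
    poisson: float = 0.5
    background_slope: float = 0.0   # N per µm of z
    noise_sd: float = 0.0           # N
    n_points: int = 400
    z_range: float = 6.0            # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true <= 0 or self.probe_radius <= 0:
            raise ValueError("E_true and probe_radius must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")
        if self.n_points < 20 or self.z_range <= 0:
            raise ValueError("need ≥20 points over a positive z range")


def generate_force_curve(spec: SyntheticForceCurveSpec) -> ForceCurve:
    """Noiseless-Hertz-plus-background force curve; F = 0 before contact."""
    z = np.linspace(0.0, spec.z_range, spec.n_points)
    delta = np.clip(z - spec.contact_point, 0.0, None)
    F = hertz_force(delta, spec.E_true, spec.probe_radius, spec.poisson)
    F = F + spec.background_slope * z
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        F = F + rng.normal(0.0, spec.noise_sd, size=F.shape)
    return ForceCurve(z=z, F=F, probe_radius=spec.probe_radius,
                      poisson=spec.poisson,
                      meta=f"synthetic(E={spec.E_true} Pa, seed={spec.seed})")


# ----------------------------------------------------------------- traction

_PATTERNS = ("gaussian_dipole", "uniform_disc", "zero")


@dataclass(frozen=True)
class SyntheticTractionSpec:
    """Balanced traction pattern on an elastic gel and its bead displacement.

    Defaults match the soft-substrate condition: 170 Pa peak traction on a
    4 kPa polyacrylamide gel.  Only force-balanced patterns are offered —
    the DC component of an unbalanced field is invisible to the inversion.
    """

    pattern: str = "gaussian_dipole"
    peak_traction: float = 170.0    # Pa
    gel_E: float = 4000.0           # Pa
    gel_poisson: float = 0.5
    grid_n: int = 64
    grid_spacing_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(
                f"unknown or unbalanced pattern {self.pattern!r}; "
                f"choose one of {_PATTERNS} (net force must vanish)")
        if self.gel_E <= 0 or self.grid_n < 4 or self.grid_spacing_um <= 0:
            raise ValueError("invalid gel or grid parameters")


def _traction_pattern(spec: SyntheticTractionSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.grid_n
    h = spec.grid_spacing_um
    c = (n - 1) / 2.0 * h
    x = np.arange(n) * h
    xx, yy = np.meshgrid(x, x)
    tx = np.zeros((n, n))
    ty = np.zeros((n, n))
    if spec.pattern == "zero":
        return tx, ty
    if spec.pattern == "gaussian_dipole":
        # two opposite-sign lobes along x, contractile (pointing inward)
        sep = n * h / 4.0
        sigma = n * h / 12.0
        r2a = (xx - (c - sep)) ** 2 + (yy - c) ** 2
        r2b = (xx - (c + sep)) ** 2 + (yy - c) ** 2
        tx = spec.peak_traction * (np.exp(-r2a / (2 * sigma ** 2))
                                   - np.exp(-r2b / (2 * sigma ** 2)))
    elif spec.pattern == "uniform_disc":
        # radially inward pull of uniform magnitude inside a disc (contractile island)
        rad = n * h / 4.0
        dx, dy = xx - c, yy - c
        r = np.hypot(dx, dy)
        inside = (r > 0) & (r <= rad)
        tx[inside] = -spec.peak_traction * dx[inside] / r[inside]
        ty[inside] = -spec.peak_traction * dy[inside] / r[inside]
    # raster symmetry leaves a ~1e-13 residual; remove it exactly
    tx -= tx.mean()
    ty -= ty.mean()
    return tx, ty


def generate_traction_scene(spec: SyntheticTractionSpec
                            ) -> tuple[VectorField, VectorField]:
    """Ground-truth traction field and the bead displacement it produces."""
    tx, ty = _traction_pattern(spec)
    ux, uy = forward_displacement(tx, ty, spec.grid_spacing_um,
                                  spec.gel_E, spec.gel_poisson)
    x = np.arange(spec.grid_n) * spec.grid_spacing_um
    truth = VectorField(grid_x=x, grid_y=x, vx=tx, vy=ty,
                        spacing=spec.grid_spacing_um, role="traction")
    disp = VectorField(grid_x=x, grid_y=x, vx=ux, vy=uy,
                       spacing=spec.grid_spacing_um, role="displacement")
    return truth, disp


def generate_equilibrated_traction(grid_n: int = 48,
                                   grid_spacing_um: float = 4.0,
                                   monolayer_height_um: float = 10.0,
                                   smoothness_px: float = 4.0,
                                   seed: int = 0) -> VectorField:
    """Random traction field of a monolayer in mechanical equilibrium.

    The field is manufactured as h·div(σ*) from a smooth, compactly
    supported random test stress σ*, then projected so that the discrete net
    force **and** all first moments Σ xᵢ Tⱼ vanish.  Because the mean
    in-plane stress of a force-balanced sheet equals the first moment of the
    traction divided by h, such a field has zero mean signed stress while
    carrying O(1) local stresses — the regime monolayer stress microscopy
    reports for confluent epithelia.
    """
    n, s, h = grid_n, grid_spacing_um, monolayer_height_um
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    x = np.arange(n) * s
    xx, yy = np.meshgrid(x, x)
    c = x[-1] / 2.0
    w = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * (x[-1] / 6.0) ** 2))

    def component():
        a = gaussian_filter(w * rng.normal(size=(n, n)), smoothness_px)
        return a - w * (a.sum() / w.sum())   # zero-integral test stress

    sxx, syy, sxy = component(), component(), component()
    tx = h * (np.gradient(sxx, s, axis=1) + np.gradient(sxy, s, axis=0))
    ty = h * (np.gradient(sxy, s, axis=1) + np.gradient(syy, s, axis=0))
    tx -= tx.mean()
    ty -= ty.mean()
    # remove residual discrete first moments with compact gradient modes
    wx = np.gradient(w, s, axis=1)
    wy = np.gradient(w, s, axis=0)
    wx -= wx.mean()
    wy -= wy.mean()
    A = np.array([[np.sum(xx * wx), np.sum(xx * wy)],
                  [np.sum(yy * wx), np.sum(yy * wy)]])
    for _ in range(3):
        ab = np.linalg.solve(A, [np.sum(xx * tx), np.sum(yy * tx)])
        cd = np.linalg.solve(A, [np.sum(xx * ty), np.sum(yy * ty)])
        tx = tx - ab[0] * wx - ab[1] * wy
        ty = ty - cd[0] * wx - cd[1] * wy
        tx -= tx.mean()
        ty -= ty.mean()
    return VectorField(grid_x=x, grid_y=x, vx=tx, vy=ty, spacing=s,
                       role="traction")


def render_bead_images(displacement, image_size_px: int = 512,
                       n_beads: int = 3000, bead_sigma_px: float = 1.2,
                       pixel_size_um: float = 1.0, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Render a (reference, deformed) fluorescent-bead image pair.

    ``displacement`` is either a callable ``(x_um, y_um) -> (ux_um, uy_um)``
    or a :class:`VectorField`; beads are Gaussian spots at uniform random
    positions, shifted by the field in the deformed image (tense gel).
    """
    if isinstance(displacement, VectorField):
        field = displacement

        def disp_fn(x, y):
            ix = np.clip(np.searchsorted(field.grid_x, x) - 1, 0,
                         len(field.grid_x) - 1)
            iy = np.clip(np.searchsorted(field.grid_y, y) - 1, 0,
                         len(field.grid_y) - 1)
            return field.vx[iy, ix], field.vy[iy, ix]
    else:
        disp_fn = displacement

    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, image_size_px, size=(n_beads, 2))  # (x, y) px

    def render(points):
        img = np.zeros((image_size_px, image_size_px))
        r = int(np.ceil(4 * bead_sigma_px))
        for x, y in points:
            xi, yi = int(round(x)), int(round(y))
            xs = np.arange(max(xi - r, 0), min(xi + r + 1, image_size_px))
            ys = np.arange(max(yi - r, 0), min(yi + r + 1, image_size_px))
            if len(xs) == 0 or len(ys) == 0:
                continue
            gx = np.exp(-((xs - x) ** 2) / (2 * bead_sigma_px ** 2))
            gy = np.exp(-((ys - y) ** 2) / (2 * bead_sigma_px ** 2))
            img[np.ix_(ys, xs)] += np.outer(gy, gx)
        return img

    ref = render(pos)
    ux, uy = disp_fn(pos[:, 0] * pixel_size_um, pos[:, 1] * pixel_size_um)
    moved = pos + np.column_stack([np.asarray(ux), np.asarray(uy)]) / pixel_size_um
    deformed = render(moved)
    return ref, deformed


# -------------------------------------------------------------- POS stacks

@dataclass(frozen=True)
class SyntheticPOSSpec:
    """3-D particle stack with a known internalized fraction.

    ``round(n_particles × fraction_internalized)`` equal-size spherical
    particles are placed with centroids strictly below the apical reference
    surface, the rest strictly above it.
    """

    n_particles: int = 60
    fraction_internalized: float = 0.5
    surface_z_um: float = 8.0
    stack_shape: tuple[int, int, int] = (40, 256, 256)   # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.5, 0.25, 0.25)  # µm (z, y, x)
    particle_radius_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_internalized <= 1.0:
            raise ValueError("fraction_internalized must lie in [0, 1]")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")


def _ball_offsets(radius_um: float, voxel: tuple[float, float, float]
                  ) -> np.ndarray:
    vz, vy, vx = voxel
    nz = int(np.floor(radius_um / vz))
    ny = int(np.floor(radius_um / vy))
    nx = int(np.floor(radius_um / vx))
    dz, dy, dx = np.meshgrid(np.arange(-nz, nz + 1), np.arange(-ny, ny + 1),
                             np.arange(-nx, nx + 1), indexing="ij")
    keep = (dz * vz) ** 2 + (dy * vy) ** 2 + (dx * vx) ** 2 <= radius_um ** 2
    return np.column_stack([dz[keep], dy[keep], dx[keep]])


def generate_pos_stack(spec: SyntheticPOSSpec, max_retries: int = 1000
                       ) -> ParticleStack:
    """Place non-overlapping equal-size particles around a flat apical surface."""
    nz, ny, nx = spec.stack_shape
    vz, vy, vx = spec.voxel_size
    offs = _ball_offsets(spec.particle_radius_um, spec.voxel_size)
    rz = int(np.floor(spec.particle_radius_um / vz))
    ry = int(np.floor(spec.particle_radius_um / vy))
    rx = int(np.floor(spec.particle_radius_um / vx))

    n_in = int(round(spec.n_particles * spec.fraction_internalized))
    surface_idx = spec.surface_z_um / vz

    # admissible integer z-centres: sphere inside the stack, centroid strictly
    # below (internalized) or above (bound) the reference surface
    z_below = [z for z in range(rz, nz - rz) if z < surface_idx - 1e-9]
    z_above = [z for z in range(rz, nz - rz) if z > surface_idx + 1e-9]
    if n_in > 0 and not z_below:
        raise ValueError("no room below the reference surface")
    if spec.n_particles - n_in > 0 and not z_above:
        raise ValueError("no room above the reference surface")

    rng = np.random.default_rng(spec.seed)
    stack = np.zeros(spec.stack_shape, dtype=np.uint16)
    occupied = np.zeros(spec.stack_shape, dtype=bool)
    for lab in range(1, spec.n_particles + 1):
        internal = lab <= n_in
        zs = z_below if internal else z_above
        for attempt in range(max_retries):
            cz = zs[rng.integers(len(zs))]
            cy = int(rng.integers(ry, ny - ry))
            cx = int(rng.integers(rx, nx - rx))
            vox = offs + (cz, cy, cx)
            idx = tuple(vox.T)
            if not occupied[idx].any():
                stack[idx] = lab
                occupied[idx] = True
                break
        else:
            raise RuntimeError(
                f"could not place particle {lab} without overlap after "
                f"{max_retries} retries; reduce n_particles or radius")

    surface = np.full((ny, nx), spec.surface_z_um)
    return ParticleStack(particle_labels=stack, reference_surface=surface,
                         voxel_size=spec.voxel_size)
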