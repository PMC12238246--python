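"""From segmentation masks to a filtered cell tessellation.

The preprocessing mirrors the monolayer-morphometry pipeline used on
cellpose output: a 15-px border strip (poor mask definition at the frame),
a σ = 2 px Gaussian to repair pixel connectivity of skeletonized boundaries,
per-cell area/perimeter/centroid in µm, a dilation-based region-adjacency
graph, a 30-px bulk criterion for edge cells, and removal of cells with
rescaled area > 2 or more than 10 neighbors from the analysis set.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure

from .containers import CellRecord, CellTessellation, NuclearShape

log = logging.getLogger(__name__)

__all__ = [
    "load_label_mask",
    "analyze_mask",
    "tessellation_from_mask",
    "build_adjacency",
    "flag_edge_cells",
    "filter_cells",
    "nuclear_shape_metrics",
    "label_perimeter",
]

BORDER_STRIP_PX = 15
SKELETON_SIGMA_PX = 2.0


# ------------------------------------------------------------- measurement

def label_polygon(region_mask: np.ndarray, smooth_sigma: float = 1.0,
                  simplify_tol: float = 0.75) -> np.ndarray:
    """Sub-pixel boundary polygon of a binary region, (N, 2) in (row, col).

    The region indicator is lightly smoothed and the 0.5 iso-contour
    extracted by marching squares, then simplified with Douglas–Peucker so
    that rasterization staircase does not inflate the length.  The smoothed
    contour sits roughly half a pixel outside the support, i.e. midway
    through the 1-px background gap skeletonization leaves between cells,
    which makes polygon area and perimeter nearly unbiased estimates of the
    underlying cell geometry (pixel counts under-, pixel-chain perimeters
    over-estimate).
    """
    padded = np.pad(region_mask.astype(float), 3)
    if smooth_sigma > 0:
        padded = ndi.gaussian_filter(padded, smooth_sigma)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    contour = max(contours, key=len)
    if simplify_tol > 0:
        contour = measure.approximate_polygon(contour, tolerance=simplify_tol)
    return contour - 3.0  # undo the padding offset


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed (row, col) contour, px²."""
    if len(contour) < 3:
        return 0.0
    y, x = contour[:, 0], contour[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def label_perimeter(region_mask: np.ndarray, smooth_sigma: float = 1.0,
                    simplify_tol: float = 0.75) -> float:
    """Perimeter (px) of a binary region from its sub-pixel boundary polygon."""
    contour = label_polygon(region_mask, smooth_sigma, simplify_tol)
    if len(contour) < 2:
        return 0.0
    d = np.diff(contour, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def tessellation_from_mask(mask: np.ndarray, pixel_size_um: float,
                           source_id: str = "",
                           trim_px: int = BORDER_STRIP_PX) -> CellTessellation:
    """Measure every labelled cell of a 2-D integer mask (after border strip)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be integer-typed")
    if trim_px > 0:
        if 2 * trim_px >= min(mask.shape):
            raise ValueError("image smaller than twice the border strip")
        mask = mask[trim_px:-trim_px, trim_px:-trim_px]
    if mask.max() == 0:
        raise ValueError("empty mask: no labelled cells")

    px = pixel_size_um
    cells = []
    for prop in measure.regionprops(mask):
        region = mask[prop.slice] == prop.label
        contour = label_polygon(region)
        area_px = polygon_area(contour)
        if area_px == 0:
            area_px = float(prop.area)  # degenerate sliver: fall back to pixel count
        d = np.diff(contour, axis=0)
        perim_px = float(np.sum(np.hypot(d[:, 0], d[:, 1]))) if len(contour) > 1 \
            else 4.0 * np.sqrt(prop.area)
        cy, cx = prop.centroid  # (row, col) within full mask
        elong = (prop.axis_major_length / prop.axis_minor_length
                 if prop.axis_minor_length > 0 else np.nan)
        cells.append(CellRecord(
            label=int(prop.label),
            area=area_px * px * px,
            perimeter=perim_px * px,
            centroid=(cx * px, cy * px),
            elongation=elong,
        ))
    return CellTessellation(cells=cells, pixel_size_um=px,
                            image_shape=mask.shape, source_id=source_id)


def load_label_mask(path: str | Path, pixel_size_um: float,
                    skeleton: bool = False,
                    trim_px: int = BORDER_STRIP_PX,
                    skeleton_threshold: float = 0.1) -> CellTessellation:
    """Read a label mask (or skeletonized boundary image) into a tessellation.

    Label TIFFs are used as-is.  A skeleton image is Gaussian-filtered
    (σ = 2 px) to repair broken boundary connectivity, thresholded, and the
    enclosed regions labelled by 4-connected components of the non-boundary
    space.  In both cases a ``trim_px`` border is stripped first.
    """
    img = tifffile.imread(str(path))
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D image")
    if skeleton:
        mask = _label_from_skeleton(img, skeleton_threshold)
    else:
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError("label mask must be integer-typed "
                             "(pass skeleton=True for boundary images)")
        mask = img
    return tessellation_from_mask(mask, pixel_size_um,
                                  source_id=str(path), trim_px=trim_px)


def _label_from_skeleton(img: np.ndarray, threshold: float) -> np.ndarray:
    skel = (img > 0).astype(float)
    blurred = ndi.gaussian_filter(skel, SKELETON_SIGMA_PX)
    boundary = blurred > threshold
    labels, _ = ndi.label(~boundary, structure=np.array([[0, 1, 0],
                                                         [1, 1, 1],
                                                         [0, 1, 0]]))
    return labels


# --------------------------------------------------------------- topology

def build_adjacency(t: CellTessellation, mask: np.ndarray,
                    reach: int = 2) -> CellTessellation:
    """Attach neighbor lists: two cells are adjacent when their supports come
    within ``reach`` pixels (Chebyshev) of each other.

    ``reach=2`` equals mutually radius-1-dilated supports touching (8-conn
    structuring element), which bridges the 1–2 px background boundary left
    between cells by skeletonization.  The relation is symmetric by
    construction.  ``mask`` must be the same (trimmed) label image the
    tessellation was measured from.
    """
    mask = np.asarray(mask)
    if mask.shape != t.image_shape:
        raise ValueError("mask shape does not match tessellation image_shape")
    pairs: set[tuple[int, int]] = set()
    offsets = [(dy, dx) for dy in range(-reach, reach + 1)
               for dx in range(-reach, reach + 1)
               if (dy, dx) != (0, 0)]
    for dy, dx in offsets:
        ys = slice(max(dy, 0), mask.shape[0] + min(dy, 0))
        yd = slice(max(-dy, 0), mask.shape[0] + min(-dy, 0))
        xs = slice(max(dx, 0), mask.shape[1] + min(dx, 0))
        xd = slice(max(-dx, 0), mask.shape[1] + min(-dx, 0))
        a = mask[ys, xs]
        b = mask[yd, xd]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            ab = np.unique(np.stack([a[sel], b[sel]], axis=1), axis=0)
            for u, v in ab:
                pairs.add((int(min(u, v)), int(max(u, v))))
    neigh: dict[int, set[int]] = {c.label: set() for c in t.cells}
    for u, v in pairs:
        if u in neigh and v in neigh:
            neigh[u].add(v)
            neigh[v].add(u)
    for c in t.cells:
        c.neighbor_labels = tuple(sorted(neigh[c.label]))
    return t


def flag_edge_cells(t: CellTessellation, mask: np.ndarray,
                    bulk_threshold_px: float = 30.0) -> CellTessellation:
    """Flag border cells: the neighborhood of each cell is reconstructed and
    the cell is *bulk* only when the mean position of its neighbors lies
    within ``bulk_threshold_px`` of the cell itself (a border cell is pulled
    off-centre by its one-sided neighborhood), and the cell does not touch
    the image frame.  Cells with no neighbors are edge by definition.
    """
    mask = np.asarray(mask)
    touching = set()
    for edge in (mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]):
        touching.update(np.unique(edge[edge > 0]).tolist())
    by_label = t.by_label()
    px = t.pixel_size_um
    for c in t.cells:
        if c.n_neighbors == 0 or c.label in touching:
            c.is_edge = True
            continue
        nbrs = np.array([by_label[l].centroid for l in c.neighbor_labels
                         if l in by_label])
        mean_pos = nbrs.mean(axis=0)
        dist_px = np.hypot(*(mean_pos - np.array(c.centroid))) / px
        c.is_edge = bool(dist_px >= bulk_threshold_px)
    return t


def filter_cells(t: CellTessellation, max_rescaled_area: float = 2.0,
                 max_neighbors: int = 10) -> CellTessellation:
    """Compute rescaled areas and mark the analysis set.

    ⟨A⟩ is the per-image mean area over non-edge cells before any filtering;
    the analysis set then excludes edge cells, cells with rescaled area
    above ``max_rescaled_area`` (unnaturally large, i.e. merged segmentation)
    and cells with more than ``max_neighbors`` neighbors.  Neighbor counts of
    the remaining cells are *not* recomputed after removal.
    """
    bulk = [c for c in t.cells if not c.is_edge]
    if not bulk:
        raise ValueError("no bulk cells: flag_edge_cells first / image too small")
    mean_area = float(np.mean([c.area for c in bulk]))
    for c in t.cells:
        c.rescaled_area = c.area / mean_area
        c.kept = (not c.is_edge
                  and c.rescaled_area <= max_rescaled_area
                  and c.n_neighbors <= max_neighbors)
    return t


def analyze_mask(mask: np.ndarray, pixel_size_um: float, source_id: str = "",
                 trim_px: int = BORDER_STRIP_PX,
                 bulk_threshold_px: float = 30.0,
                 max_rescaled_area: float = 2.0,
                 max_neighbors: int = 10) -> tuple[CellTessellation, np.ndarray]:
    """Full mask → filtered tessellation pipeline.

    Convenience wrapper chaining border strip, per-cell measurement,
    adjacency, edge flagging (on trimmed coordinates) and analysis-set
    filtering.  Returns the tessellation together with the trimmed mask the
    measurements refer to.
    """
    t = tessellation_from_mask(mask, pixel_size_um, source_id=source_id,
                               trim_px=trim_px)
    trimmed = (np.asarray(mask)[trim_px:-trim_px, trim_px:-trim_px]
               if trim_px > 0 else np.asarray(mask))
    build_adjacency(t, trimmed)
    flag_edge_cells(t, trimmed, bulk_threshold_px=bulk_threshold_px)
    filter_cells(t, max_rescaled_area=max_rescaled_area,
                 max_neighbors=max_neighbors)
    return t, trimmed


# ----------------------------------------------------------------- nuclei

def nuclear_shape_metrics(nuclear_mask: np.ndarray,
                          pixel_size_um: float = 1.0) -> list[NuclearShape]:
    """ImageJ-style descriptors per nucleus of a 2-D label mask.

    circularity = 4πA/P² (clipped to 1), roundness = 4A/(π·major²),
    aspect ratio = major/minor of the best-fit ellipse.  Degenerate
    (≤ 4 px or zero minor axis) regions are skipped with a log entry.
    """
    nuclear_mask = np.asarray(nuclear_mask)
    if nuclear_mask.ndim != 2:
        raise ValueError("nuclear mask must be 2-D")
    out = []
    px = pixel_size_um
    for prop in measure.regionprops(nuclear_mask):
        if prop.area <= 4 or prop.axis_minor_length == 0:
            log.info("skipping degenerate nucleus label=%d (area=%d px)",
                     prop.label, prop.area)
            continue
        region = nuclear_mask[prop.slice] == prop.label
        # solid regions (no skeleton gap): lighter smoothing preserves corners
        P = label_perimeter(region, smooth_sigma=0.5, simplify_tol=0.3) * px
        A = prop.area * px * px
        major = prop.axis_major_length * px
        minor = prop.axis_minor_length * px
        out.append(NuclearShape(
            label=int(prop.label),
            area=A, perimeter=P,
            major_axis=major, minor_axis=minor,
            roundness=4.0 * A / (np.pi * major ** 2),
            circularity=min(4.0 * np.pi * A / P ** 2, 1.0),
            aspect_ratio=major / minor,
        ))
    return out
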