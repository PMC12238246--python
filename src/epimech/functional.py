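"""Image-derived functional metrics.

* Photoreceptor-outer-segment (POS) phagocytosis efficiency: projected area
  of internalized particles over total projected particle area, with
  internalization decided against the apical F-actin reference surface.
* EdU/DAPI proliferation ratio in a central region of interest.
* Radial ECM-intensity quantification: eccentricity region binning and
  per-eye maximum normalization.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw, measure

from .containers import ParticleStack, RegionBins

__all__ = [
    "phagocytosis_efficiency",
    "proliferation_ratio",
    "region_of_distance",
    "normalize_per_eye",
    "roi_mean_intensity",
]


def phagocytosis_efficiency(stack: ParticleStack,
                            rule: str = "centroid",
                            min_particle_voxels: int = 0
                            ) -> tuple[float, pd.DataFrame]:
    """POS internalization efficiency from a labelled particle stack.

    A particle is internalized when its volume centroid lies below the
    apical reference surface at its (x, y) position (``rule="centroid"``) or
    when its entire extent does (``rule="entire"``).  Efficiency is the sum
    of projected (xy) areas of internalized particles divided by the total
    projected area of all particles — each particle's xy support counted
    once, overlaps resolved per-particle.

    Returns ``(efficiency, table)`` with one row per particle.
    """
    labels = stack.particle_labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no particles in stack: efficiency undefined")
    vz, vy, vx = stack.voxel_size
    pix_area = vy * vx
    rows = []
    for lab in ids:
        zz, yy, xx = np.nonzero(labels == lab)
        if len(zz) < max(min_particle_voxels, 1):
            continue
        proj_area = len({(y, x) for y, x in zip(yy.tolist(), xx.tolist())}) * pix_area
        cz = zz.mean() * vz
        cy = int(round(yy.mean()))
        cx = int(round(xx.mean()))
        surf = float(stack.reference_surface[cy, cx])
        if rule == "centroid":
            internal = cz < surf
        elif rule == "entire":
            internal = bool(np.all(zz * vz < surf))
        else:
            raise ValueError("rule must be 'centroid' or 'entire'")
        rows.append(dict(label=int(lab), centroid_z_um=float(cz),
                         surface_z_um=surf, projected_area_um2=proj_area,
                         internalized=internal))
    table = pd.DataFrame(rows)
    total = table.projected_area_um2.sum()
    if total == 0:
        raise ValueError("zero total projected area")
    eff = float(table.loc[table.internalized, "projected_area_um2"].sum() / total)
    return eff, table


def proliferation_ratio(edu_mask: np.ndarray, dapi_mask: np.ndarray,
                        central_roi: tuple[slice, slice] | None = None
                        ) -> float:
    """Fraction of nuclei in S phase: EdU⁺ nuclei over DAPI nuclei.

    Both inputs are binary or labelled 2-D masks; an EdU⁺ nucleus is a
    connected EdU component overlapping a DAPI nucleus.  ``central_roi``
    restricts the count to a central window (edge effects on the gel).
    """
    edu = np.asarray(edu_mask)
    dapi = np.asarray(dapi_mask)
    if edu.shape != dapi.shape:
        raise ValueError("masks must share a shape")
    if central_roi is not None:
        edu = edu[central_roi]
        dapi = dapi[central_roi]
    dapi_lab, n_dapi = ndi.label(dapi > 0)
    if n_dapi == 0:
        raise ValueError("no DAPI nuclei in the ROI")
    edu_lab, n_edu = ndi.label(edu > 0)
    positive = set()
    for comp in range(1, n_edu + 1):
        hit = np.unique(dapi_lab[edu_lab == comp])
        positive.update(int(h) for h in hit if h > 0)
    return len(positive) / n_dapi


def region_of_distance(d_um: float, bins: RegionBins = RegionBins()) -> str:
    """Retinal region of a distance from the optic nerve (half-open bins).

    centre [300, 1200) µm, mid periphery [1200, 2000) µm, far periphery
    [2000, 3000) µm; anything outside returns ``"unassigned"``.
    """
    if d_um < 0:
        raise ValueError("distance must be non-negative")
    for name, (lo, hi) in (("centre", bins.centre),
                           ("mid_periphery", bins.mid_periphery),
                           ("far_periphery", bins.far_periphery)):
        if lo <= d_um < hi:
            return name
    return "unassigned"


def normalize_per_eye(values: Sequence[float] | Mapping[str, Sequence[float]],
                      group_keys: Sequence[str] | None = None
                      ) -> np.ndarray | dict[str, np.ndarray]:
    """Divide each intensity by the maximum of its eye (group).

    Accepts a flat sequence with parallel ``group_keys``, or a mapping
    group → values; each group's maximum becomes exactly 1.  Idempotent.
    """
    if isinstance(values, Mapping):
        return {k: normalize_per_eye(v) for k, v in values.items()}
    v = np.asarray(values, dtype=float)
    if group_keys is None:
        m = np.nanmax(v)
        if not np.isfinite(m) or m == 0:
            raise ValueError("group maximum is zero or undefined")
        return v / m
    out = np.empty_like(v)
    for key in set(group_keys):
        sel = np.array([g == key for g in group_keys])
        m = np.nanmax(v[sel])
        if not np.isfinite(m) or m == 0:
            raise ValueError(f"group {key!r} maximum is zero or undefined")
        out[sel] = v[sel] / m
    return out


def roi_mean_intensity(image: np.ndarray,
                       rois: Sequence[np.ndarray]) -> list[float]:
    """Mean pixel intensity inside each ROI polygon of a single section.

    Polygons are (N, 2) arrays of (x, y) vertices in pixel coordinates and
    must lie within the image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D optical section")
    means = []
    for poly in rois:
        poly = np.asarray(poly, dtype=float)
        if (poly.min() < -0.5 or poly[:, 0].max() > img.shape[1] - 0.5
                or poly[:, 1].max() > img.shape[0] - 0.5):
            raise ValueError("ROI polygon extends outside the image")
        rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        if len(rr) == 0:
            raise ValueError("ROI polygon rasterizes to zero pixels")
        means.append(float(img[rr, cc].mean()))
    return means
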