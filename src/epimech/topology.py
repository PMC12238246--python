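"""Monolayer-scale topology statistics: shape factor, Lewis, Desch and
Aboav–Weaire laws, with cell-count-weighted pooling across animals.

Cells are grouped by their neighbor number n:

* Lewis' law — mean rescaled area A_i/⟨A⟩ per n class,
* Desch's law — mean rescaled perimeter per n class (perimeters divided by
  the most probable perimeter, the histogram-PDF peak),
* Aboav–Weaire — b(n) = (n − 6)·µ_m(n) − σ_n², where µ_m(n) is the mean
  neighbor-count among the neighbors of n-sided cells and σ_n² the
  population variance of the sample's neighbor-count distribution.
  b(6) = −σ_n² identically.

The neighbor-count distribution (hence σ_n²) is taken per sample (one
animal), and samples are pooled with weights proportional to their total
cell counts.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (AboavBin, CellRecord, CellTessellation, CurveBin,
                         DistributionPDF, TopologyCurves)
from .hertz import histogram_mode

log = logging.getLogger(__name__)

__all__ = [
    "shape_factor_summary",
    "rescaled_area_pdf",
    "rescaled_perimeter_mode",
    "lewis_law",
    "desch_law",
    "aboav_weaire",
    "topology_curves",
    "pool_across_animals",
]


def _analysis_cells(t: CellTessellation) -> list[CellRecord]:
    cells = t.analysis_set
    if not cells:
        raise ValueError("empty analysis set: run the tessellation filters first")
    return cells


def shape_factor_summary(t: CellTessellation) -> dict:
    """Per-image shape-index statistics over the analysis set.

    Returns mean, median and the raw distribution (violin-ready).
    """
    p = np.array([c.shape_index for c in _analysis_cells(t)])
    return dict(mean=float(p.mean()), median=float(np.median(p)),
                distribution=p)


def _binned_mean(values_by_n: dict[int, list[float]]) -> dict[int, CurveBin]:
    out = {}
    for n in sorted(values_by_n):
        v = np.asarray(values_by_n[n])
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else np.nan
        out[n] = CurveBin(mean=float(v.mean()), sem=sem, count=len(v))
    return out


def lewis_law(t: CellTessellation) -> dict[int, CurveBin]:
    """Mean rescaled area per neighbor-number class (with SEM and count)."""
    by_n: dict[int, list[float]] = {}
    for c in _analysis_cells(t):
        by_n.setdefault(c.n_neighbors, []).append(c.rescaled_area)
    return _binned_mean(by_n)


def desch_law(t: CellTessellation,
              rescale: str = "mode") -> dict[int, CurveBin]:
    """Mean rescaled perimeter per neighbor-number class.

    Perimeters are rescaled by the most probable perimeter of the sample
    (``rescale="mode"``, the PDF peak) or by the mean (``rescale="mean"``).
    """
    cells = _analysis_cells(t)
    P = np.array([c.perimeter for c in cells])
    if rescale == "mode":
        scale = rescaled_perimeter_mode(P)
    elif rescale == "mean":
        scale = float(P.mean())
    else:
        raise ValueError("rescale must be 'mode' or 'mean'")
    by_n: dict[int, list[float]] = {}
    for c in cells:
        by_n.setdefault(c.n_neighbors, []).append(c.perimeter / scale)
    return _binned_mean(by_n)


def aboav_weaire(t: CellTessellation) -> tuple[dict[int, AboavBin], float]:
    """Aboav–Weaire statistics over the bulk analysis set.

    Only cells whose neighborhood is fully defined (non-edge, kept) serve as
    centres.  Edge cells are likewise excluded from the µ_m(n) averages:
    their neighbor counts are truncated by the image frame, i.e. their
    neighborhood is not defined either.  Returns (per-n bins, σ_n²) with
    σ_n² the population variance of the neighbor-count distribution over the
    centres.
    """
    centres = _analysis_cells(t)
    by_label = t.by_label()
    ns = np.array([c.n_neighbors for c in centres])
    sigma2 = float(ns.var())  # population (central second moment)
    mu_by_n: dict[int, list[float]] = {}
    for c in centres:
        nbr_counts = [by_label[l].n_neighbors for l in c.neighbor_labels
                      if l in by_label and not by_label[l].is_edge]
        if not nbr_counts:
            continue
        mu_by_n.setdefault(c.n_neighbors, []).append(float(np.mean(nbr_counts)))
    bins = {}
    for n in sorted(mu_by_n):
        mu = float(np.mean(mu_by_n[n]))
        bins[n] = AboavBin(mu_m=mu, b=(n - 6) * mu - sigma2,
                           count=len(mu_by_n[n]))
    return bins, sigma2


def topology_curves(t: CellTessellation, sample_id: str = "") -> TopologyCurves:
    """All binned curves of one sample in a single container."""
    aboav, sigma2 = aboav_weaire(t)
    return TopologyCurves(
        lewis=lewis_law(t),
        desch=desch_law(t),
        aboav=aboav,
        sigma2=sigma2,
        n_cells=len(t.analysis_set),
        sample_id=sample_id or t.source_id,
    )


# ----------------------------------------------------------- distributions

def rescaled_area_pdf(rescaled_areas: np.ndarray | CellTessellation,
                      bin_width: float = 0.05,
                      support: tuple[float, float] = (0.0, 2.0)
                      ) -> DistributionPDF:
    """Normalized histogram density of rescaled areas on (0, 2].

    Accepts raw values (possibly pooled over images — per-image rescaled
    values concatenate directly) or a filtered tessellation.
    """
    if isinstance(rescaled_areas, CellTessellation):
        v = np.array([c.rescaled_area for c in _analysis_cells(rescaled_areas)])
    else:
        v = np.asarray(rescaled_areas, dtype=float)
    v = v[np.isfinite(v)]
    edges = np.arange(support[0], support[1] + bin_width / 2, bin_width)
    density, edges = np.histogram(v, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[np.argmax(density)])
    return DistributionPDF(bin_centers=centers, density=density,
                           bin_width=bin_width, mode=mode)


def rescaled_perimeter_mode(perimeters: np.ndarray) -> float:
    """Most probable cell perimeter: peak of the perimeter PDF.

    Estimated by the log-space KDE mode (:func:`epimech.hertz.histogram_mode`);
    a coarse-histogram tie (near-bimodal PDF) is logged, and the continuous
    density argmax — the smaller peak in the tied case — is returned."""
    v = np.asarray(perimeters, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) == 0:
        raise ValueError("no perimeters")
    if np.ptp(v) == 0:
        return float(v[0])
    counts, _ = np.histogram(v, bins="fd")
    if np.sum(counts == counts.max()) > 1:
        log.warning("multimodal perimeter PDF tie; returning the density argmax")
    return histogram_mode(v)


# ---------------------------------------------------------------- pooling

def _pool_curvebins(per_sample: list[dict[int, CurveBin]],
                    weights: np.ndarray) -> dict[int, CurveBin]:
    ns = sorted({n for d in per_sample for n in d})
    out = {}
    for n in ns:
        vals, ws, cnt = [], [], 0
        for d, w in zip(per_sample, weights):
            if n in d:
                vals.append(d[n].mean)
                ws.append(w)
                cnt += d[n].count
        vals, ws = np.asarray(vals), np.asarray(ws)
        mean = float(np.sum(vals * ws) / np.sum(ws))
        sems = [d[n].sem for d, w in zip(per_sample, weights) if n in d]
        sem = (float(np.sqrt(np.nansum((np.asarray(ws) / np.sum(ws)) ** 2
                                       * np.asarray(sems, dtype=float) ** 2)))
               if not all(np.isnan(s) for s in sems) else np.nan)
        out[n] = CurveBin(mean=mean, sem=sem, count=cnt)
    return out


def pool_across_animals(curves: list[TopologyCurves],
                        weights: list[float] | None = None) -> TopologyCurves:
    """Pool per-animal curves with weights ∝ total cell count per animal.

    Each bin present in a subset of animals is pooled over that subset.
    σ_n² and µ_m(n) pool with the same weights; b(n) is recomputed from the
    pooled quantities so the b(6) = −σ_n² identity survives pooling.
    """
    if not curves:
        raise ValueError("no curves to pool")
    w = np.asarray(weights if weights is not None
                   else [c.n_cells for c in curves], dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    lewis = _pool_curvebins([c.lewis for c in curves], w)
    desch = _pool_curvebins([c.desch for c in curves], w)
    sigma2 = float(np.sum(w * np.array([c.sigma2 for c in curves])) / w.sum())
    ns = sorted({n for c in curves for n in c.aboav})
    aboav = {}
    for n in ns:
        mus, ws, cnt = [], [], 0
        for c, wi in zip(curves, w):
            if n in c.aboav:
                mus.append(c.aboav[n].mu_m)
                ws.append(wi)
                cnt += c.aboav[n].count
        mu = float(np.sum(np.asarray(mus) * np.asarray(ws)) / np.sum(ws))
        aboav[n] = AboavBin(mu_m=mu, b=(n - 6) * mu - sigma2, count=cnt)
    return TopologyCurves(lewis=lewis, desch=desch, aboav=aboav,
                          sigma2=sigma2,
                          n_cells=int(sum(c.n_cells for c in curves)),
                          sample_id="pooled")
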