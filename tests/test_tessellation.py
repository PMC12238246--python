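"""Mask-to-tessellation pipeline: measurement, adjacency, filters, nuclei."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import draw

from epimech.tessellation import (
    analyze_mask,
    build_adjacency,
    filter_cells,
    flag_edge_cells,
    nuclear_shape_metrics,
    tessellation_from_mask,
)

from conftest import HEX_SHAPE_INDEX


def brute_force_adjacency(mask: np.ndarray) -> dict[int, set[int]]:
    """Oracle: per-label radius-1 dilation (8-connectivity), neighbors iff
    the dilated supports overlap."""
    labels = [int(l) for l in np.unique(mask) if l > 0]
    dilated = {}
    for lab in labels:
        dilated[lab] = ndi.binary_dilation(mask == lab,
                                           structure=np.ones((3, 3)))
    out = {lab: set() for lab in labels}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if np.any(dilated[a] & dilated[b]):
                out[a].add(b)
                out[b].add(a)
    return out


class TestMeasurement:
    def test_trim_of_empty_border_is_noop(self):
        mask = np.zeros((100, 100), dtype=np.uint16)
        mask[40:60, 40:60] = 1
        t_trim = tessellation_from_mask(mask, 1.0, trim_px=15)
        t_raw = tessellation_from_mask(mask, 1.0, trim_px=0)
        assert t_trim.cells[0].area == t_raw.cells[0].area
        assert t_trim.cells[0].perimeter == t_raw.cells[0].perimeter

    def test_areas_scale_with_pixel_size_squared(self, hex_monolayer):
        mask, _ = hex_monolayer
        t1 = tessellation_from_mask(mask, 1.0, trim_px=0)
        t2 = tessellation_from_mask(mask, 0.21, trim_px=0)
        a1 = np.array([c.area for c in t1.cells])
        a2 = np.array([c.area for c in t2.cells])
        assert np.allclose(a2, a1 * 0.21 ** 2)

    def test_shape_index_invariant_under_pixel_size(self, hex_monolayer):
        mask, _ = hex_monolayer
        t1 = tessellation_from_mask(mask, 1.0, trim_px=0)
        t2 = tessellation_from_mask(mask, 3.7, trim_px=0)
        p1 = np.array([c.shape_index for c in t1.cells])
        p2 = np.array([c.shape_index for c in t2.cells])
        assert np.allclose(p1, p2)

    def test_measured_geometry_matches_generator_truth(self, hex_analyzed,
                                                       hex_monolayer):
        t, _ = hex_analyzed
        _, truth = hex_monolayer
        by_truth = truth.by_label()
        interior = [c for c in t.cells if not c.is_edge]
        rel_area = [abs(c.area / by_truth[c.label].area - 1) for c in interior]
        rel_perim = [abs(c.perimeter / by_truth[c.label].perimeter - 1)
                     for c in interior]
        assert np.mean(rel_area) < 0.03
        assert np.mean(rel_perim) < 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tessellation_from_mask(np.zeros((64, 64), dtype=np.uint16), 1.0,
                                   trim_px=0)

    def test_non_integer_mask_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            tessellation_from_mask(np.zeros((64, 64)), 1.0)

    def test_3d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            tessellation_from_mask(np.zeros((4, 64, 64), dtype=np.uint16), 1.0)


class TestAdjacency:
    def test_2x2_square_block_has_three_neighbors_each(self):
        # four 10x10 squares meeting at a point: diagonal contact counts
        mask = np.zeros((21, 21), dtype=np.uint16)
        mask[0:10, 0:10] = 1
        mask[0:10, 11:21] = 2
        mask[11:21, 0:10] = 3
        mask[11:21, 11:21] = 4
        t = tessellation_from_mask(mask, 1.0, trim_px=0)
        build_adjacency(t, mask)
        assert all(c.n_neighbors == 3 for c in t.cells)
        oracle = brute_force_adjacency(mask)
        for c in t.cells:
            assert set(c.neighbor_labels) == oracle[c.label]

    def test_isolated_cell_has_no_neighbors(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        mask[10:20, 10:20] = 1
        mask[40:50, 40:50] = 2
        t = tessellation_from_mask(mask, 1.0, trim_px=0)
        build_adjacency(t, mask)
        assert all(c.n_neighbors == 0 for c in t.cells)

    def test_hex_interior_cell_has_six_neighbors(self, hex_analyzed):
        t, _ = hex_analyzed
        interior = [c for c in t.cells if not c.is_edge]
        assert {c.n_neighbors for c in interior} == {6}

    def test_symmetry_exhaustive(self, disordered_analyzed):
        t, _ = disordered_analyzed
        by_label = t.by_label()
        for c in t.cells:
            for nb in c.neighbor_labels:
                assert c.label in by_label[nb].neighbor_labels

    def test_matches_dilation_oracle_on_small_mask(self):
        from epimech.synthetic import SyntheticMonolayerSpec, generate_monolayer
        mask, _ = generate_monolayer(
            SyntheticMonolayerSpec(n_cells=40, disorder=0.35,
                                   image_size_px=256, seed=2))
        t = tessellation_from_mask(mask, 1.0, trim_px=0)
        build_adjacency(t, mask)
        oracle = brute_force_adjacency(mask)
        for c in t.cells:
            assert set(c.neighbor_labels) == oracle[c.label]


class TestEdgeFlagging:
    def test_hex_interior_is_bulk_and_border_is_edge(self, hex_analyzed,
                                                     hex_monolayer):
        t, _ = hex_analyzed
        _, truth = hex_monolayer
        by_truth = truth.by_label()
        measured_edge = {c.label for c in t.cells if c.is_edge}
        truth_edge = {c.label for c in truth.cells if c.is_edge
                      and c.label in {x.label for x in t.cells}}
        # every frame-clipped cell is detected ...
        assert truth_edge <= measured_edge
        # ... and any extra flag sits in the outermost ring (a cell whose
        # boundary is tangent to the frame touches border pixels)
        pitch_um = np.sqrt(2 * 1024 ** 2 / (np.sqrt(3) * 64)) * 0.5
        size_um = 1024 * 0.5
        for lab in measured_edge - truth_edge:
            x, y = by_truth[lab].centroid
            d = min(x, y, size_um - x, size_um - y)
            assert d < 1.2 * pitch_um

    def test_zero_threshold_flags_everything(self, hex_monolayer):
        mask, _ = hex_monolayer
        t = tessellation_from_mask(mask, 0.5, trim_px=0)
        build_adjacency(t, mask)
        flag_edge_cells(t, mask, bulk_threshold_px=0.0)
        assert all(c.is_edge for c in t.cells)

    def test_neighborless_cell_is_edge(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        mask[20:40, 20:40] = 1
        t = tessellation_from_mask(mask, 1.0, trim_px=0)
        build_adjacency(t, mask)
        flag_edge_cells(t, mask)
        assert t.cells[0].is_edge


class TestFilters:
    def test_outlier_area_and_neighbor_count_removed(self, disordered_monolayer):
        mask, _ = disordered_monolayer
        t, _ = analyze_mask(mask, 0.5, trim_px=0)   # fresh copy, safe to mutate
        bulk = [c for c in t.cells if not c.is_edge]
        mean_area = np.mean([c.area for c in bulk])
        victim_a, victim_n = bulk[0], bulk[1]
        victim_a.area = 2.5 * mean_area            # rescaled area > 2
        victim_n.neighbor_labels = tuple(range(2000, 2011))  # n = 11
        filter_cells(t)
        assert not victim_a.kept
        assert not victim_n.kept
        others = [c for c in bulk if c.label not in
                  (victim_a.label, victim_n.label)]
        # the outliers inflate <A> slightly; every other bulk cell survives
        assert all(c.kept for c in others)

    def test_mean_rescaled_area_is_one_over_rescaling_population(
            self, disordered_analyzed):
        t, _ = disordered_analyzed
        bulk = [c for c in t.cells if not c.is_edge]
        assert np.mean([c.rescaled_area for c in bulk]) == pytest.approx(
            1.0, abs=1e-9)

    def test_hexagonal_lattice_loses_nothing(self, hex_analyzed):
        t, _ = hex_analyzed
        bulk = [c for c in t.cells if not c.is_edge]
        assert all(c.kept for c in bulk)


class TestNuclearShape:
    def test_disc_is_round(self):
        mask = np.zeros((128, 128), dtype=np.uint16)
        rr, cc = draw.disk((64, 64), 50)
        mask[rr, cc] = 1
        (n,) = nuclear_shape_metrics(mask)
        assert n.circularity >= 0.95
        assert n.aspect_ratio <= 1.05

    def test_two_to_one_ellipse_aspect_ratio(self):
        mask = np.zeros((128, 128), dtype=np.uint16)
        rr, cc = draw.ellipse(64, 64, 25, 50)
        mask[rr, cc] = 1
        (n,) = nuclear_shape_metrics(mask)
        assert n.aspect_ratio == pytest.approx(2.0, rel=0.02)

    def test_square_circularity_closed_form(self):
        mask = np.zeros((128, 128), dtype=np.uint16)
        mask[30:90, 30:90] = 1
        (n,) = nuclear_shape_metrics(mask)
        assert n.circularity == pytest.approx(np.pi / 4.0, rel=0.02)

    def test_degenerate_region_skipped(self):
        mask = np.zeros((32, 32), dtype=np.uint16)
        mask[5, 5] = 1           # single pixel
        mask[10:20, 10:20] = 2
        out = nuclear_shape_metrics(mask)
        assert [n.label for n in out] == [2]


def test_full_pipeline_shape_index_on_honeycomb(hex_analyzed):
    t, _ = hex_analyzed
    p = [c.shape_index for c in t.analysis_set]
    assert np.mean(p) == pytest.approx(HEX_SHAPE_INDEX, rel=5e-3)
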