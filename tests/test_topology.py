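"""Topology laws: binning arithmetic, the b(6) = −σ² identity, pooling."""

import numpy as np
import pytest

from epimech.containers import AboavBin, CurveBin, TopologyCurves
from epimech.topology import (
    aboav_weaire,
    desch_law,
    lewis_law,
    pool_across_animals,
    rescaled_area_pdf,
    rescaled_perimeter_mode,
    shape_factor_summary,
    topology_curves,
)

from conftest import make_tessellation


def brute_force_topology(t):
    """Independent per-cell enumeration of Lewis/Desch/Aboav statistics,
    straight from the definitions (no shared code with the implementation)."""
    by_label = {c.label: c for c in t.cells}
    kept = [c for c in t.cells if c.kept]
    lewis, desch_vals, mu = {}, {}, {}
    for c in kept:
        n = len(c.neighbor_labels)
        lewis.setdefault(n, []).append(c.rescaled_area)
        desch_vals.setdefault(n, []).append(c.perimeter)
        # neighbors on the image frame have truncated, undefined neighborhoods
        counts = [len(by_label[l].neighbor_labels) for l in c.neighbor_labels
                  if l in by_label and not by_label[l].is_edge]
        if counts:
            mu.setdefault(n, []).append(sum(counts) / len(counts))
    ns = np.array([len(c.neighbor_labels) for c in kept], dtype=float)
    sigma2 = float(np.mean((ns - ns.mean()) ** 2))
    lewis_out = {n: sum(v) / len(v) for n, v in lewis.items()}
    mu_out = {n: sum(v) / len(v) for n, v in mu.items()}
    b_out = {n: (n - 6) * m - sigma2 for n, m in mu_out.items()}
    return lewis_out, desch_vals, mu_out, b_out, sigma2


class TestShapeFactor:
    def test_unit_squares_give_four(self):
        t = make_tessellation([6, 6, 6], perimeters=[4.0, 4.0, 4.0])
        for c in t.analysis_set:
            c.area = 1.0
        s = shape_factor_summary(t)
        assert s["mean"] == pytest.approx(4.0)
        assert s["median"] == pytest.approx(4.0)

    def test_empty_analysis_set_rejected(self):
        t = make_tessellation([6])
        for c in t.cells:
            c.kept = False
        with pytest.raises(ValueError):
            shape_factor_summary(t)


class TestLewisDesch:
    def test_toy_lewis_arithmetic(self):
        t = make_tessellation([5, 5, 6, 7], rescaled=[0.8, 0.9, 1.0, 1.2])
        lw = lewis_law(t)
        assert lw[5].mean == pytest.approx(0.85)
        assert lw[5].count == 2
        assert lw[6].mean == pytest.approx(1.0)
        assert lw[7].mean == pytest.approx(1.2)
        assert np.isnan(lw[6].sem)     # singleton bin: count but no SEM
        assert not np.isnan(lw[5].sem)

    def test_toy_desch_arithmetic(self):
        # dominant perimeter cluster at 1.0 defines the mode
        n_vals = [5] + [6] * 20 + [7]
        perims = [0.9] + [1.0] * 20 + [1.1]
        t = make_tessellation(n_vals, perimeters=perims)
        ds = desch_law(t)
        assert ds[5].mean == pytest.approx(0.9, abs=0.02)
        assert ds[7].mean == pytest.approx(1.1, abs=0.02)

    def test_hexagonal_lattice_collapses_to_single_point(self, hex_analyzed):
        t, _ = hex_analyzed
        lw, ds = lewis_law(t), desch_law(t)
        assert set(lw) == {6} and set(ds) == {6}
        assert lw[6].mean == pytest.approx(1.0, abs=1e-9)
        assert ds[6].mean == pytest.approx(1.0, abs=5e-3)

    def test_lewis_increases_with_n_on_disordered_voronoi(self):
        from epimech.synthetic import SyntheticMonolayerSpec, generate_monolayer
        from epimech.tessellation import analyze_mask
        vals = {}
        for seed in range(3):
            mask, _ = generate_monolayer(SyntheticMonolayerSpec(
                n_cells=150, disorder=0.4, image_size_px=1024, seed=seed))
            t, _ = analyze_mask(mask, 0.5, trim_px=0)
            for n, b in lewis_law(t).items():
                vals.setdefault(n, []).append((b.mean, b.count))
        pooled = {n: np.average([m for m, _ in v],
                                weights=[c for _, c in v])
                  for n, v in vals.items()}
        ns = [n for n in sorted(pooled) if 4 <= n <= 8]
        seq = [pooled[n] for n in ns]
        assert all(a < b for a, b in zip(seq, seq[1:]))

    def test_desch_increases_with_n_on_disordered_voronoi(
            self, disordered_analyzed):
        t, _ = disordered_analyzed
        ds = desch_law(t)
        ns = [n for n in sorted(ds) if ds[n].count >= 5]
        seq = [ds[n].mean for n in ns]
        assert all(a < b for a, b in zip(seq, seq[1:]))

    def test_frequency_weighted_lewis_mean_equals_population_mean(
            self, disordered_analyzed):
        t, _ = disordered_analyzed
        lw = lewis_law(t)
        weighted = sum(b.mean * b.count for b in lw.values()) \
            / sum(b.count for b in lw.values())
        pop = np.mean([c.rescaled_area for c in t.analysis_set])
        assert weighted == pytest.approx(pop, abs=1e-12)


class TestAboavWeaire:
    def test_hexagonal_lattice(self, hex_analyzed):
        t, _ = hex_analyzed
        bins, sigma2 = aboav_weaire(t)
        assert sigma2 == 0.0
        assert set(bins) == {6}
        assert bins[6].mu_m == pytest.approx(6.0)
        assert bins[6].b == pytest.approx(0.0)

    def test_hand_computed_toy_sample(self):
        """n-distribution {5,5,6,6,6,7,7} (σ² = 4/7); 5-sided cells see
        neighborhoods averaging 6.0 → b(5) = −6.0 − 4/7 = −6.571."""
        neighbor_n = [
            [6, 6, 6, 7, 5],          # n = 5 cell, mean 6.0
            [6, 6, 6, 6, 6],          # n = 5 cell, mean 6.0
            [6] * 6, [6] * 6, [6] * 6,
            [6] * 7, [6] * 7,
        ]
        t = make_tessellation([5, 5, 6, 6, 6, 7, 7], neighbor_n=neighbor_n)
        bins, sigma2 = aboav_weaire(t)
        assert sigma2 == pytest.approx(4.0 / 7.0)
        assert bins[5].mu_m == pytest.approx(6.0)
        assert bins[5].b == pytest.approx((5 - 6) * 6.0 - 4.0 / 7.0)
        assert bins[5].b == pytest.approx(-6.571, abs=5e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_b6_equals_minus_sigma2(self, seed):
        from epimech.synthetic import SyntheticMonolayerSpec, generate_monolayer
        from epimech.tessellation import analyze_mask
        mask, _ = generate_monolayer(SyntheticMonolayerSpec(
            n_cells=80, disorder=0.3, image_size_px=512, seed=seed))
        t, _ = analyze_mask(mask, 0.5, trim_px=0)
        bins, sigma2 = aboav_weaire(t)
        if 6 in bins:
            assert bins[6].b == pytest.approx(-sigma2, abs=1e-12)

    def test_matches_brute_force_enumeration(self, disordered_analyzed):
        t, _ = disordered_analyzed
        bins, sigma2 = aboav_weaire(t)
        _, _, mu_bf, b_bf, sigma2_bf = brute_force_topology(t)
        assert sigma2 == pytest.approx(sigma2_bf, abs=1e-12)
        assert set(bins) == set(b_bf)
        for n in bins:
            assert bins[n].mu_m == pytest.approx(mu_bf[n], abs=1e-12)
            assert bins[n].b == pytest.approx(b_bf[n], abs=1e-12)


class TestDistributions:
    def test_pdf_integrates_to_one(self, disordered_analyzed):
        t, _ = disordered_analyzed
        pdf = rescaled_area_pdf(t)
        assert pdf.integral() == pytest.approx(1.0, abs=1e-6)

    def test_hexagonal_pdf_concentrates_at_unity(self, hex_analyzed):
        t, _ = hex_analyzed
        pdf = rescaled_area_pdf(t, bin_width=0.05)
        assert pdf.mode == pytest.approx(1.0, abs=0.05)
        near_one = np.abs(pdf.bin_centers - 1.0) <= 0.05
        assert np.sum(pdf.density[near_one]) * 0.05 == pytest.approx(
            1.0, abs=1e-6)

    def test_two_population_mix_is_bimodal(self):
        rng = np.random.default_rng(0)
        lo = rng.lognormal(np.log(0.6), 0.05, 4000)
        hi = rng.lognormal(np.log(1.4), 0.05, 4000)
        pdf = rescaled_area_pdf(np.concatenate([lo, hi]), bin_width=0.05)
        d = pdf.density
        peaks = [i for i in range(1, len(d) - 1)
                 if d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.2 * d.max()]
        centers = sorted(pdf.bin_centers[i] for i in peaks)
        assert abs(centers[0] - 0.6) <= 0.05
        assert abs(centers[-1] - 1.4) <= 0.05

    def test_perimeter_mode_on_lognormal(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(np.log(20.0), 0.3, 10_000)
        analytic = np.exp(np.log(20.0) - 0.3 ** 2)
        assert rescaled_perimeter_mode(v) == pytest.approx(analytic, rel=0.03)

    def test_perimeter_mode_constant_sample(self):
        assert rescaled_perimeter_mode(np.full(40, 7.5)) == 7.5


class TestPooling:
    def _curves(self, b5_mu, sigma2, n_cells):
        return TopologyCurves(
            lewis={5: CurveBin(1.0, 0.1, n_cells)},
            desch={5: CurveBin(1.0, 0.1, n_cells)},
            aboav={5: AboavBin(mu_m=b5_mu, b=(5 - 6) * b5_mu - sigma2,
                               count=n_cells)},
            sigma2=sigma2, n_cells=n_cells, sample_id="x")

    def test_single_animal_is_identity(self):
        c = self._curves(5.0, 1.0, 1000)
        pooled = pool_across_animals([c])
        assert pooled.aboav[5].b == pytest.approx(c.aboav[5].b)
        assert pooled.sigma2 == pytest.approx(c.sigma2)
        assert pooled.lewis[5].mean == pytest.approx(1.0)

    def test_cell_count_weighted_mean(self):
        # b(5) = −6 with 1000 cells and −8 with 3000 cells → −7.5
        a = self._curves(5.0, 1.0, 1000)   # b = −6
        b = self._curves(6.0, 2.0, 3000)   # b = −8
        pooled = pool_across_animals([a, b])
        assert pooled.aboav[5].b == pytest.approx(-7.5)
        assert pooled.n_cells == 4000

    def test_equal_weights_give_simple_mean(self):
        a = self._curves(5.0, 1.0, 500)
        b = self._curves(6.0, 2.0, 500)
        pooled = pool_across_animals([a, b])
        assert pooled.aboav[5].b == pytest.approx(-7.0)

    def test_all_equal_inputs_unchanged(self):
        cs = [self._curves(5.5, 1.2, 800) for _ in range(3)]
        pooled = pool_across_animals(cs)
        assert pooled.aboav[5].b == pytest.approx(cs[0].aboav[5].b)
        assert pooled.sigma2 == pytest.approx(1.2)

    def test_pooling_preserves_b6_identity(self):
        def curves(mu6, s2, n):
            return TopologyCurves(
                aboav={6: AboavBin(mu_m=mu6, b=-s2, count=n)},
                sigma2=s2, n_cells=n)
        pooled = pool_across_animals([curves(6.0, 0.5, 1000),
                                      curves(6.2, 1.5, 2000)])
        assert pooled.aboav[6].b == pytest.approx(-pooled.sigma2, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_across_animals([])


def test_topology_curves_container_roundtrip(disordered_analyzed):
    t, _ = disordered_analyzed
    curves = topology_curves(t, sample_id="m1")
    df = curves.to_dataframe()
    assert set(df.curve) == {"lewis", "desch", "aboav_b"}
    assert curves.n_cells == len(t.analysis_set)
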