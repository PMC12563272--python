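import math

import numpy as np
import pytest
from scipy.integrate import quad

import wellquant as wq
from wellquant.counting import (
    colony_height,
    colony_volume,
    count_u_bottom,
    gap_height,
)

PDMS = wq.WellSpec(shape="u_bottom", top_radius_um=750.0, depth_um=248.0)
CELL = wq.make_cell_model(15.0)


class TestCellModel:
    def test_projected_area_at_15um(self):
        assert CELL.projected_area_um2 == pytest.approx(176.71, abs=0.005)

    def test_volume_at_15um(self):
        assert CELL.volume_um3 == pytest.approx(math.pi * 15**3 / 6, rel=1e-12)
        assert CELL.volume_um3 == pytest.approx(1767.15, abs=0.01)

    def test_small_cell(self):
        assert wq.make_cell_model(2.0).projected_area_um2 == pytest.approx(math.pi)

    def test_consistency(self):
        c = wq.make_cell_model(11.3)
        assert c.projected_area_um2 == pytest.approx(math.pi * c.diameter_um**2 / 4)
        assert c.volume_um3 == pytest.approx(math.pi * c.diameter_um**3 / 6)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            wq.make_cell_model(0)


class TestCountFlat:
    def test_zero_area(self):
        assert wq.count_flat(0, CELL) == 0

    def test_hundred_cells(self):
        assert wq.count_flat(17671.458676, CELL) == pytest.approx(100.0, rel=1e-6)

    def test_linear_in_area(self):
        assert wq.count_flat(2 * 12345.0, CELL) == pytest.approx(
            2 * wq.count_flat(12345.0, CELL)
        )


class TestColonyGeometry:
    def test_full_width_colony_has_zero_gap(self):
        assert gap_height(248, 750, 750) == 0.0

    def test_empty_well_gap_is_depth(self):
        assert gap_height(248, 0, 750) == 248.0

    def test_gap_height_half_radius(self):
        assert gap_height(248, 375, 750) == pytest.approx(214.774300, abs=1e-5)

    def test_gap_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gap_height(248, 800, 750)

    def test_colony_height_chain(self):
        assert colony_height(248, 0) == 248
        assert colony_height(248, 248) == 0
        assert colony_height(248, 214.774300) == pytest.approx(33.225700, abs=1e-5)

    def test_volume_zero_height(self):
        assert colony_volume(375, 0, 248) == 0.0

    def test_volume_half_radius_colony(self):
        assert colony_volume(375, 33.2256999, 248) == pytest.approx(
            1.4590841e7, rel=1e-6
        )

    def test_full_well_volume_is_half_prolate_spheroid(self):
        """At r = R, h = c the volume formula reduces to (2/3) pi R^2 c to
        10 significant figures."""
        R, c = 750.0, 248.0
        expected = 2.0 / 3.0 * math.pi * R**2 * c
        assert colony_volume(R, c, c) == pytest.approx(expected, rel=1e-10)
        assert colony_volume(R, c, c, mode="exact_cap") == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize("h_frac", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_exact_cap_matches_numerical_integration(self, h_frac):
        """exact_cap equals the solid-of-revolution cap volume to 0.1%."""
        R, c = 750.0, 248.0
        h = h_frac * c
        r = R * math.sqrt(1 - ((c - h) / c) ** 2)
        numeric, _ = quad(
            lambda z: math.pi * R**2 * (1 - ((c - z) / c) ** 2), 0, h
        )
        assert colony_volume(r, h, c, mode="exact_cap") == pytest.approx(
            numeric, rel=1e-3
        )

    @pytest.mark.parametrize("h_frac", [0.2, 0.5, 0.8])
    def test_printed_formula_differs_from_exact_cap_at_interior_heights(
        self, h_frac
    ):
        R, c = 750.0, 248.0
        h = h_frac * c
        r = R * math.sqrt(1 - ((c - h) / c) ** 2)
        assert colony_volume(r, h, c) != pytest.approx(
            colony_volume(r, h, c, mode="exact_cap"), rel=1e-6
        )


class TestCountUBottom:
    def test_empty_cluster_list(self):
        est = count_u_bottom([], PDMS, CELL)
        assert est.n_cells_est == 0

    def test_half_radius_colony_chain(self):
        est = count_u_bottom([math.pi * 375**2], PDMS, CELL)
        assert est.r_um == pytest.approx(375.0)
        assert est.h_prime_um == pytest.approx(214.7743, abs=1e-3)
        assert est.h_um == pytest.approx(33.2257, abs=1e-3)
        assert est.v_cells_um3 == pytest.approx(1.4590841e7, rel=1e-5)
        assert est.n_cells_est == pytest.approx(8256.7, abs=1.0)

    def test_full_well_closed_form(self):
        R, c = 750.0, 248.0
        est = count_u_bottom([math.pi * R**2], PDMS, CELL)
        expected_v = 2 / 3 * math.pi * R**2 * c
        assert est.v_cells_um3 == pytest.approx(expected_v, rel=1e-10)
        assert est.n_cells_est == pytest.approx(
            expected_v / (math.pi * 15**3 / 6), rel=1e-10
        )

    def test_cluster_areas_sum(self):
        """Splitting the same total across clusters changes nothing."""
        total = math.pi * 300**2
        a = count_u_bottom([total], PDMS, CELL)
        b = count_u_bottom([total / 4] * 4, PDMS, CELL)
        assert a.n_cells_est == pytest.approx(b.n_cells_est)

    def test_overfull_area_warns_and_clamps(self):
        too_big = math.pi * 750**2 * 1.05
        with pytest.warns(UserWarning, match="clamped"):
            est = count_u_bottom([too_big], PDMS, CELL)
        assert est.clamped
        assert est.r_um == 750.0

    def test_flat_spec_rejected(self):
        flat = wq.WellSpec(shape="flat", top_radius_um=400, bottom_diameter_um=800)
        with pytest.raises(ValueError):
            count_u_bottom([100.0], flat, CELL)

    def test_monotone_in_covered_area(self):
        """The count never decreases as the summed area grows on a grid over
        [0, pi R^2]."""
        areas = np.linspace(0, math.pi * 750**2, 200)
        counts = [count_u_bottom([a], PDMS, CELL).n_cells_est for a in areas]
        assert all(b >= a - 1e-9 for a, b in zip(counts, counts[1:]))


class TestRoundTripWithSyntheticData:
    @pytest.mark.parametrize("n", [10, 50, 100, 200])
    def test_ground_truth_area_recovers_count(self, n):
        """count_flat on the generator's own mask area recovers the true
        cell number within 3% (rasterization only)."""
        spec = wq.WellSpec(
            shape="flat",
            top_radius_um=400,
            bottom_diameter_um=800,
            pixel_scale_um_per_px=1.6,
        )
        _, truth = wq.render_well(spec, wq.CellRenderSpec(), n, seed=1000 + n)
        est = wq.count_flat(truth.covered_area_um2, CELL)
        assert est == pytest.approx(n, rel=0.03)
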