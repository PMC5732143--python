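"""Synthetic-image generator: size law, phenotypes, determinism."""

import dataclasses

import numpy as np
import pytest

from spherohca.exceptions import ValidationError
from spherohca.plate import Condition, PlateLayout
from spherohca.simulate import (
    SpheroidPhenotypeParams,
    render_well,
    simulate_drug_response,
    simulate_plate,
)


class TestSizeLaw:
    def test_initial_radius_matches_equivalent_sphere(self):
        # 2000 cells x 12 pL = 24 nL -> r = (3V/4pi)^(1/3) ~= 179 um
        p = SpheroidPhenotypeParams(seeded_cells=2000)
        assert p.radius_um(0.0) == pytest.approx(178.94, abs=0.01)

    def test_initial_volume_exact(self):
        p = SpheroidPhenotypeParams(seeded_cells=1234, volume_per_cell_pl=12.0)
        assert p.volume_pl(0.0) == 1234 * 12.0

    def test_exponential_growth(self):
        p = SpheroidPhenotypeParams(seeded_cells=1000, growth_rate=0.1)
        assert p.volume_pl(2.0) / p.volume_pl(0.0) == pytest.approx(np.exp(0.2))


class TestRendering:
    def test_mask_area_matches_disk_within_perimeter_order(self, clean_well, geometry):
        params, images, truth = clean_well
        r_px = truth.radius_um / geometry.pixel_size_um
        assert abs(truth.area_px2 - np.pi * r_px**2) <= 4.0 * r_px

    def test_apoptotic_core_is_step_function_of_diameter(self, geometry):
        # threshold 450 um: 3700 cells -> d=439, 4200 cells -> d=458
        for cells, has_core in ((3700, False), (4200, True)):
            p = SpheroidPhenotypeParams(seeded_cells=cells, noise_sd=0.0)
            images, truth = render_well(p, geometry, 0.0, seed=3)
            assert (
                truth.equiv_diameter_um > p.core_apoptosis_threshold_um
            ) == has_core
            assert (images["apoptosis"].max() > 1000) == has_core

    def test_identical_seed_bit_identical(self, geometry):
        p = SpheroidPhenotypeParams(seeded_cells=2000)
        a, _ = render_well(p, geometry, 1.0, seed=5)
        b, _ = render_well(p, geometry, 1.0, seed=5)
        for ch in a:
            np.testing.assert_array_equal(a[ch], b[ch])

    def test_out_of_field_warning(self, geometry):
        p = SpheroidPhenotypeParams(seeded_cells=30000)  # d > 800 um
        with pytest.warns(UserWarning, match="field of view"):
            render_well(p, geometry, 0.0, seed=1)

    def test_uptake_reaches_95pct_of_plateau_by_8h(self):
        p = SpheroidPhenotypeParams()
        frac = 1.0 - np.exp(-p.uptake_rate_per_h * 8.0)
        assert frac >= 0.95

    def test_fragmentation_adds_satellites_below_filter(self, geometry):
        p = SpheroidPhenotypeParams(
            seeded_cells=2000, disruption="fragmentation", noise_sd=0.0
        )
        _, truth = render_well(p, geometry, 0.0, seed=9)
        p0 = dataclasses.replace(p, disruption="none")
        _, truth0 = render_well(p0, geometry, 0.0, seed=9)
        extra = truth.area_px2 - truth0.area_px2
        assert 0 < extra < 3 * 1000  # each satellite below the 1000 px^2 filter


class TestDrugResponse:
    def test_zero_concentration_returns_base(self):
        base = SpheroidPhenotypeParams()
        (out,) = simulate_drug_response(base, "arrest", [50.0], 1.0, [0.0])
        assert out == base

    def test_arrest_halves_growth_at_ec50(self):
        base = SpheroidPhenotypeParams(growth_rate=0.2)
        (out,) = simulate_drug_response(base, "arrest", [50.0], 1.0, [50.0])
        assert out.growth_rate == pytest.approx(0.1)

    def test_disruption_blebs_above_ec50(self):
        base = SpheroidPhenotypeParams()
        (out,) = simulate_drug_response(base, "disruption", [250.0], 1.0, [500.0])
        assert out.disruption == "unilateral_bleb"
        (low,) = simulate_drug_response(base, "disruption", [250.0], 1.0, [100.0])
        assert low.disruption == "none"

    def test_uptake_suppression_lowers_plateau_and_viability(self):
        base = SpheroidPhenotypeParams(uptake_plateau=1000.0)
        (out,) = simulate_drug_response(
            base, "uptake_suppression", [50.0], 1.0, [50.0]
        )
        assert out.uptake_plateau == pytest.approx(500.0)
        assert out.viability == pytest.approx(0.5)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            simulate_drug_response(
                SpheroidPhenotypeParams(), "necrosis", [50.0], 1.0, [1.0]
            )


def _small_layout(replicates=6):
    layout = PlateLayout.default_96(replicates_per_condition=replicates)
    layout.assign_block([Condition("VCaP", 1000)])
    return layout


class TestPlateSimulation:
    def test_noise_free_replicates_share_ground_truth(self):
        layout = _small_layout()
        params = SpheroidPhenotypeParams(seeded_cells=1000, noise_sd=0.0)
        _, _, truth = simulate_plate(
            layout, lambda c: params, [0.0, 2.0], seed=1,
            lum_noise_cv=0.0, render_images=False,
        )
        per_time = truth.groupby("time_days").sphere_volume_pl.nunique()
        assert (per_time == 1).all()

    def test_vehicle_area_grows_monotonically(self):
        layout = _small_layout()
        params = SpheroidPhenotypeParams(seeded_cells=1000, growth_rate=0.2)
        _, _, truth = simulate_plate(
            layout, lambda c: params, [0.0, 1.0, 2.0], seed=1,
            render_images=False,
        )
        series = truth.groupby("time_days").area_um2.mean()
        assert series.is_monotonic_increasing

    def test_flat_bottom_scaling_triples_luminescence(self):
        layout = _small_layout()
        params = SpheroidPhenotypeParams(seeded_cells=1000)
        _, lum_u, _ = simulate_plate(
            layout, lambda c: params, [0.0], seed=2,
            lum_noise_cv=0.0, render_images=False,
        )
        _, lum_f, _ = simulate_plate(
            layout, lambda c: params, [0.0], seed=2,
            lum_noise_cv=0.0, format_scaling=3.0, render_images=False,
        )
        ratio = lum_f.rlu.to_numpy() / lum_u.rlu.to_numpy()
        np.testing.assert_allclose(ratio, 3.0)
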