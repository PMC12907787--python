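"""Scatter model, subtraction, water BHC, vendor emulation, estimation."""

import numpy as np
import pytest

import dectbench as db
from dectbench import scatter as sc
from dectbench.scatter import ScatterParams, WaterBHCLookup
from conftest import mono_response


@pytest.fixture(scope="module")
def bhc_le(response_le, water):
    return WaterBHCLookup(response=response_le, water=water)


@pytest.fixture(scope="module")
def acr_free_le(acr, geometry, response_le):
    return sc.simulate_scan(acr, geometry, response_le, scatter_params=None)


class TestScatterProfile:
    def test_zero_alpha_gives_zero(self):
        s = sc.scatter_profile(ScatterParams(0.0, 1.0), np.full(64, 0.5))
        assert np.all(s == 0.0)

    def test_constant_intensity_beta_one(self):
        """I = c, beta = 1: unit-sum kernel preserves constants, s = alpha c^2."""
        c = 0.37
        s = sc.scatter_profile(ScatterParams(2.0, 1.0), np.full(128, c))
        assert np.allclose(s, 2.0 * c * c, atol=1e-12)

    def test_linear_in_alpha(self, acr_free_le):
        i_p = np.exp(-acr_free_le.values)
        s1 = sc.scatter_profile(ScatterParams(1.0, 0.9), i_p)
        s2 = sc.scatter_profile(ScatterParams(2.0, 0.9), i_p)
        assert np.allclose(s2, 2.0 * s1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScatterParams(np.inf, 1.0)
        with pytest.raises(ValueError):
            ScatterParams(1.0, 1.0, sigma=0.0)


class TestSubtractScatter:
    def test_zero_scatter_is_identity(self, acr_free_le):
        out = sc.subtract_scatter(acr_free_le, ScatterParams(0.0, 1.0))
        assert np.allclose(out.values, acr_free_le.values, atol=1e-12)

    def test_exact_inverse_of_simulation(self, acr, geometry, response_le,
                                         acr_free_le):
        params = ScatterParams(0.25, 0.95, sigma=5.0)
        raw = sc.simulate_scan(acr, geometry, response_le,
                               scatter_params=params)
        out = sc.subtract_scatter(raw, params)
        assert np.max(np.abs(out.values - acr_free_le.values)) < 1e-10

    def test_exact_inverse_with_strong_scatter(self, acr, geometry,
                                               response_le, acr_free_le):
        params = ScatterParams(2.0, 0.95, sigma=5.0)
        raw = sc.simulate_scan(acr, geometry, response_le,
                               scatter_params=params)
        out = sc.subtract_scatter(raw, params)
        assert np.max(np.abs(out.values - acr_free_le.values)) < 1e-8

    def test_output_increases_where_scatter_positive(self, acr, geometry,
                                                     response_le):
        params = ScatterParams(0.3, 0.95)
        raw = sc.simulate_scan(acr, geometry, response_le,
                               scatter_params=params)
        out = sc.subtract_scatter(raw, params)
        assert np.all(out.values - raw.values > 0)


class TestWaterBHC:
    def test_monoenergetic_identity(self, geometry, water):
        resp = mono_response(geometry, 70.0, "LE")
        lookup = WaterBHCLookup(response=resp, water=water, e_ref=70.0)
        g = np.tile(np.linspace(0.0, 5.0, geometry.n_channels), (3, 1))
        sino = db.Sinogram(g, label="LE", geometry=geometry)
        out = sc.water_bhc(sino, resp, lookup=lookup)
        assert np.allclose(out.values, g, atol=1e-9)

    def test_roundtrip_known_length(self, response_le, water, bhc_le,
                                    geometry):
        l_true = 15.0
        mu = db.material_mu(water, response_le.grid.energies)
        t = response_le.weights @ np.exp(-mu * l_true)
        g = np.tile(-np.log(t), (4, 1))
        sino = db.Sinogram(g, label="LE", geometry=geometry)
        out = sc.water_bhc(sino, response_le, lookup=bhc_le)
        assert np.allclose(out.values, bhc_le.mu_ref * l_true, atol=1e-3)

    def test_monotone(self, bhc_le, geometry, response_le):
        g = np.tile(np.linspace(0.0, 5.5, 80), (geometry.n_channels, 1)).T
        sino = db.Sinogram(g, label="LE", geometry=geometry)
        out = sc.water_bhc(sino, response_le, lookup=bhc_le)
        assert np.all(np.diff(out.values, axis=0) > 0)


@pytest.fixture(scope="module")
def vendor_le(materials, geometry, response_le):
    return sc.calibrate_vendor_water_correction(
        materials, geometry, response_le,
        scatter_params=ScatterParams(0.25, 0.95, sigma=5.0))


class TestVendorCorrection:

    def test_reproduces_calibration_scans(self, vendor_le, materials,
                                          geometry, response_le):
        """On the cylinders it was built from, the map is accurate to 0.5%."""
        params = ScatterParams(0.25, 0.95, sigma=5.0)
        for d in (150.0, 250.0):
            ph = db.make_water_cylinder(materials, d)
            sino = sc.simulate_scan(ph, geometry, response_le,
                                    scatter_params=params)
            ideal = vendor_le.mu_ref * db.path_lengths(ph, geometry)["water"]
            got = vendor_le.apply(sino).values
            sel = ideal > 0.5 * vendor_le.mu_ref
            rel = np.abs(got[sel] - ideal[sel]) / ideal[sel]
            assert np.median(rel) < 0.005

    def test_held_out_diameter_bulk_accuracy(self, vendor_le, materials,
                                             geometry, response_le):
        """Median line-integral error on an unseen diameter below 1%."""
        params = ScatterParams(0.25, 0.95, sigma=5.0)
        ph = db.make_water_cylinder(materials, 175.0)
        sino = sc.simulate_scan(ph, geometry, response_le,
                                scatter_params=params)
        ideal = vendor_le.mu_ref * db.path_lengths(ph, geometry)["water"]
        got = vendor_le.apply(sino).values
        sel = ideal > 2.0 * vendor_le.mu_ref  # rays with > 2 cm of water
        rel = np.abs(got[sel] - ideal[sel]) / ideal[sel]
        assert np.median(rel) < 0.01

    def test_residual_bias_on_bone_rays(self, vendor_le, materials, geometry,
                                        response_le, acr):
        """A water-only correction under-corrects rays crossing bone: the
        corrected water-equivalent length exceeds the true water-equivalent
        content there, which is what motivates the explicit decomposition."""
        params = ScatterParams(0.25, 0.95, sigma=5.0)
        sino = sc.simulate_scan(acr, geometry, response_le,
                                scatter_params=params)
        corrected = vendor_le.apply(sino).values
        lengths = db.path_lengths(acr, geometry)
        bone = lengths["bone"]
        water_eq = vendor_le.mu_ref * lengths["water"]
        sel = bone > 2.0
        excess = corrected[sel] - water_eq[sel]
        # bone contributes more than its length in water-equivalent units
        assert np.median(excess) > vendor_le.mu_ref * np.median(bone[sel])

    def test_too_few_diameters_rejected(self, materials, geometry,
                                        response_le):
        with pytest.raises(sc.CalibrationError):
            sc.calibrate_vendor_water_correction(
                materials, geometry, response_le,
                diameters_mm=(100.0, 200.0))


class TestEstimation:
    def test_parameter_recovery(self, acr, geometry, response_le, water,
                                acr_free_le, bhc_le):
        """Matched-model synthesis with (2.0, 0.95) is recovered to 1%."""
        truth = ScatterParams(2.0, 0.95, sigma=5.0)
        raw = sc.simulate_scan(acr, geometry, response_le,
                               scatter_params=truth)
        ref = sc.water_bhc(acr_free_le, response_le, lookup=bhc_le)
        est = sc.estimate_scatter_params(raw, ref, response_le, water)
        assert est.params.alpha == pytest.approx(2.0, rel=0.01)
        assert est.params.beta == pytest.approx(0.95, rel=0.01)
        assert est.iterations <= 500

    def test_zero_scatter_identifiability(self, acr_free_le, response_le,
                                          water, bhc_le):
        """On scatter-free data the optimum is no worse than alpha = 0."""
        ref = sc.water_bhc(acr_free_le, response_le, lookup=bhc_le)
        est = sc.estimate_scatter_params(acr_free_le, ref, response_le, water)
        sub0 = sc.subtract_scatter(acr_free_le, ScatterParams(0.0, 1.0))
        cost0 = float(np.mean(
            (sc.water_bhc(sub0, response_le, lookup=bhc_le).values
             - ref.values) ** 2))
        assert est.cost <= cost0 + 1e-8
        assert abs(est.params.alpha) < 0.02

    def test_descent_from_initial_simplex(self, acr, geometry, response_le,
                                          water, acr_free_le, bhc_le):
        truth = ScatterParams(0.6, 0.9, sigma=5.0)
        raw = sc.simulate_scan(acr, geometry, response_le,
                               scatter_params=truth)
        ref = sc.water_bhc(acr_free_le, response_le, lookup=bhc_le)
        est = sc.estimate_scatter_params(raw, ref, response_le, water)
        assert est.cost <= est.init_cost


class TestRecoveryGrid:
    def test_median_recovery_error_below_2pct(self, materials, geometry_tiny,
                                              water):
        """Seeded (alpha, beta) grid spanning the plausible range."""
        bow = db.bowtie_profile(geometry_tiny.fan_angles)
        resp = db.build_energy_response(80.0, bow, label="LE",
                                        filter_material=materials["aluminum"])
        ph = db.make_water_cylinder(materials, 200.0)
        free = sc.simulate_scan(ph, geometry_tiny, resp, scatter_params=None)
        lookup = WaterBHCLookup(response=resp, water=water)
        ref = sc.water_bhc(free, resp, lookup=lookup)
        errors = []
        for alpha in (0.5, 1.75, 3.0):
            for beta in (0.8, 0.95, 1.1):
                raw = sc.simulate_scan(ph, geometry_tiny, resp,
                                       scatter_params=ScatterParams(
                                           alpha, beta, sigma=5.0))
                est = sc.estimate_scatter_params(raw, ref, resp, water)
                errors += [abs(est.params.alpha / alpha - 1.0),
                           abs(est.params.beta / beta - 1.0)]
        assert np.median(errors) < 0.02
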