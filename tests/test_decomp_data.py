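"""Projection-domain decomposition: training grids, polynomial fits,
round trips, conventional calibration variants."""

import numpy as np
import pytest

import dectbench as db
from dectbench import decomp_data as dd
from dectbench import scatter as sc
from conftest import mono_response


@pytest.fixture(scope="module")
def length_grid():
    return dd.build_length_grid()


@pytest.fixture(scope="module")
def quintic_polys(length_grid, response_le, response_he, water, materials,
                  bowtie):
    return dd.fit_decomposition_polynomials(
        length_grid, response_le, response_he, water, materials["calcium"],
        degree=5, bowtie_mm=bowtie, n_groups=16)


def _forward_pair(lw, lc, response, water, calcium):
    """Noise-free g for one (L_w, L_c) pair on every channel."""
    e = response.grid.energies
    att = np.exp(-(db.material_mu(water, e) * lw
                   + db.material_mu(calcium, e) * lc))
    return -np.log(response.weights @ att)


class TestLengthGrid:
    def test_reference_grid_sizes(self, length_grid):
        assert length_grid.water.size == 301
        assert length_grid.calcium.size == 91
        assert length_grid.pairs.shape == (301 * 91, 2)

    def test_grids_include_negative_lengths(self, length_grid):
        assert length_grid.water.min() == pytest.approx(-2.0)
        assert length_grid.calcium.min() == pytest.approx(-4.0)

    def test_row_major_enumeration(self, length_grid):
        pairs = length_grid.pairs
        assert pairs[0, 0] == pytest.approx(-2.0)
        assert np.allclose(pairs[:91, 0], -2.0)
        assert pairs[1, 1] - pairs[0, 1] == pytest.approx(0.1)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            dd.build_length_grid(step=0.0)


class TestProposedFit:
    def test_monoenergetic_degree_one_is_exact(self, geometry, water,
                                               materials, length_grid):
        """With single-energy responses the forward map is linear, so a
        degree-1 fit reproduces the training lengths almost exactly."""
        rle = mono_response(geometry, 55.0, "LE")
        rhe = mono_response(geometry, 75.0, "HE")
        polys = dd.fit_decomposition_polynomials(
            length_grid, rle, rhe, water, materials["calcium"], degree=1,
            channel_binding="central-only")
        assert polys.residual_rms.max() < 1e-8

    def test_quintic_training_residual(self, quintic_polys):
        """Quintic fits reach the expected adequacy scale on the grid."""
        assert quintic_polys.residual_rms.max() < 0.05

    def test_residual_monotone_in_degree(self, length_grid, response_le,
                                         response_he, water, materials):
        rms = []
        for degree in (1, 3, 5):
            p = dd.fit_decomposition_polynomials(
                length_grid, response_le, response_he, water,
                materials["calcium"], degree=degree,
                channel_binding="central-only")
            rms.append(p.residual_rms.max())
        assert rms[2] <= rms[1] <= rms[0]

    def test_channel_grouping_by_bowtie(self, bowtie):
        group_of, members = dd.group_channels_by_bowtie(bowtie, n_groups=16)
        assert group_of.size == bowtie.size
        assert sum(m.size for m in members) == bowtie.size
        # symmetric bowtie: mirrored channels share a group
        assert group_of[0] == group_of[-1]

    def test_invalid_degree_rejected(self, length_grid, response_le,
                                     response_he, water, materials):
        with pytest.raises(ValueError):
            dd.fit_decomposition_polynomials(
                length_grid, response_le, response_he, water,
                materials["calcium"], degree=0, channel_binding="central-only")


class TestApplyDecomposition:
    @pytest.mark.parametrize("lw,lc,tol", [
        (17.5, 0.25, 0.05),   # water-dominated ray with a little calcium
        (0.0, 0.0, 0.05),     # air ray
        (20.0, 0.0, 0.05),    # pure water: calcium channel stays near zero
    ])
    def test_roundtrip_recovers_lengths(self, quintic_polys, response_le,
                                        response_he, water, materials,
                                        geometry, lw, lc, tol):
        ghe = _forward_pair(lw, lc, response_he, water, materials["calcium"])
        gle = _forward_pair(lw, lc, response_le, water, materials["calcium"])
        le = db.Sinogram(gle[None, :], label="LE", geometry=geometry)
        he = db.Sinogram(ghe[None, :], label="HE", geometry=geometry)
        out_w, out_c = dd.apply_decomposition(le, he, quintic_polys)
        assert np.allclose(out_w.values, lw, atol=tol)
        assert np.allclose(out_c.values, lc, atol=tol)

    def test_misaligned_inputs_rejected(self, quintic_polys, geometry):
        le = db.Sinogram(np.zeros((2, geometry.n_channels)), label="LE",
                         geometry=geometry)
        he = db.Sinogram(np.zeros((3, geometry.n_channels)), label="HE",
                         geometry=geometry)
        with pytest.raises(ValueError):
            dd.apply_decomposition(le, he, quintic_polys)


class TestConventional:
    def test_cubic_has_nine_terms(self):
        assert len(dd.CUBIC_TERMS) == 9
        assert all(1 <= k + l <= 3 for k, l in dd.CUBIC_TERMS)

    def test_coefficient_counts(self, bench_small, materials):
        from dectbench.projector import path_lengths
        calib_le, calib_he, lengths = [], [], []
        for cfg in ("central-calcium", "offset-calcium"):
            ph = db.make_calibration_phantom(materials, cfg)
            le, he = bench_small.simulate_pair(ph)
            calib_le.append(le)
            calib_he.append(he)
            lengths.append(path_lengths(ph, bench_small.geometry))
        cubic = dd.fit_conventional_polynomials(calib_le, calib_he, lengths,
                                                variant="cubic")
        quartic = dd.fit_conventional_polynomials(
            calib_le, calib_he, lengths, variant="constrained-quartic")
        assert cubic.coeffs_w.size == 9 and cubic.coeffs_c.size == 9
        assert quartic.coeffs_w.size == 4 and quartic.coeffs_c.size == 4

    def test_monoenergetic_cubic_is_exact(self, geometry, materials, water):
        """Scatter-free single-energy calibration: the true map is linear,
        a sub-case of the cubic form, so residuals vanish."""
        from dectbench.projector import path_lengths, polychromatic_forward
        rle = mono_response(geometry, 55.0, "LE")
        rhe = mono_response(geometry, 75.0, "HE")
        calib_le, calib_he, lengths = [], [], []
        for cfg in ("central-calcium", "offset-calcium"):
            ph = db.make_calibration_phantom(materials, cfg)
            ls = path_lengths(ph, geometry)
            calib_le.append(polychromatic_forward(ls, rle))
            calib_he.append(polychromatic_forward(ls, rhe))
            lengths.append(ls)
        model = dd.fit_conventional_polynomials(calib_le, calib_he, lengths,
                                                variant="cubic")
        assert max(model.residual_rms) < 1e-6

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            dd.fit_conventional_polynomials([], [], [], variant="quadratic")
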