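"""End-to-end experiment runners: pipelines, orderings, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import dectbench as db
from dectbench import decomp_image, evaluation
from dectbench.experiments import (Bench, BenchConfig, run_accuracy_experiment,
                                   run_conventional_comparison,
                                   run_position_consistency,
                                   run_scatter_ablation)


@pytest.fixture(scope="module")
def tiny_config():
    return BenchConfig(n_projections=180, n_channels=92, n_pixels=128,
                       pixel_size_mm=2.0, n_channel_groups=8,
                       energy_step_eval_kev=55.0)  # 30/85/140 keV only


@pytest.fixture(scope="module")
def bench_mismatch(bench_small):
    """Half-scale bench with the mismatch scatter truth."""
    import dataclasses
    return Bench(dataclasses.replace(bench_small.config, model_mismatch=True))


class TestDataBasedPipeline:
    def test_water_region_density_near_unity(self, matched_densities_small,
                                             bench_small):
        f_w, f_c, _ = matched_densities_small
        roi = db.ROISpec("circle", (0.0, 0.0), radius=10.0)
        assert db.roi_stats(f_w, roi)[0] == pytest.approx(1.0, abs=0.01)
        assert abs(db.roi_stats(f_c, roi)[0]) < 0.01

    def test_vmi_synthesis_commutes_with_reconstruction(
            self, bench_small, acr_raw_small, matched_densities_small):
        """Reconstruction is linear, so recombining length sinograms before
        FBP equals recombining the reconstructed density images."""
        from dectbench import decomp_data, scatter
        raw_le, raw_he = acr_raw_small
        params, const = bench_small.true_scatter()
        corr_le = scatter.subtract_scatter(raw_le, params)
        corr_he = scatter.subtract_scatter(raw_he, params)
        polys = bench_small.decomposition_polynomials()
        lw, lc = decomp_data.apply_decomposition(corr_le, corr_he, polys)
        e = 70.0
        mu_w = db.material_mu(bench_small.water, e)
        mu_c = db.material_mu(bench_small.calcium, e)
        mono = db.Sinogram(mu_w * lw.values + mu_c * lc.values, label="mono",
                           geometry=bench_small.geometry)
        img_first = bench_small.reconstruct(mono)
        f_w, f_c, _ = matched_densities_small
        vmi = decomp_image.synthesize_vmi(f_w, f_c, e, bench_small.water,
                                          bench_small.calcium, units="mu")
        assert np.allclose(img_first.pixels, vmi.pixels, atol=1e-10)

    def test_scatter_correction_reduces_water_bias(self, bench_small,
                                                   acr_raw_small):
        """Matched-model subtraction removes >= 80% of the water-background
        HU bias left by skipping the scatter step entirely."""
        raw_le, raw_he = acr_raw_small
        roi = db.ROISpec("ring", (0.0, 0.0), inner_radius=28.0,
                         thickness=16.0)
        biases = {}
        for subtract in (True, False):
            f_w, f_c, _ = bench_small.data_based_densities(
                raw_le, raw_he, scatter_mode="known", subtract=subtract)
            vmi = decomp_image.synthesize_vmi(f_w, f_c, 70.0,
                                              bench_small.water,
                                              bench_small.calcium)
            biases[subtract] = abs(db.roi_stats(vmi, roi)[0])
        assert biases[True] < 0.2 * biases[False]


class TestImageBasedPipeline:
    def test_effective_energies_ordered_and_plausible(self, bench_mismatch):
        eps_le = bench_mismatch.effective_energy("LE")
        eps_he = bench_mismatch.effective_energy("HE")
        assert eps_le < eps_he
        assert 40.0 < eps_le < 80.0
        assert 55.0 < eps_he < 100.0

    def test_image_based_path_reconstructs_water_correctly(
            self, bench_mismatch, acr):
        """The comparator reproduces the water insert accurately at 70 keV
        even though its beam-hardening handling is only implicit."""
        raw_le, raw_he = bench_mismatch.simulate_pair(acr)
        g_w, g_c, _ = bench_mismatch.image_based_densities(raw_le, raw_he)
        vmi = decomp_image.synthesize_vmi(g_w, g_c, 70.0,
                                          bench_mismatch.water,
                                          bench_mismatch.calcium)
        roi = bench_mismatch.acr_rois()["water"][0]
        assert abs(db.roi_stats(vmi, roi)[0]) < 10.0


class TestNoiseBehavior:
    def test_interior_noise_minimum_and_seed_stability(self, bench_small,
                                                       acr):
        """VMI noise vs energy is parabolic with an interior minimum whose
        location is stable across seeds within one 5 keV step."""
        energies = np.arange(30.0, 141.0, 5.0)
        argmins = []
        for seed in (3, 4):
            n_le, n_he = bench_small.simulate_pair(acr, noisy=True, seed=seed)
            f_w, f_c, _ = bench_small.data_based_densities(
                n_le, n_he, scatter_mode="known")
            stack = [decomp_image.synthesize_vmi(f_w, f_c, e,
                                                 bench_small.water,
                                                 bench_small.calcium)
                     for e in energies]
            roi = bench_small.acr_rois()["water"][0]
            stds, argmin = evaluation.noise_energy_curve(stack, energies, roi)
            assert stds[0] > stds.min() and stds[-1] > stds.min()
            assert energies[0] < argmin < energies[-1]
            argmins.append(argmin)
        assert abs(argmins[0] - argmins[1]) <= 5.0


class TestExperimentRunners:
    def test_accuracy_experiment_reproducible(self, tiny_config, tmp_path):
        """Same config and seed produce byte-identical metric CSVs."""
        outs = []
        for run in ("a", "b"):
            run_accuracy_experiment(tiny_config, out_dir=tmp_path / run,
                                    seed=5, positions=("centered",),
                                    methods=("data-based",),
                                    include_noise=False)
            outs.append((tmp_path / run / "accuracy.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_accuracy_experiment_outputs(self, tiny_config, tmp_path):
        report = run_accuracy_experiment(
            tiny_config, out_dir=tmp_path / "acc", seed=1,
            positions=("centered",), methods=("data-based",),
            include_noise=False)
        df = report["tables"]["accuracy"]
        assert set(df.roi) == {"bone", "polyethylene", "acrylic", "air",
                               "water"}
        assert (tmp_path / "acc" / "report.json").exists()
        assert (tmp_path / "acc" / "config.cfg").exists()

    def test_scatter_ablation_detects_scatter(self, tmp_path):
        """With scatter on, skipping the subtraction shifts the water
        background by more than 5 HU; profile plumbing is consistent."""
        cfg = BenchConfig(n_projections=180, n_channels=92, n_pixels=128,
                          pixel_size_mm=2.0, n_channel_groups=8)
        report = run_scatter_ablation(cfg, out_dir=tmp_path / "abl", seed=1)
        assert report["max_abs_diff_water_hu_70"] > 5.0
        prof = report["tables"]["ablation_profile"]
        assert len(prof[prof.energy_kev == 50.0]) == cfg.n_pixels

    def test_ablation_without_scatter_is_noop(self, tmp_path):
        cfg = BenchConfig(n_projections=180, n_channels=92, n_pixels=128,
                          pixel_size_mm=2.0, n_channel_groups=8,
                          scatter_alpha=0.0, mismatch_constant=0.0)
        report = run_scatter_ablation(cfg, seed=1)
        assert report["max_abs_diff_water_hu_70"] < 0.5

    def test_conventional_comparison_outputs(self, bench_small, tmp_path):
        """The comparison emits the four VMI panels with a shared grayscale
        window and one ring-error row per variant (the error ordering itself
        is asserted at full scale in the acceptance suite)."""
        import dataclasses
        cfg = dataclasses.replace(bench_small.config, model_mismatch=True)
        report = run_conventional_comparison(cfg, out_dir=tmp_path / "conv",
                                             seed=1)
        mae = report["ring_mae_hu"]
        assert set(mae) == {"proposed", "proposed-central-only",
                            "conventional-cubic",
                            "conventional-constrained-quartic"}
        assert all(v > 0 for v in mae.values())
        windows = {img.meta.get("window", {}).get("width")
                   for name, img in report["images"].items()}
        assert windows == {400.0}
        assert (tmp_path / "conv" / "conventional_ring_mae.csv").exists()


    def test_position_consistency_report(self, tmp_path):
        """The abdomen-surrogate experiment reports the profile-overlap
        metric against its tolerance and writes both profiles."""
        cfg = BenchConfig(n_projections=180, n_channels=92, n_pixels=128,
                          n_channel_groups=8)
        report = run_position_consistency(cfg, out_dir=tmp_path / "pos",
                                          seed=1)
        assert report["tolerance_hu"] == 6.0
        assert np.isfinite(report["max_profile_diff_hu"])
        assert isinstance(report["within_tolerance"], bool)
        prof = report["tables"]["position_profiles"]
        assert {"centered_hu", "off_centered_hu"} <= set(prof.columns)
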