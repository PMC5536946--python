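"""Unit tests for the synthetic ground-truth generators."""

import numpy as np
import pytest

from nanopack.frap import extract_trace, fit_trace
from nanopack.simulate import (
    AntibodyModel,
    EfwbGroundTruth,
    FrapGroundTruth,
    ImagingConfig,
    QuenchGroundTruth,
    render_emitters,
    render_image_pair,
    simulate_antibody_binding,
    simulate_cluster_field,
    simulate_efwb_experiment,
    simulate_frap_stack,
    simulate_quench_pair,
)
from nanopack.simulate.clusters import _rsa_occupancy


class TestClusterField:
    def test_zero_density_gives_only_free_molecules(self):
        f = simulate_cluster_field(0.0, 10.0, free_molecule_density=5.0, seed=0)
        assert f.n_clusters == 0
        assert f.n_molecules > 0
        assert np.all(f.cluster_index == -1)

    def test_cluster_count_follows_poisson_process(self):
        # homogeneous Poisson process: E[count] = density * area
        expected = 16.0 * 12.96
        counts = [
            simulate_cluster_field(16.0, 12.96, molecules_dist=(1, 1), seed=s).n_clusters
            for s in range(200)
        ]
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_default_molecule_counts_in_range(self):
        f = simulate_cluster_field(16.0, 12.96, seed=3)
        assert np.all((f.molecules_per_cluster >= 50) & (f.molecules_per_cluster <= 75))
        assert np.all((f.cluster_radius_nm >= 25.0) & (f.cluster_radius_nm <= 30.0))

    def test_molecules_inside_cluster_disks(self):
        f = simulate_cluster_field(10.0, 4.0, seed=4)
        for k in range(f.n_clusters):
            pts = f.epitope_positions[f.cluster_index == k]
            d = np.linalg.norm(pts - f.cluster_centers[k], axis=1)
            assert np.all(d <= f.cluster_radius_nm[k] + 1e-9)

    @pytest.mark.parametrize("kwargs", [dict(density_per_um2=-1, area_um2=1),
                                        dict(density_per_um2=1, area_um2=0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            simulate_cluster_field(**kwargs)

    def test_hard_core_separation_respected(self):
        f = simulate_cluster_field(16.0, 12.96, seed=5, min_separation_nm=150.0)
        from scipy.spatial.distance import pdist

        assert pdist(f.cluster_centers).min() >= 150.0

    def test_reproducible(self):
        a = simulate_cluster_field(16.0, 4.0, seed=11)
        b = simulate_cluster_field(16.0, 4.0, seed=11)
        assert np.array_equal(a.epitope_positions, b.epitope_positions)


class TestAntibodyBinding:
    def test_mutual_exclusion_close_pair(self):
        f = simulate_cluster_field(0.0, 1.0, seed=0)
        f.epitope_positions = np.array([[500.0, 500.0], [504.0, 500.0]])
        f.cluster_index = np.array([-1, -1])
        out = simulate_antibody_binding(f, AntibodyModel(footprint_diameter_nm=10.0), seed=1)
        assert out.occupancy.sum() == 1

    def test_distant_pair_both_bind(self):
        f = simulate_cluster_field(0.0, 1.0, seed=0)
        f.epitope_positions = np.array([[500.0, 500.0], [512.0, 500.0]])
        f.cluster_index = np.array([-1, -1])
        out = simulate_antibody_binding(f, AntibodyModel(footprint_diameter_nm=10.0), seed=1)
        assert out.occupancy.sum() == 2

    def test_label_efficiency_zero_binds_nothing(self):
        f = simulate_cluster_field(4.0, 2.0, seed=2)
        out = simulate_antibody_binding(f, AntibodyModel(label_efficiency=0.0), seed=3)
        assert out.occupancy.sum() == 0

    def test_invalid_footprint(self):
        with pytest.raises(ValueError):
            AntibodyModel(footprint_diameter_nm=0.0)

    def test_reproducible_bit_identical(self):
        f = simulate_cluster_field(16.0, 2.0, seed=7)
        a = simulate_antibody_binding(f, AntibodyModel(label_efficiency=0.8), seed=8)
        b = simulate_antibody_binding(f, AntibodyModel(label_efficiency=0.8), seed=8)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_occupancy_monotone_in_packing_density(self):
        # tighter intra-cluster packing -> lower per-epitope occupancy
        fracs = []
        for n_mol in (10, 20, 40, 80):
            f = simulate_cluster_field(
                16.0, 4.0, molecules_dist=(n_mol, n_mol), seed=10
            )
            out = simulate_antibody_binding(f, AntibodyModel(), seed=11)
            fracs.append(out.occupancy.mean())
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_rsa_coverage_saturates_toward_jamming(self):
        # bound antibodies per area is bounded; the dense-candidate asymptote,
        # estimated from the simulation itself, is the hard-disk RSA jamming
        # coverage (~0.547)
        side, d = 500.0, 12.0
        disk_area = np.pi * (d / 2.0) ** 2
        ns = [4000, 8000, 16000, 32000, 64000]
        cov = []
        for n in ns:
            r = np.random.default_rng(42)
            pos = r.uniform(0, side, (n, 2))
            occ = _rsa_occupancy(pos, d, 1.0, r)
            cov.append(occ.sum() * disk_area / side**2)
        assert all(a < b for a, b in zip(cov, cov[1:]))  # approached from below
        assert max(cov) < 0.56
        # RSA kinetics: theta(t) ~ theta_J - c / sqrt(t); extrapolate
        x = 1.0 / np.sqrt(ns)
        slope, intercept = np.polyfit(x[-3:], cov[-3:], 1)
        assert slope < 0
        assert 0.50 < intercept < 0.60


class TestRendering:
    def test_zero_bound_antibodies_offset_only(self):
        f = simulate_cluster_field(0.0, 1.0, seed=0)
        f = simulate_antibody_binding(f, AntibodyModel(), seed=0)
        cfg = ImagingConfig(camera_offset=50.0)
        conf, sted = render_image_pair(f, cfg, noise=False)
        assert np.all(conf == 50.0) and np.all(sted == 50.0)

    def test_single_emitter_is_psf_gaussian(self):
        f = simulate_cluster_field(0.0, (64 * 20.0 / 1000.0) ** 2, seed=0)
        f.epitope_positions = np.array([[640.0 + 10.0, 640.0 + 10.0]])  # pixel 32 centre
        f.cluster_index = np.array([-1])
        f = simulate_antibody_binding(f, AntibodyModel(), seed=0)
        cfg = ImagingConfig(photon_scale=100.0, camera_offset=0.0)
        _, sted = render_image_pair(f, cfg, noise=False)
        assert np.unravel_index(sted.argmax(), sted.shape) == (32, 32)
        sigma_px = 60.0 / (2 * np.sqrt(2 * np.log(2))) / 20.0
        xs = np.arange(64) - 32.0
        expected = 100.0 * np.exp(-(xs**2) / (2 * sigma_px**2))
        # 5-sigma kernel truncation leaves ~3e-7 residuals at the patch edge
        assert np.allclose(sted[32, :], expected, atol=1e-6)

    def test_total_mass_matches_kernel_integral(self):
        # sum(noiseless - offset) = photon_scale * n_bound * 2 pi sigma_px^2
        rng = np.random.default_rng(5)
        area = (128 * 20.0 / 1000.0) ** 2
        f = simulate_cluster_field(0.0, area, seed=0)
        f.epitope_positions = rng.uniform(800, 1760, size=(7, 2))
        f.cluster_index = np.full(7, -1)
        f = simulate_antibody_binding(f, AntibodyModel(footprint_diameter_nm=1e-9), seed=1)
        assert f.occupancy.all()
        cfg = ImagingConfig(photon_scale=50.0, camera_offset=10.0)
        conf, sted = render_image_pair(f, cfg, noise=False)
        for img, fwhm in ((conf, 250.0), (sted, 60.0)):
            sigma_px = fwhm / (2 * np.sqrt(2 * np.log(2))) / 20.0
            mass = 50.0 * 7 * 2 * np.pi * sigma_px**2
            assert abs((img - 10.0).sum() - mass) / mass < 1e-3

    def test_rendering_linear_in_emitter_sets(self):
        shape = (48, 48)
        a = np.array([[300.0, 300.0], [500.0, 420.0]])
        b = np.array([[700.0, 640.0]])
        img_a = render_emitters(a, shape, 20.0, 60.0, 80.0)
        img_b = render_emitters(b, shape, 20.0, 60.0, 80.0)
        both = render_emitters(np.vstack([a, b]), shape, 20.0, 60.0, 80.0)
        assert np.allclose(both, img_a + img_b, atol=1e-12)


class TestFrapSimulator:
    def test_no_mobility_no_recovery(self):
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.0, immobile_fraction=0.0,
                            post_duration_s=30.0)
        res = simulate_frap_stack(t)
        post = res.roi_trace_truth[res.bleach_index:]
        assert np.allclose(post, post[0], atol=1e-12)

    def test_fluorescence_conserved_without_bleach(self):
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.2, bleach_depth=0.0,
                            post_duration_s=30.0)
        res = simulate_frap_stack(t)
        sums = res.stack.sum(axis=(1, 2))
        assert np.ptp(sums) / sums[0] < 1e-6

    def test_fluorescence_conserved_after_bleach(self):
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.2, post_duration_s=30.0)
        res = simulate_frap_stack(t)
        post_sums = res.stack[res.bleach_index:].sum(axis=(1, 2))
        assert np.ptp(post_sums) / post_sums[0] < 1e-6

    def test_stability_bound_refused_with_required_step(self):
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.4)
        with pytest.raises(ValueError, match="required step"):
            simulate_frap_stack(t, dt_s=10.0)

    def test_immobile_fraction_limits_recovery(self):
        # conservation argument: the mobile pool re-equilibrates to its
        # post-bleach grid mean, the immobile pool in the ROI stays bleached
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.4, immobile_fraction=0.3,
                            bleach_depth=0.9, post_duration_s=600.0)
        res = simulate_frap_stack(t)
        f, beta = 0.3, 0.9
        roi_area = t.roi_px**2
        grid_area = t.grid_px**2
        expected = (1 - f) * (1 - beta * roi_area / grid_area) + f * (1 - beta)
        assert abs(res.roi_trace_truth[-1] - expected) < 0.02

    def test_trace_extraction_matches_simulator_bookkeeping(self):
        t = FrapGroundTruth(diffusion_coeff_um2_s=0.1, post_duration_s=60.0)
        res = simulate_frap_stack(t, noise_sd=2.0, seed=1)
        lo = res.roi_slice[0].start
        tr = extract_trace(
            res.stack,
            (lo, lo, t.roi_px, t.roi_px),
            (4, 4, 12, 12),
            (78, 4, 12, 12),
            times_s=res.times_s,
        )
        # the simulated field is uniformly fluorescent, so the background ROI
        # subtracts one intensity_scale worth of signal from the trace
        truth = t.intensity_scale * (res.roi_trace_truth - 1.0)
        assert np.abs(tr.roi_intensity - truth).max() < 5.0  # within noise

    def test_halftime_halves_when_diffusion_doubles(self):
        halves = []
        for d in (0.1, 0.2):
            res = simulate_frap_stack(FrapGroundTruth(diffusion_coeff_um2_s=d))
            tr = extract_trace(res.stack, (42, 42, 12, 12), (8, 8, 12, 12),
                               (80, 8, 12, 12), times_s=res.times_s)
            halves.append(fit_trace(tr).t_half_s)
        assert abs(halves[0] / halves[1] - 2.0) < 0.2  # within 10%


class TestQuenchAndEfwb:
    def test_full_quench_kills_cell_signal(self):
        truth = QuenchGroundTruth(surface_fraction=1.0, quench_efficiency=1.0,
                                  n_cells=4, amplitude_cv=0.0, seed=0)
        cfg = ImagingConfig(camera_offset=10.0)
        i74, i43, mask, _ = simulate_quench_pair(truth, cfg, noise=False)
        assert np.all(i43[mask > 0] == 10.0)
        assert np.all(i74[mask > 0] == 510.0)

    def test_remaining_fraction_arithmetic(self):
        truth = QuenchGroundTruth(surface_fraction=0.7, quench_efficiency=1.0)
        assert truth.remaining_fraction == pytest.approx(0.30)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            QuenchGroundTruth(surface_fraction=1.2)

    def test_noiseless_efwb_ratio_exact(self):
        truth = EfwbGroundTruth(n_pairs=5, noise_cv=0.0,
                                accessibility={"reference": 0.2, "variant": 0.6})
        ef, wb = simulate_efwb_experiment(truth, seed=0)
        ef = ef.set_index(["pair_id", "construct"])["ef_value"]
        wb = wb.set_index(["pair_id", "construct"])
        for pid in range(5):
            r_ref = ef[pid, "reference"] / (
                wb.loc[(pid, "reference"), "band_intensity"]
                / wb.loc[(pid, "reference"), "loading_control"]
            )
            r_var = ef[pid, "variant"] / (
                wb.loc[(pid, "variant"), "band_intensity"]
                / wb.loc[(pid, "variant"), "loading_control"]
            )
            assert r_var / r_ref == pytest.approx(3.0, rel=1e-12)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            EfwbGroundTruth(n_pairs=0)
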