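"""PSF extraction: detection/filter soundness against simulator truth,
sub-pixel localization against a supersampled center-of-mass oracle, and
FWHM metrics against closed forms."""

import numpy as np
import pandas as pd
import pytest

import triscope as t
from triscope.psf import (
    FWHM_PER_SIGMA,
    average_psf,
    extract_subvolume,
    filter_outliers_pearson,
    find_beads,
    fit_gaussian_1d,
    localize_bead,
    max_project_z,
    measure_psf,
    run_psf_pipeline,
    subvolume_halfwidth,
    upsample_volume,
)
from triscope.simulate import sim_bead_stack


def _gauss_volume(shape, center, sigmas, amplitude=1000.0, offset=10.0):
    """(z, y, x) separable Gaussian; center and sigmas ordered (x, y, z)."""
    nz, ny, nx = shape
    x0, y0, z0 = center
    sx, sy, sz = sigmas
    zz = np.exp(-((np.arange(nz) - z0) ** 2) / (2 * sz**2))
    yy = np.exp(-((np.arange(ny) - y0) ** 2) / (2 * sy**2))
    xx = np.exp(-((np.arange(nx) - x0) ** 2) / (2 * sx**2))
    return offset + amplitude * zz[:, None, None] * yy[None, :, None] * xx[None, None, :]


class TestProjection:
    def test_single_plane_projection_is_that_plane(self):
        vol = np.random.default_rng(0).random((1, 8, 8))
        np.testing.assert_array_equal(max_project_z(vol), vol[0])

    def test_two_beads_at_different_z_both_visible(self):
        vol = np.zeros((5, 16, 16))
        vol[1, 4, 4] = 3.0
        vol[3, 10, 12] = 2.0
        proj = max_project_z(vol)
        # per-pixel max oracle
        np.testing.assert_array_equal(proj, vol.max(axis=0))
        assert proj[4, 4] == 3.0 and proj[10, 12] == 2.0


class TestSubvolumeHalfwidth:
    def test_stated_example_arithmetic(self):
        cfg = t.OpticalConfig()  # lambda 520, NA 0.85, 65 nm/px, 50 nm steps
        hxy, hz = subvolume_halfwidth(cfg, k_xy=3.0, k_z=2.0)
        assert hxy == 15  # ceil(3*520/(2*0.85)/65)
        assert hz == 29  # ceil(2*520/0.85^2/50)

    def test_doubling_pixel_size_roughly_halves_lateral_halfwidth(self):
        a, _ = subvolume_halfwidth(t.OpticalConfig(pixel_size=65.0))
        b, _ = subvolume_halfwidth(t.OpticalConfig(pixel_size=130.0))
        assert abs(a - 2 * b) <= 1  # ceiling slack

    def test_degenerate_k_factors_rejected(self):
        with pytest.raises(ValueError):
            subvolume_halfwidth(t.OpticalConfig(), k_xy=0.0)

    def test_axial_window_exceeding_stack_rejected(self):
        cfg = t.OpticalConfig(z_range=(-500.0, 500.0), z_step=100.0)
        with pytest.raises(ValueError, match="axial"):
            subvolume_halfwidth(cfg)


class TestFindBeads:
    def test_single_clean_blob(self):
        proj = _gauss_volume((1, 64, 64), (30.0, 33.0, 0.0), (2.5, 2.5, 1.0))[0]
        cands = find_beads(proj, min_separation_px=10, border_margin_px=8)
        assert len(cands) == 1 and cands[0].clean
        assert cands[0].x == pytest.approx(30.0, abs=0.2)

    def test_double_intensity_cluster_flagged_by_mass(self):
        proj = (
            _gauss_volume((1, 96, 96), (25.0, 30.0, 0.0), (2.5, 2.5, 1.0),
                          amplitude=100.0, offset=0.0)[0]
            + _gauss_volume((1, 96, 96), (70.0, 60.0, 0.0), (2.5, 2.5, 1.0),
                            amplitude=200.0, offset=0.0)[0]
        )
        # brute-force pixel-sum oracle for the two masses
        mass_single = proj[22:39, 17:34].sum()
        mass_double = proj[52:69, 62:79].sum()
        assert mass_double == pytest.approx(2 * mass_single, rel=0.05)
        cands = find_beads(proj, min_separation_px=12, border_margin_px=8,
                           min_mass=0.5 * mass_single, max_mass=1.5 * mass_single,
                           mass_radius_px=8)
        flagged = {round(c.x): c.flags for c in cands}
        assert flagged[25] == set()
        assert "mass_high" in flagged[70]

    def test_close_pair_both_flagged_proximal(self):
        proj = (
            _gauss_volume((1, 64, 64), (28.0, 32.0, 0.0), (2.0, 2.0, 1.0), offset=0.0)[0]
            + _gauss_volume((1, 64, 64), (40.0, 32.0, 0.0), (2.0, 2.0, 1.0), offset=0.0)[0]
            + _gauss_volume((1, 64, 64), (10.0, 52.0, 0.0), (2.0, 2.0, 1.0), offset=0.0)[0]
        )
        cands = find_beads(proj, min_separation_px=24, border_margin_px=4)
        by_x = {round(c.x): c for c in cands}
        assert "proximal" in by_x[28].flags and "proximal" in by_x[40].flags
        assert "proximal" not in by_x[10].flags

    def test_no_unflagged_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="threshold"):
            find_beads(np.zeros((32, 32)), min_separation_px=5, border_margin_px=3)


class TestPearsonFilter:
    def test_identical_subvolumes_all_kept(self):
        sv = _gauss_volume((9, 15, 15), (7.0, 7.0, 4.0), (2.0, 2.0, 1.5))
        kept, rejected = filter_outliers_pearson([sv] * 5)
        assert len(kept) == 5 and rejected == []

    def test_doublet_is_the_rejected_minimum(self):
        sv = _gauss_volume((9, 15, 15), (7.0, 7.0, 4.0), (2.0, 2.0, 1.5))
        doublet = sv + _gauss_volume((9, 15, 15), (3.0, 11.0, 4.0), (2.0, 2.0, 1.5),
                                     offset=0.0)
        subvols = [sv] * 4 + [doublet]
        # brute-force check that the doublet has the minimum median r
        mips = [v.max(axis=0).ravel() for v in subvols]
        r = np.corrcoef(np.stack(mips))
        med = [np.median(np.delete(r[i], i)) for i in range(5)]
        assert np.argmin(med) == 4
        kept, rejected = filter_outliers_pearson(subvols)
        assert rejected == [4] and len(kept) == 4

    def test_two_dissimilar_subvolumes_rejected_as_degenerate(self):
        a = _gauss_volume((9, 15, 15), (4.0, 4.0, 4.0), (1.5, 1.5, 1.5))
        rng = np.random.default_rng(0)
        b = rng.random((9, 15, 15))
        with pytest.raises(ValueError, match="rejected"):
            filter_outliers_pearson([a, b])


class TestLocalize:
    def test_subpixel_offsets_recovered_within_tolerance(self):
        center = (15.30, 14.55, 15.40)  # (x, y, z)
        sv = _gauss_volume((31, 31, 31), center, (2.5, 2.5, 3.0))
        # oracle: center of mass of a 10x supersampled noiseless rendering
        f = 10
        zz = np.arange(31 * f) / f
        g = lambda u, c, s: np.exp(-((u - c) ** 2) / (2 * s**2))
        com = [float((g(zz, c, s) * zz).sum() / g(zz, c, s).sum())
               for c, s in zip(center, (2.5, 2.5, 3.0))]
        np.testing.assert_allclose(com, center, atol=0.01)
        x, y, z = localize_bead(sv)
        assert x == pytest.approx(com[0], abs=0.05)
        assert y == pytest.approx(com[1], abs=0.05)
        assert z == pytest.approx(com[2], abs=0.1)

    def test_centered_blob_at_exact_center(self):
        sv = _gauss_volume((15, 15, 15), (7.0, 7.0, 7.0), (2.0, 2.0, 2.0))
        x, y, z = localize_bead(sv)
        assert (x, y, z) == pytest.approx((7.0, 7.0, 7.0), abs=1e-6)

    def test_flat_subvolume_raises_fit_error(self):
        with pytest.raises(t.FitError):
            localize_bead(np.full((7, 9, 9), 5.0))


class TestAveraging:
    def test_single_centered_subvolume_is_upsampled_input(self):
        sv = _gauss_volume((11, 11, 11), (5.0, 5.0, 5.0), (2.0, 2.0, 2.0))
        out = average_psf([sv], [(5.0, 5.0, 5.0)], pixel_size=65.0, z_step=50.0)
        expected = upsample_volume(sv, 5)
        np.testing.assert_allclose(out.volume, expected / expected.max(), atol=1e-12)
        assert out.voxel_size == (10.0, 13.0, 13.0)

    def test_random_subpixel_offsets_widen_by_at_most_one_upsampled_voxel(self):
        rng = np.random.default_rng(3)
        sigma = 2.2
        svs, positions = [], []
        for _ in range(6):
            dx, dy, dz = rng.uniform(-0.5, 0.5, 3)
            c = (10.0 + dx, 10.0 + dy, 10.0 + dz)
            svs.append(_gauss_volume((21, 21, 21), c, (sigma, sigma, sigma)))
            positions.append(c)
        avg = average_psf(svs, positions, pixel_size=65.0, z_step=65.0)
        metrics = measure_psf(avg)
        single = FWHM_PER_SIGMA * sigma * 65.0
        assert abs(metrics.fwhm_x - single) <= 65.0 / 5 + 1e-6
        assert abs(metrics.fwhm_z - single) <= 65.0 / 5 + 1e-6

    def test_noise_shrinks_with_replicate_count(self):
        rng = np.random.default_rng(4)
        clean = _gauss_volume((9, 15, 15), (7.0, 7.0, 4.0), (2.0, 2.0, 1.5),
                              amplitude=1.0, offset=0.0)

        def residual_sd(n):
            svs = [clean + rng.normal(0, 0.02, clean.shape) for _ in range(n)]
            avg = average_psf(svs, [(7.0, 7.0, 4.0)] * n, pixel_size=65.0,
                              z_step=50.0, interpolation="nearest")
            ref = average_psf([clean], [(7.0, 7.0, 4.0)], pixel_size=65.0,
                              z_step=50.0, interpolation="nearest")
            return float((avg.volume - ref.volume).std())

        ratio = residual_sd(16) / residual_sd(4)
        assert 0.3 < ratio < 0.7  # ~ 1/sqrt(4)

    def test_mixed_shapes_rejected(self):
        a = _gauss_volume((9, 15, 15), (7, 7, 4), (2, 2, 1.5))
        b = _gauss_volume((9, 13, 13), (6, 6, 4), (2, 2, 1.5))
        with pytest.raises(ValueError, match="shape"):
            average_psf([a, b], [(7, 7, 4), (6, 6, 4)], pixel_size=65.0, z_step=50.0)


class TestMetrics:
    def test_closed_form_fwhm_recovered_within_2_percent(self):
        sigma = 3.0
        vol = _gauss_volume((31, 31, 31), (15.0, 15.0, 15.0), (sigma, sigma, sigma),
                            amplitude=1.0, offset=0.0)
        psf = t.AveragedPSF(volume=vol / vol.max(), voxel_size=(10.0, 13.0, 13.0),
                            n_beads=1)
        m = measure_psf(psf)
        assert m.fwhm_x == pytest.approx(FWHM_PER_SIGMA * sigma * 13.0, rel=0.02)
        assert m.fwhm_z == pytest.approx(FWHM_PER_SIGMA * sigma * 10.0, rel=0.02)

    def test_widefield_pipeline_ellipticity_near_unity(self, small_config):
        stack, _ = sim_bead_stack(small_config, n_beads=6, noise_sd=1.0,
                                  field_shape=(200, 200), seed=21)
        res = run_psf_pipeline(stack, small_config)
        ell = res.metrics.ellipticity_vs_z.ellipticity
        assert np.all((ell > 0.95) & (ell < 1.05))

    def test_astigmatic_pipeline_ellipticity_crosses_unity(self, small_config):
        cfg = t.OpticalConfig(z_range=small_config.z_range,
                              z_step=small_config.z_step, cyl_theta=92.0)
        stack, _ = sim_bead_stack(cfg, n_beads=6, noise_sd=1.0,
                                  field_shape=(200, 200), seed=22)
        res = run_psf_pipeline(stack, cfg)
        e = res.metrics.ellipticity_vs_z
        above = e[e.defocus_nm > 150].ellipticity
        below = e[e.defocus_nm < -150].ellipticity
        assert (above.mean() - 1.0) * (below.mean() - 1.0) < 0


class TestPipeline:
    def test_clean_stack_all_beads_found_and_averaged(self, small_config):
        stack, truth = sim_bead_stack(small_config, n_beads=10, noise_sd=1.0,
                                      field_shape=(256, 256), seed=30)
        res = run_psf_pipeline(stack, small_config)
        assert res.qc["found"] == 10 and res.qc["averaged"] == 10
        assert res.qc["mass_high"] == res.qc["border"] == res.qc["proximal"] == 0

    def test_clusters_and_border_beads_excluded_matching_truth(self, small_config):
        stack, truth = sim_bead_stack(small_config, n_beads=10, n_clusters=2,
                                      n_border=2, noise_sd=1.0,
                                      field_shape=(256, 256), seed=31)
        res = run_psf_pipeline(stack, small_config)
        assert res.qc["found"] == 14
        assert res.qc["mass_high"] == (truth.kind == "cluster").sum() == 2
        assert res.qc["border"] == (truth.kind == "border").sum() == 2
        assert res.qc["averaged"] == 10

    def test_empty_stack_is_an_error(self, small_config):
        empty = t.BeadStack(volume=np.zeros((31, 64, 64)), pixel_size=65.0,
                            z_step=100.0, wavelength=520.0, na=0.85)
        with pytest.raises(ValueError):
            run_psf_pipeline(empty, small_config)
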