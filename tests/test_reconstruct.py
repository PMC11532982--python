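"""Projection/back-projection operators and tomogram reconstruction."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from tomopipe.geometry import ProjectionModel, TiltProjection
from tomopipe.metadata import ValidationError
from tomopipe.mrc import read_mrc
from tomopipe.reconstruct import (
    TomogramGrid,
    backproject,
    backproject_weighted,
    forward_project,
    reconstruct_tomograms,
)

TILT_AXIS = 85.0


def central_slice_projection(volume, img, pad=4):
    """Independent oracle: extract the central Fourier slice of the
    (zero-padded) volume along the image's orientation and invert it."""
    n = volume.shape[0]
    N = n * pad
    big = np.zeros((N, N, N))
    s = slice(N // 2 - n // 2, N // 2 + n // 2)
    big[s, s, s] = volume
    V = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(big)))
    f1 = np.fft.fftshift(np.fft.fftfreq(n))
    fy, fx = np.meshgrid(f1, f1, indexing="ij")
    r = img.rotation()
    q = fx[..., None] * r[0] + fy[..., None] * r[1]
    idx = q * N + N // 2
    coords = [idx[..., 2], idx[..., 1], idx[..., 0]]
    slc = map_coordinates(V.real, coords, order=1) + 1j * map_coordinates(V.imag, coords, order=1)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(slc))).real


def smooth_phantom(n, seed=7, n_blobs=6, sigma=2.0):
    rng = np.random.default_rng(seed)
    ax = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    v = np.zeros((n, n, n))
    for c in rng.uniform(-n / 4, n / 4, size=(n_blobs, 3)):
        v += np.exp(-((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2) / (2 * sigma**2))
    return v


class TestForwardProject:
    def test_zero_angles_is_z_sum(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 8, 8))
        img = forward_project(v, 1.0, ProjectionModel([TiltProjection()]), (8, 8))[0]
        np.testing.assert_allclose(img, v.sum(axis=0), atol=1e-12)

    def test_supersampling_preserves_total_intensity(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(8, 8, 8))
        m = ProjectionModel([TiltProjection()])
        # image larger than the volume footprint so no splat mass is clipped
        img1 = forward_project(v, 1.0, m, (16, 16), supersample=1)[0]
        img2 = forward_project(v, 1.0, m, (16, 16), supersample=2)[0]
        assert img2.sum() == pytest.approx(img1.sum(), rel=1e-9)
        np.testing.assert_allclose(img1[4:12, 4:12], v.sum(axis=0), atol=1e-12)

    def test_central_delta_lands_on_shifts(self):
        v = np.zeros((16, 16, 16))
        v[8, 8, 8] = 1.0
        m = ProjectionModel([TiltProjection(dx_A=3.0, dy_A=-2.0)])
        img = forward_project(v, 1.0, m, (16, 16))[0]
        y, x = np.unravel_index(img.argmax(), img.shape)
        assert (x, y) == (8 + 3, 8 - 2)

    def test_matches_central_slice_extraction(self):
        """Agreement with the slice-theorem oracle at 32^3 over the tilt
        range, for both an oblique and a near-axial tilt-axis angle."""
        n = 32
        v = smooth_phantom(n)
        for theta_z in (30.0, TILT_AXIS):
            model = ProjectionModel(
                [TiltProjection(theta_y_deg=t, theta_z_deg=theta_z) for t in (-60, -30, 0, 30, 60)]
            )
            proj = forward_project(v, 1.0, model, (n, n), supersample=2)
            for i, img in enumerate(model):
                oracle = central_slice_projection(v, img)
                err = np.linalg.norm(proj[i] - oracle) / np.linalg.norm(oracle)
                assert err < 0.05, f"theta_z={theta_z} tilt={img.theta_y_deg}: {err:.4f}"

    def test_linear_in_volume(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 8, 8, 8))
        m = ProjectionModel([TiltProjection(theta_y_deg=30, theta_z_deg=40)])
        lhs = forward_project(2 * a - b, 1.0, m, (8, 8))
        rhs = 2 * forward_project(a, 1.0, m, (8, 8)) - forward_project(b, 1.0, m, (8, 8))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.zeros((8, 8, 8)), 1.0, ProjectionModel([]), (8, 8))


class TestAdjointness:
    @pytest.mark.parametrize("supersample", [1, 2])
    def test_forward_and_unweighted_backprojection_are_adjoint(self, supersample):
        rng = np.random.default_rng(11)
        vol = rng.normal(size=(16, 16, 16))
        model = ProjectionModel(
            [
                TiltProjection(*rng.uniform(-50, 50, 3), *rng.uniform(-3, 3, 2))
                for _ in range(6)
            ]
        )
        imgs = rng.normal(size=(6, 16, 16))
        P = forward_project(vol, 1.0, model, (16, 16), supersample=supersample)
        B = backproject(imgs, model, TomogramGrid(16, 16, 16), weighting="none",
                        supersample=supersample)
        lhs = float(np.vdot(P, imgs))
        rhs = float(np.vdot(vol, B))
        assert abs(lhs - rhs) / abs(lhs) < 1e-4


class TestBackproject:
    def test_single_zero_tilt_delta_constant_along_z(self):
        img = np.zeros((16, 16))
        img[5, 9] = 1.0
        rec = backproject(img[None], ProjectionModel([TiltProjection()]),
                          TomogramGrid(16, 16, 16), weighting="none")
        np.testing.assert_allclose(rec[:, 5, 9], 1.0)
        rec[:, 5, 9] = 0.0
        np.testing.assert_allclose(rec, 0.0, atol=1e-12)

    def test_linear_operator(self):
        rng = np.random.default_rng(3)
        model = ProjectionModel([TiltProjection(theta_y_deg=t, theta_z_deg=TILT_AXIS)
                                 for t in (-30, 0, 30)])
        i1, i2 = rng.normal(size=(2, 3, 16, 16))
        grid = TomogramGrid(16, 16, 16)
        lhs = backproject_weighted(0.5 * i1 + 2.0 * i2, model, grid)
        rhs = 0.5 * backproject_weighted(i1, model, grid) + 2.0 * backproject_weighted(i2, model, grid)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backproject(np.zeros((2, 8, 8)), ProjectionModel([TiltProjection()]),
                        TomogramGrid(8, 8, 8))

    def test_phantom_reconstruction_correlates_in_measured_wedge(self):
        """Forward-project a phantom over ±60°/3°, reconstruct, compare in
        the measured region of Fourier space (single-axis wedge)."""
        n = 64
        v = smooth_phantom(n, seed=3, n_blobs=10, sigma=2.5)
        tilts = np.arange(-60, 61, 3)
        model = ProjectionModel([TiltProjection(theta_y_deg=t, theta_z_deg=TILT_AXIS)
                                 for t in tilts])
        proj = forward_project(v, 1.0, model, (n, n))
        rec = backproject_weighted(proj, model, TomogramGrid(n, n, n))
        f1 = np.fft.fftshift(np.fft.fftfreq(n))
        fz, fy, fx = np.meshgrid(f1, f1, f1, indexing="ij")
        # stage tilt rotates about the specimen y axis: wedge in (fx, fz)
        measured = np.abs(fz) <= np.tan(np.deg2rad(60)) * np.abs(fx) + 1e-12
        V = (np.fft.fftshift(np.fft.fftn(v)) * measured).ravel()
        R = (np.fft.fftshift(np.fft.fftn(rec)) * measured).ravel()
        cc = np.abs(np.vdot(V, R)) / (np.linalg.norm(V) * np.linalg.norm(R))
        assert cc >= 0.8

    def test_missing_wedge_power_suppressed(self):
        """Deep inside the unmeasured wedge the apodised power spectrum of a
        noiseless reconstruction sits >=40 dB below the measured region, and
        power decays monotonically as the wedge boundary is crossed.

        Points close to the tilt axis (fy) belong to every central slice and
        are excluded via the perpendicular radius; apodisation removes the
        cube-window sinc spill that would otherwise mask the true wedge
        content."""
        n = 64
        v = gaussian_filter(np.random.default_rng(0).normal(size=(n, n, n)), 1.5)
        tilts = np.arange(-60, 61, 3)
        model = ProjectionModel([TiltProjection(theta_y_deg=t, theta_z_deg=TILT_AXIS)
                                 for t in tilts])
        rec = backproject_weighted(
            forward_project(v, 1.0, model, (n, n), supersample=2), model,
            TomogramGrid(n, n, n), supersample=2,
        )
        w1 = np.hanning(n)
        P = np.abs(np.fft.fftshift(np.fft.fftn(
            rec * w1[:, None, None] * w1[None, :, None] * w1[None, None, :]))) ** 2
        f1 = np.fft.fftshift(np.fft.fftfreq(n))
        fz, fy, fx = np.meshgrid(f1, f1, f1, indexing="ij")
        rho = np.sqrt(fx**2 + fz**2)  # radius perpendicular to the tilt axis
        ang = np.degrees(np.arctan2(np.abs(fz), np.abs(fx)))
        band = (rho > 0.08) & (rho < 0.3)
        in_mean = P[band & (ang < 45)].mean()
        deep_mean = P[band & (ang > 78)].mean()
        assert 10 * np.log10(in_mean / deep_mean) >= 40.0
        shells = [P[band & (ang >= lo) & (ang < lo + 5)].mean() for lo in range(60, 80, 5)]
        assert all(b < a for a, b in zip(shells, shells[1:]))

    def test_bitwise_deterministic(self):
        rng = np.random.default_rng(5)
        model = ProjectionModel([TiltProjection(theta_y_deg=t, theta_z_deg=TILT_AXIS)
                                 for t in (-30, 0, 30)])
        imgs = rng.normal(size=(3, 16, 16))
        a = backproject_weighted(imgs, model, TomogramGrid(16, 16, 16))
        b = backproject_weighted(imgs, model, TomogramGrid(16, 16, 16))
        assert np.array_equal(a, b)


class TestReconstructTomograms:
    def _aligned_set(self, sim_project, sim):
        from tomopipe.metadata import OpticsSettings, import_from_mdoc

        tss = import_from_mdoc(
            [sim_project["mdoc"]], sim_project["frames"],
            OpticsSettings(tilt_series_pixel_size_A=2.0, movie_pixel_size_A=2.0),
        )
        for tomo in tss:
            for img in tomo.tilt_images:
                img.x_tilt_deg = 0.0
                img.y_tilt_deg = img.nominal_stage_tilt_deg
                img.z_rot_deg = img.nominal_tilt_axis_deg
                img.x_shift_A = 0.0
                img.y_shift_A = 0.0
        return tss

    def test_binned_voxel_size_in_mrc_header(self, sim_project, tmp_path):
        """Binning 5 of a 2 Å series gives 10 Å voxels, the scale typically
        used for picking."""
        tss = self._aligned_set(sim_project, sim_project["sim"])
        out = reconstruct_tomograms(tss, (30, 30, 30), binning=5.0,
                                    out_dir=tmp_path / "rec", with_ctf=False)
        tomo = out.tomograms[0]
        m = read_mrc(tmp_path / "rec" / tomo.tomogram_path)
        assert m.voxel_size_A == pytest.approx(10.0)
        assert m.data.shape == (6, 6, 6)
        assert tomo.tomogram_binning == pytest.approx(5.0)
        assert (tomo.size_x, tomo.size_y, tomo.size_z) == (30, 30, 30)

    def test_scale_factor_column_is_cosine_of_tilt(self, sim_project, tmp_path):
        from tomopipe.ctf import ctf_scale_factor

        tss = self._aligned_set(sim_project, sim_project["sim"])
        out = reconstruct_tomograms(tss, (16, 16, 16), binning=2.0,
                                    out_dir=tmp_path / "rec", with_ctf=False)
        for img in out.tomograms[0].tilt_images:
            assert img.ctf_scale_factor == pytest.approx(
                ctf_scale_factor(img.y_tilt_deg), abs=1e-6
            )

    def test_halves_bookkeeping_and_linearity(self, sim_project, tmp_path):
        tss = self._aligned_set(sim_project, sim_project["sim"])
        out = reconstruct_tomograms(tss, (32, 32, 32), binning=1.0,
                                    out_dir=tmp_path / "rec", with_halves=True,
                                    with_ctf=False)
        tomo = out.tomograms[0]
        assert tomo.half1_path and tomo.half2_path
        h1 = read_mrc(tmp_path / "rec" / tomo.half1_path).data.astype(np.float64)
        h2 = read_mrc(tmp_path / "rec" / tomo.half2_path).data.astype(np.float64)
        full = read_mrc(tmp_path / "rec" / tomo.tomogram_path).data.astype(np.float64)
        err = np.linalg.norm((h1 + h2) / 2 - full) / np.linalg.norm(full)
        assert err < 1e-6

    def test_missing_alignment_names_series(self, sim_project, tmp_path):
        from tomopipe.metadata import OpticsSettings, import_from_mdoc

        tss = import_from_mdoc(
            [sim_project["mdoc"]], sim_project["frames"],
            OpticsSettings(tilt_series_pixel_size_A=10.0, movie_pixel_size_A=10.0),
        )
        with pytest.raises(ValidationError, match="TS_01.*lack alignment"):
            reconstruct_tomograms(tss, (16, 16, 16), 1.0, tmp_path / "rec")


class TestEvenOddIndependence:
    def test_pure_noise_half_tomograms_are_uncorrelated(self):
        """Even/odd half reconstructions of pure independent noise have a
        Fourier-shell correlation consistent with zero."""
        from tomopipe.simulate import SimulationConfig, make_phantom, simulate_tilt_series

        cfg = SimulationConfig(seed=21, volume_size=32, voxel_size_A=10.0,
                               n_beads=0, bead_positions_A=[], noise_sigma=1.0,
                               with_ctf=False)
        sim = simulate_tilt_series(make_phantom(cfg), cfg)
        grid = TomogramGrid(32, 32, 32, voxel_size_A=10.0)
        h1 = backproject_weighted(sim.even, sim.model, grid, pixel_size_A=10.0)
        h2 = backproject_weighted(sim.odd, sim.model, grid, pixel_size_A=10.0)
        F1 = np.fft.fftshift(np.fft.fftn(h1))
        F2 = np.fft.fftshift(np.fft.fftn(h2))
        f1 = np.fft.fftshift(np.fft.fftfreq(32))
        fz, fy, fx = np.meshgrid(f1, f1, f1, indexing="ij")
        freq = np.sqrt(fx**2 + fy**2 + fz**2)
        fscs = []
        for lo in np.arange(0.1, 0.4, 0.05):
            sel = (freq >= lo) & (freq < lo + 0.05)
            num = np.real(np.vdot(F1[sel], F2[sel]))
            den = np.linalg.norm(F1[sel]) * np.linalg.norm(F2[sel])
            fscs.append(num / den)
        # each shell has thousands of samples; 3 sigma of a zero-true FSC
        assert abs(np.mean(fscs)) < 0.05
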