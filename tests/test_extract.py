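"""Particle extraction: visibility filters, stack/pseudo-subtomogram
geometry, disc-space accounting, determinism."""

import numpy as np
import pytest

from tomopipe.extract import (
    ExtractionSpec,
    extract_2d_stack,
    extract_pseudo_subtomogram,
    run_extraction,
    visible_images,
)
from tomopipe.geometry import ProjectionModel, TiltProjection
from tomopipe.metadata import ParticleRecord
from tomopipe.reconstruct import _series_model
from tomopipe.simulate import SimulationConfig, make_phantom, simulate_tilt_series

from .conftest import ground_truth_tomogram


def bead_setup(bead_A, seed=0, hand=-1, noise=0.0, tilt_axis=85.0, size=64):
    """Simulate one tilt series containing a single bead at a known spot."""
    snapped = tuple(np.round(np.asarray(bead_A) / 10.0) * 10.0)
    cfg = SimulationConfig(seed=seed, volume_size=size, voxel_size_A=10.0,
                           noise_sigma=noise, bead_positions_A=[snapped],
                           hand=hand, tilt_axis_deg=tilt_axis)
    sim = simulate_tilt_series(make_phantom(cfg), cfg)
    tomo = ground_truth_tomogram(sim)
    particle = ParticleRecord(cfg.name, *snapped)
    return sim, tomo, particle


class TestVisibleImages:
    def _ctx(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        model = _series_model(tomo)
        return sim, tomo, particle, model

    def test_centre_particle_visible_everywhere(self):
        sim, tomo, particle, model = self._ctx()
        spec = ExtractionSpec(box_px=32, crop_px=16)
        vis = visible_images(particle, tomo, spec, model, (64, 64))
        assert vis == list(range(len(tomo.tilt_images)))

    def test_max_dose_cuts_late_images(self):
        sim, tomo, particle, model = self._ctx()
        # dose-symmetric schedule: only the first-acquired image is below 1.5
        spec = ExtractionSpec(box_px=32, crop_px=16, max_dose_e_per_A2=1.5)
        vis = visible_images(particle, tomo, spec, model, (64, 64))
        assert len(vis) == 1
        assert tomo.tilt_images[vis[0]].pre_exposure_e_per_A2 == 0.0

    def test_high_particle_loses_extreme_tilts(self):
        # a particle near the top of the tomogram projects near the image
        # centre at zero tilt but sweeps out of the field of view (x' =
        # z*sin(tilt)) as the stage tilt grows
        sim, tomo, particle = bead_setup((0.0, 0.0, 310.0), tilt_axis=0.0)
        model = _series_model(tomo)
        spec = ExtractionSpec(box_px=32, crop_px=16)
        vis = visible_images(particle, tomo, spec, model, (64, 64))
        n_imgs = len(tomo.tilt_images)
        assert 0 < len(vis) < n_imgs
        lost = sorted(set(range(n_imgs)) - set(vis))
        tilts = [abs(tomo.tilt_images[i].nominal_stage_tilt_deg) for i in lost]
        assert min(tilts) >= 45.0
        # the zero-tilt image is always kept
        assert any(tomo.tilt_images[i].nominal_stage_tilt_deg == 0.0 for i in vis)

    def test_filter_monotonicity(self):
        sim, tomo, particle, model = self._ctx()
        sizes = []
        for dose in (None, 50.0, 20.0, 5.0):
            spec = ExtractionSpec(box_px=32, crop_px=16, max_dose_e_per_A2=dose)
            sizes.append(len(visible_images(particle, tomo, spec, model, (64, 64))))
        assert sizes == sorted(sizes, reverse=True)


class TestExtract2D:
    def test_bead_recentred_on_every_visible_image(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            hand = int(rng.choice([-1, 1]))
            bead = rng.uniform(-120, 120, 3)
            sim, tomo, particle = bead_setup(bead, seed=trial, hand=hand,
                                             tilt_axis=float(rng.uniform(0, 180)))
            spec = ExtractionSpec(box_px=32, crop_px=16)
            stack, meta = extract_2d_stack(particle, tomo, sim.images, spec, hand)
            c = spec.crop_px // 2
            for k in range(len(stack)):
                sl = np.abs(stack[k].astype(np.float64))
                py, px = np.unravel_index(sl.argmax(), sl.shape)
                assert max(abs(px - c), abs(py - c)) <= 1

    def test_ctf_disabled_is_plain_windowing(self):
        sim, tomo, particle = bead_setup((50.0, -30.0, 20.0), noise=0.3)
        spec = ExtractionSpec(box_px=32, crop_px=16)
        stack, meta = extract_2d_stack(particle, tomo, sim.images, spec, -1,
                                       with_ctf=False)
        model = _series_model(tomo)
        from tomopipe.geometry import project_point, to_image_pixels

        for k, i in enumerate(meta["visible_indices"]):
            p2d = project_point(model[i], np.array(particle.position()))
            px, py = to_image_pixels(p2d, 10.0, (64, 64))
            cx, cy = int(round(px)), int(round(py))
            direct = sim.images[i][cy - 8 : cy + 8, cx - 8 : cx + 8]
            np.testing.assert_allclose(stack[k], direct.astype(np.float32), atol=1e-5)

    def test_stack_shape_and_metadata(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        spec = ExtractionSpec(box_px=32, crop_px=16, min_visible_images=10)
        stack, meta = extract_2d_stack(particle, tomo, sim.images, spec, -1)
        n_vis = len(meta["visible_indices"])
        assert stack.shape == (n_vis, 16, 16)
        assert len(meta["visible_image_names"]) == n_vis
        assert all(abs(r[0]) <= 0.5 and abs(r[1]) <= 0.5
                   for r in meta["subpixel_residuals_px"])

    def test_too_few_visible_images_skips_particle(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        spec = ExtractionSpec(box_px=32, crop_px=16, max_dose_e_per_A2=1.5,
                              min_visible_images=2)
        assert extract_2d_stack(particle, tomo, sim.images, spec, -1) is None

    def test_fourier_crop_binning_halves_box(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        spec = ExtractionSpec(box_px=32, crop_px=16, binning=2.0)
        stack, meta = extract_2d_stack(particle, tomo, sim.images, spec, -1)
        assert stack.shape[1:] == (16, 16)
        assert meta["pixel_size_A"] == pytest.approx(20.0)

    def test_half_precision_dtype(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        spec = ExtractionSpec(box_px=32, crop_px=16, half_precision=True)
        stack, _ = extract_2d_stack(particle, tomo, sim.images, spec, -1)
        assert stack.dtype == np.float16


class TestPseudoSubtomogram:
    def test_single_zero_tilt_image_constant_along_z(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        # restrict the series to the zero-tilt image only
        from dataclasses import replace

        i0 = next(i for i, img in enumerate(tomo.tilt_images)
                  if img.nominal_stage_tilt_deg == 0.0)
        tomo0 = replace(tomo, tilt_images=[replace(tomo.tilt_images[i0], z_rot_deg=0.0)])
        spec = ExtractionSpec(box_px=32, crop_px=16)
        data, weight, meta = extract_pseudo_subtomogram(
            particle, tomo0, sim.images[i0][None], spec, -1, with_ctf=False
        )
        d = data.astype(np.float64)
        interior = d[:, 4:12, 4:12]
        np.testing.assert_allclose(interior - interior[0], 0.0, atol=1e-5)

    def test_bead_peak_within_one_voxel_of_centre(self):
        sim, tomo, particle = bead_setup((60.0, -40.0, 30.0))
        spec = ExtractionSpec(box_px=32, crop_px=16)
        data, weight, meta = extract_pseudo_subtomogram(
            particle, tomo, sim.images, spec, -1
        )
        d = np.abs(data.astype(np.float64))
        iz, iy, ix = np.unravel_index(d.argmax(), d.shape)
        assert max(abs(ix - 8), abs(iy - 8), abs(iz - 8)) <= 1

    def test_weight_volume_nonnegative_and_wedge_shaped(self):
        sim, tomo, particle = bead_setup((0, 0, 0))
        spec = ExtractionSpec(box_px=32, crop_px=16)
        data, weight, _ = extract_pseudo_subtomogram(particle, tomo, sim.images, spec, -1)
        w = weight.astype(np.float64)
        assert w.min() >= 0.0
        assert w.max() > 0.0

    def test_2d_payload_smaller_when_fewer_tilts_than_box_side(self):
        n_tilt, crop = 41, 64
        assert n_tilt * crop**2 < crop**3


class TestRunExtraction:
    def _project(self, tmp_path, monkeypatch, **spec_kw):
        """Full mini-project on disk, extraction run from its root."""
        from tomopipe.metadata import (
            TiltSeriesSet,
            write_optimisation_set,
            write_particles,
            write_tilt_series_set,
        )
        from tomopipe.mrc import write_mrc

        monkeypatch.chdir(tmp_path)
        sim, tomo, particle = bead_setup((0, 0, 0))
        frames = tmp_path / "frames"
        frames.mkdir(exist_ok=True)
        for i, img in enumerate(tomo.tilt_images):
            p = frames / f"img_{i:03d}.mrc"
            write_mrc(p, sim.images[i].astype(np.float32), 10.0)
            img.micrograph_path = f"frames/img_{i:03d}.mrc"
        write_tilt_series_set(TiltSeriesSet([tomo]), tmp_path, "tomograms.star")
        write_particles([particle], tmp_path / "particles.star")
        optset = write_optimisation_set(tmp_path / "optimisation_set.star",
                                        "tomograms.star", "particles.star")
        spec = ExtractionSpec(box_px=32, crop_px=16, **spec_kw)
        return run_extraction(optset, spec, tmp_path / "Extract"), spec

    def test_conservation_no_filters(self, tmp_path, monkeypatch):
        from tomopipe.metadata import read_particles

        out, _ = self._project(tmp_path, monkeypatch)
        ps = read_particles(tmp_path / "Extract" / out.particles_path)
        assert len(ps) == 1
        assert ps[0].image_path is not None
        assert len(ps[0].visible_image_names) == 41

    def test_payload_bytes_match_closed_form(self, tmp_path, monkeypatch):
        """Emitted data bytes are exactly N_vis * crop^2 * width; float16
        halves the payload of float32."""
        from tomopipe.metadata import read_particles

        sizes = {}
        for half in (False, True):
            out, spec = self._project(tmp_path, monkeypatch, half_precision=half)
            ps = read_particles(tmp_path / "Extract" / out.particles_path)
            path = tmp_path / "Extract" / ps[0].image_path
            n_vis = len(ps[0].visible_image_names)
            width = 2 if half else 4
            payload = path.stat().st_size - 1024  # MRC header
            assert payload == n_vis * spec.crop_px**2 * width
            sizes[half] = payload
        assert sizes[True] * 2 == sizes[False]

    def test_all_particles_filtered_leaves_valid_empty_star(self, tmp_path, monkeypatch, caplog):
        import logging

        from tomopipe.metadata import read_particles

        with caplog.at_level(logging.WARNING):
            out, _ = self._project(tmp_path, monkeypatch,
                                   max_dose_e_per_A2=0.5, min_visible_images=2)
        ps = read_particles(tmp_path / "Extract" / out.particles_path)
        assert ps == []
        assert any("no particles survived" in r.message for r in caplog.records)

    def test_byte_identical_across_runs(self, tmp_path, monkeypatch):
        from tomopipe.metadata import read_particles

        out, _ = self._project(tmp_path, monkeypatch)
        ps = read_particles(tmp_path / "Extract" / out.particles_path)
        path = tmp_path / "Extract" / ps[0].image_path
        first = path.read_bytes()
        out2, _ = self._project(tmp_path, monkeypatch)
        assert path.read_bytes() == first


class TestSpecValidation:
    def test_odd_or_oversized_boxes_rejected(self):
        with pytest.raises(ValueError):
            ExtractionSpec(box_px=31, crop_px=16)
        with pytest.raises(ValueError):
            ExtractionSpec(box_px=16, crop_px=32)
        with pytest.raises(ValueError):
            ExtractionSpec(box_px=32, crop_px=16, binning=0.5)
        with pytest.raises(ValueError):
            ExtractionSpec(box_px=32, crop_px=16, min_visible_images=0)
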