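"""Shared fixtures: randomized schema-valid metadata sets and a small
simulated project, generated programmatically (no stored binary fixtures)."""

from __future__ import annotations

import numpy as np
import pytest

from tomopipe.metadata import (
    OpticsSettings,
    TiltImageRecord,
    TiltSeriesSet,
    TomogramRecord,
)
from tomopipe.simulate import SimulationConfig, make_phantom, simulate_tilt_series


def random_tilt_series_set(rng: np.random.Generator, max_series: int = 3) -> TiltSeriesSet:
    """A random schema-valid set with a random subset of optional fields."""
    n_series = int(rng.integers(1, max_series + 1))
    tomos = []
    for s in range(n_series):
        movie_px = float(rng.uniform(0.5, 2.0))
        optics = OpticsSettings(
            voltage_kV=float(rng.choice([200.0, 300.0])),
            cs_mm=float(rng.uniform(0.0, 3.0)),
            amplitude_contrast=float(rng.uniform(0.0, 0.2)),
            movie_pixel_size_A=movie_px,
            tilt_series_pixel_size_A=movie_px * float(rng.choice([1.0, 2.0])),
            hand=int(rng.choice([-1, 1])),
            optics_group_name=f"opticsGroup{s + 1}",
        )
        n_img = int(rng.integers(1, 8))
        with_ctf = bool(rng.integers(0, 2))
        with_align = bool(rng.integers(0, 2))
        with_movie = bool(rng.integers(0, 2))
        images = []
        dose = 0.0
        for i in range(n_img):
            du = float(rng.uniform(10000, 40000))
            dv = du + float(rng.uniform(-500, 500))
            images.append(
                TiltImageRecord(
                    nominal_stage_tilt_deg=float(-60 + 3 * i),
                    pre_exposure_e_per_A2=dose,
                    nominal_tilt_axis_deg=float(rng.uniform(-180, 180)),
                    nominal_defocus_um=float(rng.uniform(-5, -1)),
                    micrograph_path=f"frames/TS_{s}_{i:03d}.mrc",
                    movie_path=f"movies/TS_{s}_{i:03d}.tiff" if with_movie else None,
                    frame_count=int(rng.integers(4, 12)) if with_movie else None,
                    defocus_u_A=du if with_ctf else None,
                    defocus_v_A=dv if with_ctf else None,
                    defocus_angle_deg=float(rng.uniform(-90, 90)) if with_ctf else None,
                    ctf_fom=float(rng.uniform(0, 1)) if with_ctf else None,
                    ctf_max_res_A=float(rng.uniform(3, 20)) if with_ctf else None,
                    x_tilt_deg=0.0 if with_align else None,
                    y_tilt_deg=float(-60 + 3 * i) if with_align else None,
                    z_rot_deg=85.0 if with_align else None,
                    x_shift_A=float(rng.uniform(-20, 20)) if with_align else None,
                    y_shift_A=float(rng.uniform(-20, 20)) if with_align else None,
                )
            )
            dose += float(rng.uniform(2.0, 4.0))
        tomos.append(TomogramRecord(name=f"TS_{s + 1:02d}", optics=optics, tilt_images=images))
    return TiltSeriesSet(tomograms=tomos)


@pytest.fixture(scope="session")
def small_sim():
    """One 32-voxel simulated tilt series with beads, shared across tests."""
    cfg = SimulationConfig(
        seed=11, volume_size=32, voxel_size_A=10.0, n_beads=3,
        noise_sigma=0.05, shell_radius_A=120.0,
    )
    phantom = make_phantom(cfg)
    return simulate_tilt_series(phantom, cfg)


@pytest.fixture()
def sim_project(tmp_path, small_sim):
    """The small simulation written to disk as mdoc + micrographs."""
    from tomopipe.simulate import write_project

    mdoc_path, frames = write_project(small_sim, tmp_path / "sim")
    return {"mdoc": mdoc_path, "frames": frames, "sim": small_sim, "root": tmp_path}


def ground_truth_tomogram(sim, name=None) -> TomogramRecord:
    """TomogramRecord carrying the simulation's ground-truth alignment/CTF."""
    cfg = sim.config
    tilts = cfg.stage_tilts_deg
    images = [
        TiltImageRecord(
            nominal_stage_tilt_deg=float(t),
            pre_exposure_e_per_A2=float(sim.pre_exposure_e_per_A2[i]),
            nominal_tilt_axis_deg=cfg.tilt_axis_deg,
            nominal_defocus_um=float(sim.nominal_defocus_um[i]),
            x_tilt_deg=0.0,
            y_tilt_deg=float(t),
            z_rot_deg=cfg.tilt_axis_deg,
            x_shift_A=0.0,
            y_shift_A=0.0,
            defocus_u_A=abs(float(sim.nominal_defocus_um[i])) * 1e4,
            defocus_v_A=abs(float(sim.nominal_defocus_um[i])) * 1e4,
            defocus_angle_deg=0.0,
        )
        for i, t in enumerate(tilts)
    ]
    optics = OpticsSettings(
        voltage_kV=cfg.voltage_kV,
        cs_mm=cfg.cs_mm,
        amplitude_contrast=cfg.amplitude_contrast,
        movie_pixel_size_A=cfg.voxel_size_A,
        tilt_series_pixel_size_A=cfg.voxel_size_A,
        hand=cfg.hand,
    )
    return TomogramRecord(name=name or cfg.name, optics=optics, tilt_images=images)
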