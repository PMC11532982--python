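"""Synthetic tilt-series generator with known ground truth.

Emulates a minimal dose-symmetric (or linear) cryo-ET acquisition of a
phantom specimen: gold-bead-like point features and/or a spherical shell
(a stand-in for a virus-like particle), projected with the 5-parameter
tilt geometry, modulated by a per-image CTF whose defocus follows a
schedule, and degraded with additive Gaussian noise whose variance grows as
1/cos(tilt) to mimic the increasing specimen thickness at high tilt.  Even
and odd half-images carry independent noise whose mean is exactly the full
image, matching the even/odd movie-frame convention used for
noise2noise-style denoising.

Everything is reproducible from (config, seed), and the ground truth
(bead positions in centred Å, the projection model, the CTF parameters)
is returned so downstream oracles never need external data.  The generator
can also write the project to disk — per-tilt MRC micrographs and a
SerialEM-style mdoc — in exactly the form the import stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctf import CtfParams, ctf_scale_factor, premultiply_ctf
from .geometry import ProjectionModel
from .mrc import write_mrc
from .reconstruct import forward_project

__all__ = ["SimulationConfig", "Phantom", "SimulatedTiltSeries", "make_phantom",
           "simulate_tilt_series", "write_project"]


@dataclass
class SimulationConfig:
    """Acquisition and phantom parameters for one synthetic tilt series."""

    seed: int = 0
    name: str = "TS_01"
    volume_size: int = 64
    voxel_size_A: float = 10.0
    tilt_min_deg: float = -60.0
    tilt_max_deg: float = 60.0
    tilt_step_deg: float = 3.0
    dose_per_image_e_per_A2: float = 3.0
    nominal_defocus_um: float = -3.0  # acquisition convention: negative = underfocus
    defocus_step_um: float = 0.0  # optional per-acquisition-index ramp
    noise_sigma: float = 0.1
    hand: int = -1
    tilt_axis_deg: float = 85.0
    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    dose_symmetric: bool = True
    n_beads: int = 8
    bead_value: float = 1.0
    shell_radius_A: float | None = None
    shell_thickness_A: float = 20.0
    bead_positions_A: list[tuple[float, float, float]] | None = None
    with_ctf: bool = True

    def __post_init__(self) -> None:
        if self.volume_size < 16:
            raise ValueError("volume size must be >= 16")
        if self.voxel_size_A <= 0 or self.tilt_step_deg <= 0:
            raise ValueError("voxel size and tilt step must be positive")
        if self.hand not in (-1, 1):
            raise ValueError("hand must be -1 or +1")

    @property
    def stage_tilts_deg(self) -> np.ndarray:
        """Tilt angles in ascending order."""
        return np.arange(self.tilt_min_deg, self.tilt_max_deg + 1e-9, self.tilt_step_deg)

    def acquisition_order(self) -> list[int]:
        """Indices into :attr:`stage_tilts_deg` in the order acquired.

        Dose-symmetric: 0°, +step, -step, +2·step, ... — the scheme that
        spends the low-dose images on low tilts; otherwise simple ascending
        order.
        """
        tilts = self.stage_tilts_deg
        if not self.dose_symmetric:
            return list(range(len(tilts)))
        zero = int(np.argmin(np.abs(tilts)))
        order = [zero]
        for k in range(1, len(tilts)):
            for idx in (zero + k, zero - k):
                if 0 <= idx < len(tilts) and idx not in order:
                    order.append(idx)
        return order


@dataclass
class Phantom:
    """Ground-truth specimen: the volume plus feature coordinates."""

    volume: np.ndarray  # (nz, ny, nx)
    voxel_size_A: float
    bead_positions_A: np.ndarray  # (n, 3) centred Å, ordered x, y, z
    shell_radius_A: float | None = None
    shell_centre_A: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_phantom(config: SimulationConfig) -> Phantom:
    """Deterministic phantom: point beads and an optional spherical shell.

    Beads are placed uniformly at random inside the central 60% of the
    volume (so that their projections stay in the field of view at high
    tilt) unless explicit positions are given; the shell mimics a
    virus-like particle so that sphere-picking tests have a target.
    """
    rng = np.random.default_rng(config.seed)
    n = config.volume_size
    vs = config.voxel_size_A
    vol = np.zeros((n, n, n))

    if config.bead_positions_A is not None:
        beads = np.asarray(config.bead_positions_A, dtype=float)
    else:
        half = 0.3 * n * vs
        beads = rng.uniform(-half, half, size=(config.n_beads, 3))
    for b in beads:
        idx = np.round(b / vs).astype(int) + n // 2
        if np.all((idx >= 0) & (idx < n)):
            vol[idx[2], idx[1], idx[0]] += config.bead_value

    if config.shell_radius_A is not None:
        ax = (np.arange(n) - n // 2) * vs
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        rad = np.sqrt(xx**2 + yy**2 + zz**2)
        shell = np.exp(-0.5 * ((rad - config.shell_radius_A) / (config.shell_thickness_A / 2)) ** 2)
        vol += 0.2 * config.bead_value * shell

    return Phantom(
        volume=vol,
        voxel_size_A=vs,
        bead_positions_A=beads,
        shell_radius_A=config.shell_radius_A,
    )


@dataclass
class SimulatedTiltSeries:
    """Everything one acquisition produces, plus its ground truth."""

    config: SimulationConfig
    images: np.ndarray  # (n_tilt, n, n), tilt-ascending order
    even: np.ndarray
    odd: np.ndarray
    model: ProjectionModel  # ground truth, tilt-ascending order
    ctf: list[CtfParams]
    pre_exposure_e_per_A2: np.ndarray  # per image, tilt-ascending order
    nominal_defocus_um: np.ndarray
    mdoc_text: str
    phantom: Phantom = field(repr=False, default=None)  # type: ignore[assignment]


def _mdoc_text(config: SimulationConfig, order: list[int]) -> str:
    """SerialEM-style mdoc in acquisition order."""
    tilts = config.stage_tilts_deg
    defoci = _defocus_schedule(config)
    lines = [
        f"PixelSpacing = {config.voxel_size_A:.3f}",
        f"Voltage = {config.voltage_kV:.0f}",
        f"ImageFile = {config.name}.mrc",
        "",
        f"[T = SerialEM: simulated acquisition    Tilt axis angle = {config.tilt_axis_deg:.1f}, binning = 1]",
        "",
    ]
    for z, idx in enumerate(order):
        lines += [
            f"[ZValue = {z}]",
            f"TiltAngle = {tilts[idx]:.2f}",
            f"ExposureDose = {config.dose_per_image_e_per_A2:.3f}",
            f"TargetDefocus = {defoci[idx]:.2f}",
            f"SubFramePath = X:\\frames\\{config.name}_{z:03d}.mrc",
            "NumSubFrames = 8",
            "",
        ]
    return "\n".join(lines) + "\n"


def _defocus_schedule(config: SimulationConfig) -> np.ndarray:
    """Nominal defocus per tilt-ascending image (μm, negative = underfocus)."""
    order = config.acquisition_order()
    defoci = np.empty(len(order))
    for acq_pos, idx in enumerate(order):
        defoci[idx] = config.nominal_defocus_um - config.defocus_step_um * acq_pos
    return defoci


def simulate_tilt_series(phantom: Phantom, config: SimulationConfig) -> SimulatedTiltSeries:
    """Project the phantom, apply CTF and noise, build even/odd halves."""
    tilts = config.stage_tilts_deg
    order = config.acquisition_order()
    n = config.volume_size
    model = ProjectionModel.from_nominal(tilts, config.tilt_axis_deg)
    clean = forward_project(phantom.volume, phantom.voxel_size_A, model, (n, n))

    defoci_um = _defocus_schedule(config)
    ctf_list = []
    for i, tilt in enumerate(tilts):
        params = CtfParams(
            defocus_u_A=abs(defoci_um[i]) * 1e4,
            defocus_v_A=abs(defoci_um[i]) * 1e4,
            defocus_angle_deg=0.0,
            voltage_kV=config.voltage_kV,
            cs_mm=config.cs_mm,
            amplitude_contrast=config.amplitude_contrast,
            scale_factor=ctf_scale_factor(float(tilt)),
        )
        ctf_list.append(params)
        if config.with_ctf:
            clean[i] = premultiply_ctf(clean[i], phantom.voxel_size_A, params)

    rng = np.random.default_rng(config.seed + 1)
    images = np.empty_like(clean)
    even = np.empty_like(clean)
    odd = np.empty_like(clean)
    for i, tilt in enumerate(tilts):
        sigma = config.noise_sigma / np.sqrt(np.cos(np.deg2rad(tilt)))
        n1 = rng.normal(0.0, sigma * np.sqrt(2.0), size=clean[i].shape)
        n2 = rng.normal(0.0, sigma * np.sqrt(2.0), size=clean[i].shape)
        even[i] = clean[i] + n1
        odd[i] = clean[i] + n2
        images[i] = (even[i] + odd[i]) / 2.0  # the identity holds bitwise

    # pre-exposure accumulates in acquisition order; report per tilt index
    pre = np.empty(len(tilts))
    for acq_pos, idx in enumerate(order):
        pre[idx] = acq_pos * config.dose_per_image_e_per_A2

    return SimulatedTiltSeries(
        config=config,
        images=images,
        even=even,
        odd=odd,
        model=model,
        ctf=ctf_list,
        pre_exposure_e_per_A2=pre,
        nominal_defocus_um=defoci_um,
        mdoc_text=_mdoc_text(config, order),
        phantom=phantom,
    )


def write_project(sim: SimulatedTiltSeries, out_dir: str | Path) -> tuple[Path, Path]:
    """Write micrographs and the mdoc; returns (mdoc_path, micrograph_dir).

    Micrograph filenames follow the mdoc's SubFramePath basenames
    (acquisition order), so the import stage can resolve them; even/odd
    half-micrographs sit alongside with ``_even``/``_odd`` suffixes.
    """
    out_dir = Path(out_dir)
    frames = out_dir / "frames"
    frames.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    order = cfg.acquisition_order()
    vs = sim.phantom.voxel_size_A if sim.phantom is not None else cfg.voxel_size_A
    for z, idx in enumerate(order):
        base = f"{cfg.name}_{z:03d}"
        write_mrc(frames / f"{base}.mrc", sim.images[idx].astype(np.float32), vs)
        write_mrc(frames / f"{base}_even.mrc", sim.even[idx].astype(np.float32), vs)
        write_mrc(frames / f"{base}_odd.mrc", sim.odd[idx].astype(np.float32), vs)
    mdoc_path = out_dir / f"{cfg.name}.mrc.mdoc"
    mdoc_path.write_text(sim.mdoc_text)
    return mdoc_path, frames
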