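"""Real-space weighted back-projection of tilt series into tomograms.

The forward projector splats each voxel into the image plane with bilinear
weights at its projected position; the back-projector gathers, for every
voxel of the output grid, the bilinearly interpolated value of each
(filtered) tilt image at the voxel's projected position.  The two are exact
transposes of one another, so ⟨P·V, I⟩ = ⟨V, Pᵀ·I⟩ holds to machine
precision — a property the tests use as the operator oracle.

"Weighted" back-projection applies, per image, a 1D ramp filter |f⊥| along
the direction perpendicular to the tilt axis (the image x axis rotated by
theta_z); CTF premultiplication uses a single defocus per image (errors grow
away from the tomogram centre, which is acceptable because the tomograms
are used for picking, not for high-resolution averaging), scaled by
cos(stage tilt).

Array convention: volumes are (nz, ny, nx), images (ny, nx); the centred
origin sits at index n // 2 on each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .ctf import CtfParams, ctf_scale_factor, premultiply_ctf
from .geometry import ProjectionModel, apply_tilt_offset
from .metadata import TiltSeriesSet, TomogramRecord, ValidationError, write_tilt_series_set
from .mrc import read_mrc, write_mrc

__all__ = [
    "TomogramGrid",
    "forward_project",
    "backproject",
    "backproject_weighted",
    "ramp_filter",
    "reconstruct_tomograms",
]


@dataclass(frozen=True)
class TomogramGrid:
    """Output grid: dimensions in unbinned voxels plus a binning factor."""

    size_x: int
    size_y: int
    size_z: int
    binning: float = 1.0
    voxel_size_A: float = 1.0  # unbinned voxel (= tilt-series pixel size)

    def __post_init__(self) -> None:
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.binning <= 0 or self.voxel_size_A <= 0:
            raise ValueError("binning and voxel size must be positive")

    @property
    def binned_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of the reconstructed array."""
        b = self.binning
        return (
            math.ceil(self.size_z / b),
            math.ceil(self.size_y / b),
            math.ceil(self.size_x / b),
        )

    @property
    def binned_voxel_size_A(self) -> float:
        return self.voxel_size_A * self.binning


def _voxel_coords_A(shape_zyx: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Centred Å coordinates of all voxel centres, shape (N, 3) ordered x,y,z."""
    nz, ny, nx = shape_zyx
    ix = (np.arange(nx) - nx // 2) * voxel_size
    iy = (np.arange(ny) - ny // 2) * voxel_size
    iz = (np.arange(nz) - nz // 2) * voxel_size
    zz, yy, xx = np.meshgrid(iz, iy, ix, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _projected_pixels(
    image, coords_A: np.ndarray, pixel_size: float, image_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Project (N, 3) centred Å coords into 0-based (px, py) pixel arrays."""
    r = image.rotation()
    p2d = coords_A @ r.T[:, :2]
    p2d[:, 0] += image.dx_A
    p2d[:, 1] += image.dy_A
    nx, ny = image_size
    px = p2d[:, 0] / pixel_size + nx // 2
    py = p2d[:, 1] / pixel_size + ny // 2
    return px, py


def _sub_offsets(supersample: int, voxel_size: float) -> np.ndarray:
    """Centred sub-voxel offsets (Å) of an s^3 subdivision of one voxel."""
    s = supersample
    d1 = ((np.arange(s) + 0.5) / s - 0.5) * voxel_size
    dz, dy, dx = np.meshgrid(d1, d1, d1, indexing="ij")
    return np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)


def forward_project(
    volume: np.ndarray,
    voxel_size_A: float,
    model: ProjectionModel,
    image_size_px: tuple[int, int],
    pixel_size_A: float | None = None,
    supersample: int = 1,
) -> np.ndarray:
    """Project a (nz, ny, nx) volume through every image of *model*.

    Each voxel is treated as ``supersample**3`` equal point masses splatted
    with bilinear weights at their projected pixel positions; an
    all-zero-angle image is exactly the z-sum of the volume for any
    supersampling.  ``supersample > 1`` suppresses the lattice-interference
    ripple that plain one-point splatting shows at oblique in-plane
    rotations, at proportional cost.  Returns a stack (n_images, ny, nx).
    """
    if len(model) == 0:
        raise ValueError("projection model has no images")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    vol = np.asarray(volume, dtype=float)
    pixel_size = voxel_size_A if pixel_size_A is None else pixel_size_A
    nx, ny = image_size_px
    coords = _voxel_coords_A(vol.shape, voxel_size_A)
    values = vol.ravel()
    offsets = _sub_offsets(supersample, voxel_size_A)
    stack = np.zeros((len(model), ny, nx))
    for i, img in enumerate(model):
        flat = stack[i].ravel()
        for off in offsets:
            px, py = _projected_pixels(img, coords + off, pixel_size, image_size_px)
            x0 = np.floor(px).astype(np.int64)
            y0 = np.floor(py).astype(np.int64)
            fx = px - x0
            fy = py - y0
            for dx, dy, w in (
                (0, 0, (1 - fx) * (1 - fy)),
                (1, 0, fx * (1 - fy)),
                (0, 1, (1 - fx) * fy),
                (1, 1, fx * fy),
            ):
                xi, yi = x0 + dx, y0 + dy
                ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
                np.add.at(flat, yi[ok] * nx + xi[ok], values[ok] * w[ok] / len(offsets))
    return stack


def ramp_filter(image: np.ndarray, pixel_size_A: float, theta_z_deg: float) -> np.ndarray:
    """Apply the WBP ramp |f⊥| perpendicular to the in-image tilt axis."""
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny, d=pixel_size_A)[:, None]
    fx = np.fft.rfftfreq(nx, d=pixel_size_A)[None, :]
    c, s = np.cos(np.deg2rad(theta_z_deg)), np.sin(np.deg2rad(theta_z_deg))
    f_perp = np.abs(fx * c + fy * s)
    spec = np.fft.rfft2(image) * f_perp
    return np.fft.irfft2(spec, s=image.shape)


def backproject(
    images: np.ndarray,
    model: ProjectionModel,
    grid: TomogramGrid,
    pixel_size_A: float | None = None,
    ctf: Sequence[CtfParams] | None = None,
    weighting: str = "ramp",
    supersample: int = 1,
) -> np.ndarray:
    """Back-project a stack into a (binned) tomogram grid.

    ``weighting`` is "ramp" (standard WBP) or "none" (the plain adjoint of
    :func:`forward_project`, used by the adjointness oracle).  If *ctf* is
    given, each image is first premultiplied by its CTF (single defocus per
    image).  With equal ``supersample`` the unweighted backprojection is
    the exact transpose of :func:`forward_project`.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if len(images) != len(model):
        raise ValueError(f"{len(images)} images but {len(model)} model rows")
    if ctf is not None and len(ctf) != len(images):
        raise ValueError(f"{len(images)} images but {len(ctf)} CTF parameter sets")
    if weighting not in ("ramp", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    pixel_size = grid.voxel_size_A if pixel_size_A is None else pixel_size_A
    shape = grid.binned_shape
    coords = _voxel_coords_A(shape, grid.binned_voxel_size_A)
    offsets = _sub_offsets(supersample, grid.binned_voxel_size_A)
    out = np.zeros(int(np.prod(shape)))
    ny, nx = images.shape[1:]
    for i, img_model in enumerate(model):
        img = images[i]
        if ctf is not None:
            img = premultiply_ctf(img, pixel_size, ctf[i])
        if weighting == "ramp":
            img = ramp_filter(img, pixel_size, img_model.theta_z_deg)
        for off in offsets:
            px, py = _projected_pixels(img_model, coords + off, pixel_size, (nx, ny))
            # grid-constant: zero-padded bilinear interpolation, the exact
            # transpose of the forward splat at the image borders
            out += map_coordinates(
                img, np.stack([py, px]), order=1, mode="grid-constant", cval=0.0
            ) / len(offsets)
    return out.reshape(shape)


def backproject_weighted(
    images: np.ndarray,
    model: ProjectionModel,
    grid: TomogramGrid,
    ctf: Sequence[CtfParams] | None = None,
    pixel_size_A: float | None = None,
    supersample: int = 1,
) -> np.ndarray:
    """Ramp-weighted back-projection with optional CTF premultiplication."""
    return backproject(images, model, grid, pixel_size_A=pixel_size_A, ctf=ctf,
                       weighting="ramp", supersample=supersample)


def _series_model(tomo: TomogramRecord) -> ProjectionModel:
    missing = [i for i, img in enumerate(tomo.tilt_images) if not img.has_alignment]
    if missing:
        raise ValidationError(
            f"tomogram {tomo.name!r}: images {missing} lack alignment "
            "(rlnTomoXTilt/YTilt/ZRot/XShiftAngst/YShiftAngst)"
        )
    return ProjectionModel.from_arrays(
        [img.x_tilt_deg for img in tomo.tilt_images],
        [img.y_tilt_deg for img in tomo.tilt_images],
        [img.z_rot_deg for img in tomo.tilt_images],
        [img.x_shift_A for img in tomo.tilt_images],
        [img.y_shift_A for img in tomo.tilt_images],
    )


def _series_ctf(tomo: TomogramRecord, tilt_offset_deg: float = 0.0) -> list[CtfParams] | None:
    if any(img.defocus_u_A is None for img in tomo.tilt_images):
        return None
    return [
        CtfParams(
            defocus_u_A=img.defocus_u_A,
            defocus_v_A=img.defocus_v_A if img.defocus_v_A is not None else img.defocus_u_A,
            defocus_angle_deg=img.defocus_angle_deg or 0.0,
            voltage_kV=tomo.optics.voltage_kV,
            cs_mm=tomo.optics.cs_mm,
            amplitude_contrast=tomo.optics.amplitude_contrast,
            scale_factor=ctf_scale_factor(img.y_tilt_deg + tilt_offset_deg),
        )
        for img in tomo.tilt_images
    ]


def reconstruct_tomograms(
    tss: TiltSeriesSet,
    grid_size_unbinned: tuple[int, int, int],
    binning: float,
    out_dir: str | Path,
    tilt_offset_deg: float = 0.0,
    with_halves: bool = False,
    with_ctf: bool = True,
    project_root: str | Path = ".",
) -> TiltSeriesSet:
    """Reconstruct every series of *tss* and register the results.

    Writes one MRC per tomogram under ``<out_dir>/tomograms/`` at voxel size
    ``tilt_series_pixel_size * binning``, plus half-tomograms from the
    even/odd micrographs when requested, and a ``tomograms.star`` whose
    per-image rows carry ``rlnCtfScalefactor = cos(stage tilt)``.
    """
    out_dir = Path(out_dir)
    project_root = Path(project_root)
    tomo_dir = out_dir / "tomograms"
    tomo_dir.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = grid_size_unbinned

    out_tomos = []
    for tomo in tss.tomograms:
        if not tomo.tilt_images:
            raise ValidationError(f"tomogram {tomo.name!r} has no tilt images")
        model = _series_model(tomo)
        if tilt_offset_deg:
            model = apply_tilt_offset(model, tilt_offset_deg)
        pixel = tomo.optics.tilt_series_pixel_size_A
        grid = TomogramGrid(sx, sy, sz, binning=binning, voxel_size_A=pixel)
        ctf = _series_ctf(tomo, tilt_offset_deg) if with_ctf else None

        def _load(paths: list[str]) -> np.ndarray:
            return np.stack([read_mrc(project_root / p).data[0] for p in paths])

        images = _load([img.micrograph_path for img in tomo.tilt_images])
        volume = backproject_weighted(images, model, grid, ctf=ctf, pixel_size_A=pixel)
        vol_path = tomo_dir / f"{tomo.name}.mrc"
        write_mrc(vol_path, volume.astype(np.float32), grid.binned_voxel_size_A)

        half_paths: dict[str, str | None] = {"half1_path": None, "half2_path": None}
        if with_halves:
            for key, attr, suffix in (
                ("half1_path", "micrograph_even_path", "half1"),
                ("half2_path", "micrograph_odd_path", "half2"),
            ):
                paths = [getattr(img, attr) for img in tomo.tilt_images]
                if any(p is None for p in paths):
                    raise ValidationError(
                        f"tomogram {tomo.name!r}: even/odd micrographs missing, "
                        "cannot reconstruct halves"
                    )
                half = backproject_weighted(_load(paths), model, grid, ctf=ctf, pixel_size_A=pixel)
                hp = tomo_dir / f"{tomo.name}_{suffix}.mrc"
                write_mrc(hp, half.astype(np.float32), grid.binned_voxel_size_A)
                half_paths[key] = str(hp.relative_to(out_dir))

        new_images = [
            replace(img, ctf_scale_factor=ctf_scale_factor(img.y_tilt_deg + tilt_offset_deg))
            for img in tomo.tilt_images
        ]
        out_tomos.append(
            replace(
                tomo,
                tilt_images=new_images,
                tomogram_binning=binning,
                size_x=sx,
                size_y=sy,
                size_z=sz,
                tomogram_path=str(vol_path.relative_to(out_dir)),
                **half_paths,
            )
        )
    result = TiltSeriesSet(tomograms=out_tomos)
    write_tilt_series_set(result, out_dir, filename="tomograms.star")
    return result
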