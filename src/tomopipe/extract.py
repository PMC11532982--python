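"""Particle extraction: CTF-premultiplied 2D stacks and 3D pseudo-subtomograms.

For every particle and every tilt image on which it is visible, a window of
``box_px`` pixels is cropped around the particle's projected position
(integer pixel; the residual sub-pixel offset is recorded, not applied),
premultiplied by the *per-particle* CTF — the image defocus shifted by
``hand * z`` for the particle's rotated height — scaled by cos(stage tilt),
and finally reduced to ``crop_px``: a real-space centre crop at binning 1,
or a Fourier-space crop (simultaneous binning) at binning > 1, after the
CTF's signal delocalisation has been compensated inside the big box.

2D stacks hold the visible crops (N_vis * crop^2 pixels); pseudo-subtomograms
back-project the same crops (no ramp) into a crop^3 volume plus a matching
CTF^2 weight volume kept separate so no division-by-zero policy is needed.
Because a tilt series has far fewer images than a box has pixels along one
side, the 2D payload is usually much smaller than the 3D one; writing
float16 instead of float32 halves it again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ctf import CtfParams, ctf_scale_factor, premultiply_ctf
from .geometry import ProjectionModel, TiltProjection, particle_defocus, project_point, to_image_pixels
from .metadata import (
    OptimisationSet,
    ParticleRecord,
    TiltSeriesSet,
    TomogramRecord,
    ValidationError,
    read_optimisation_set,
    read_particles,
    read_tilt_series_set,
    write_optimisation_set,
    write_particles,
)
from .mrc import read_mrc, write_mrc
from .reconstruct import _series_ctf, _series_model

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionSpec",
    "visible_images",
    "extract_2d_stack",
    "extract_pseudo_subtomogram",
    "run_extraction",
]


@dataclass(frozen=True)
class ExtractionSpec:
    """Extraction parameters.

    ``box_px`` is the big premultiplication box, ``crop_px`` the output box;
    ``max_dose_e_per_A2`` drops late high-dose images and
    ``min_visible_images`` drops particles seen on too few images.
    """

    box_px: int = 64
    crop_px: int = 32
    binning: float = 1.0
    max_dose_e_per_A2: float | None = None
    min_visible_images: int = 1
    as_2d_stacks: bool = True
    half_precision: bool = False

    def __post_init__(self) -> None:
        if self.box_px <= 0 or self.crop_px <= 0 or self.box_px % 2 or self.crop_px % 2:
            raise ValueError("box sizes must be positive and even")
        if self.crop_px > self.box_px:
            raise ValueError("crop box cannot exceed the premultiplication box")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")
        if self.min_visible_images < 1:
            raise ValueError("min_visible_images must be >= 1")


def _image_size(series: TomogramRecord, images: np.ndarray) -> tuple[int, int]:
    ny, nx = images.shape[1:]
    return nx, ny


def visible_images(
    particle: ParticleRecord,
    series: TomogramRecord,
    spec: ExtractionSpec,
    model: ProjectionModel,
    image_size_px: tuple[int, int],
) -> list[int]:
    """Indices (series order) of tilt images on which the particle is usable.

    An image counts if its pre-exposure dose does not exceed the cap and the
    crop box centred at the projected position lies fully inside the image
    (the conservative definition of "visible").
    """
    pixel = series.optics.tilt_series_pixel_size_A
    half = spec.crop_px // 2
    nx, ny = image_size_px
    p3d = np.array(particle.position())
    out = []
    for i, img in enumerate(series.tilt_images):
        if spec.max_dose_e_per_A2 is not None and img.pre_exposure_e_per_A2 > spec.max_dose_e_per_A2:
            continue
        p2d = project_point(model[i], p3d)
        px, py = to_image_pixels(p2d, pixel, image_size_px)
        cx, cy = int(round(px)), int(round(py))
        if cx - half < 0 or cx + half > nx or cy - half < 0 or cy + half > ny:
            continue
        out.append(i)
    return out


def _crop_window(image: np.ndarray, cx: int, cy: int, box: int) -> np.ndarray:
    half = box // 2
    return image[cy - half : cy + half, cx - half : cx + half]


def _fourier_crop(window: np.ndarray, out_px: int, binning: float) -> np.ndarray:
    """Crop to ``out_px`` with simultaneous binning via a Fourier crop."""
    n = window.shape[0]
    small = int(round(n / binning))
    small -= small % 2
    spec = np.fft.fftshift(np.fft.fft2(window))
    lo = n // 2 - small // 2
    spec = spec[lo : lo + small, lo : lo + small]
    reduced = np.fft.ifft2(np.fft.ifftshift(spec)).real * (small * small) / (n * n)
    if reduced.shape[0] < out_px:
        raise ValueError(
            f"box {n} binned by {binning} gives {reduced.shape[0]} px, "
            f"smaller than the requested crop {out_px}"
        )
    lo = reduced.shape[0] // 2 - out_px // 2
    return reduced[lo : lo + out_px, lo : lo + out_px]


def _reduce(window: np.ndarray, spec: ExtractionSpec) -> np.ndarray:
    if spec.binning > 1:
        return _fourier_crop(window, spec.crop_px, spec.binning)
    lo = window.shape[0] // 2 - spec.crop_px // 2
    return window[lo : lo + spec.crop_px, lo : lo + spec.crop_px]


def extract_2d_stack(
    particle: ParticleRecord,
    series: TomogramRecord,
    images: np.ndarray,
    spec: ExtractionSpec,
    hand: int,
    model: ProjectionModel | None = None,
    ctf: list[CtfParams] | None = None,
    with_ctf: bool = True,
) -> tuple[np.ndarray, dict] | None:
    """Extract the per-particle 2D crop stack.

    Returns ``(stack, meta)`` where stack has shape (N_vis, crop, crop) and
    meta records the visible image indices/names, the integer crop centres
    and the residual sub-pixel offsets (in pixels).  Returns None (with a
    logged reason) if fewer than ``min_visible_images`` images qualify.
    """
    model = _series_model(series) if model is None else model
    if ctf is None and with_ctf:
        ctf = _series_ctf(series)
    image_size = _image_size(series, images)
    vis = visible_images(particle, series, spec, model, image_size)
    if len(vis) < spec.min_visible_images:
        logger.info(
            "particle at %s skipped: visible on %d < %d images",
            particle.position(), len(vis), spec.min_visible_images,
        )
        return None

    pixel = series.optics.tilt_series_pixel_size_A
    p3d = np.array(particle.position())
    dtype = np.float16 if spec.half_precision else np.float32
    stack = np.zeros((len(vis), spec.crop_px, spec.crop_px), dtype=np.float64)
    centres, residuals = [], []
    for k, i in enumerate(vis):
        p2d = project_point(model[i], p3d)
        px, py = to_image_pixels(p2d, pixel, image_size)
        cx, cy = int(round(px)), int(round(py))
        window = _crop_window(images[i], cx, cy, spec.box_px)
        if window.shape != (spec.box_px, spec.box_px):
            # big box may spill outside even when the crop box fits: pad
            padded = np.zeros((spec.box_px, spec.box_px))
            half = spec.box_px // 2
            ys = slice(max(0, cy - half), min(image_size[1], cy + half))
            xs = slice(max(0, cx - half), min(image_size[0], cx + half))
            padded[
                ys.start - (cy - half) : ys.stop - (cy - half),
                xs.start - (cx - half) : xs.stop - (cx - half),
            ] = images[i][ys, xs]
            window = padded
        if with_ctf and ctf is not None:
            pctf = particle_defocus(model[i], ctf[i], hand, p3d)
            window = premultiply_ctf(window, pixel, pctf)
        elif with_ctf:
            raise ValidationError("CTF requested but series has no defocus values")
        stack[k] = _reduce(window, spec)
        centres.append((cx, cy))
        residuals.append((float(px - cx), float(py - cy)))

    names = [
        series.tilt_images[i].micrograph_path or f"{series.name}@{i}" for i in vis
    ]
    meta = {
        "visible_indices": vis,
        "visible_image_names": names,
        "crop_centres_px": centres,
        "subpixel_residuals_px": residuals,
        "pixel_size_A": pixel * spec.binning,
    }
    return stack.astype(dtype), meta


def extract_pseudo_subtomogram(
    particle: ParticleRecord,
    series: TomogramRecord,
    images: np.ndarray,
    spec: ExtractionSpec,
    hand: int,
    model: ProjectionModel | None = None,
    ctf: list[CtfParams] | None = None,
    with_ctf: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict] | None:
    """Back-project the premultiplied crops into a crop^3 volume.

    Returns ``(data, weight, meta)``: the real-space data volume, the
    Fourier-space CTF^2 weight volume (each image's squared CTF accumulated
    on its central slice; kept separate so that no division-by-zero policy
    is baked in) and the same metadata as the 2D extraction.
    """
    from scipy.ndimage import map_coordinates

    from .ctf import ctf_value

    result = extract_2d_stack(
        particle, series, images, spec, hand, model=model, ctf=ctf, with_ctf=with_ctf
    )
    if result is None:
        return None
    stack, meta = result
    stack = stack.astype(np.float64)
    model = _series_model(series) if model is None else model
    if ctf is None and with_ctf:
        ctf = _series_ctf(series)
    pixel_out = meta["pixel_size_A"]
    n = spec.crop_px
    ax = (np.arange(n) - n // 2) * pixel_out
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    data = np.zeros(n**3)
    weight = np.zeros((n, n, n))
    p3d = np.array(particle.position())

    # centred Fourier grid of one crop image (cycles/Å)
    f1d = np.fft.fftshift(np.fft.fftfreq(n, d=pixel_out))
    fyy, fxx = np.meshgrid(f1d, f1d, indexing="ij")
    fxy = np.stack([fxx.ravel(), fyy.ravel()], axis=1)
    freq_step = 1.0 / (n * pixel_out)

    for k, i in enumerate(meta["visible_indices"]):
        r = model[i].rotation()
        # position inside the crop: rotation of the local offset only, plus
        # the stored sub-pixel residual of the integer-pixel crop centre
        p2d_local = coords @ r.T[:, :2]
        resx, resy = meta["subpixel_residuals_px"][k]
        px = p2d_local[:, 0] / pixel_out + n // 2 + resx / spec.binning
        py = p2d_local[:, 1] / pixel_out + n // 2 + resy / spec.binning
        data += map_coordinates(stack[k], np.stack([py, px]), order=1, mode="grid-constant")

        # central slice of this image in the 3D Fourier grid: q = fx*R[0] + fy*R[1]
        q = fxy[:, :1] * r[0][None, :] + fxy[:, 1:2] * r[1][None, :]
        if with_ctf and ctf is not None:
            pctf = particle_defocus(model[i], ctf[i], hand, p3d)
            c2 = ctf_value(pctf, np.hypot(fxx, fyy).ravel(),
                           np.rad2deg(np.arctan2(fyy, fxx)).ravel()) ** 2
        else:
            c2 = np.ones(n * n)
        idx = np.round(q / freq_step).astype(np.int64) + n // 2
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        np.add.at(weight, (idx[ok, 2], idx[ok, 1], idx[ok, 0]), c2[ok])

    dtype = np.float16 if spec.half_precision else np.float32
    return data.reshape(n, n, n).astype(dtype), weight.astype(dtype), meta


def run_extraction(
    optset_path: str | Path,
    spec: ExtractionSpec,
    out_dir: str | Path,
    project_root: str | Path | None = None,
) -> OptimisationSet:
    """Extract every particle of an optimisation set into ``Subtomograms/``.

    Writes per-particle MRC files, an updated ``particles.star`` with image
    paths (and visible-image arrays for 2D stacks) and a new
    ``optimisation_set.star`` pointing at it plus the input tomograms file.
    Particles failing the visibility filter are skipped with a warning; the
    job continues.
    """
    optset_path = Path(optset_path)
    star_root = optset_path.parent  # optset references are relative to itself
    root = Path(".") if project_root is None else Path(project_root)  # micrographs
    optset = read_optimisation_set(optset_path)
    tss = read_tilt_series_set(star_root / optset.tomograms_path)
    particles = read_particles(star_root / optset.particles_path)
    out_dir = Path(out_dir)
    sub_dir = out_dir / "Subtomograms"

    images_cache: dict[str, np.ndarray] = {}

    def _images(series: TomogramRecord) -> np.ndarray:
        if series.name not in images_cache:
            images_cache[series.name] = np.stack(
                [read_mrc(root / img.micrograph_path).data[0] for img in series.tilt_images]
            )
        return images_cache[series.name]

    kept: list[ParticleRecord] = []
    counter: dict[str, int] = {}
    for p in particles:
        try:
            series = tss[p.tomo_name]
        except KeyError:
            logger.warning("particle references unknown tomogram %r; skipped", p.tomo_name)
            continue
        hand = series.optics.hand if series.optics.hand is not None else -1
        images = _images(series)
        idx = counter.get(p.tomo_name, 0)
        counter[p.tomo_name] = idx + 1
        tdir = sub_dir / p.tomo_name
        tdir.mkdir(parents=True, exist_ok=True)
        pixel_out = series.optics.tilt_series_pixel_size_A * spec.binning
        if spec.as_2d_stacks:
            result = extract_2d_stack(p, series, images, spec, hand)
            if result is None:
                continue
            stack, meta = result
            path = tdir / f"{p.tomo_name}_{idx:06d}_stack2d.mrcs"
            write_mrc(path, stack, pixel_out, is_stack=True)
            p.image_path = str(path.relative_to(out_dir))
            p.visible_image_names = meta["visible_image_names"]
        else:
            result = extract_pseudo_subtomogram(p, series, images, spec, hand)
            if result is None:
                continue
            data, weight, meta = result
            path = tdir / f"{p.tomo_name}_{idx:06d}_data.mrc"
            wpath = tdir / f"{p.tomo_name}_{idx:06d}_weights.mrc"
            write_mrc(path, data, pixel_out)
            write_mrc(wpath, weight, pixel_out)
            p.image_path = str(path.relative_to(out_dir))
        kept.append(p)

    if not kept:
        logger.warning("no particles survived the extraction filters")
    particles_path = out_dir / "particles.star"
    write_particles(kept, particles_path)
    # re-point the tomograms file relative to the new optimisation set
    tomo_rel = Path(
        __import__("os").path.relpath(star_root / optset.tomograms_path, out_dir)
    ).as_posix()
    return_optset = out_dir / "optimisation_set.star"
    write_optimisation_set(return_optset, tomo_rel, "particles.star")
    return read_optimisation_set(return_optset)
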