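"""Typed data model for tilt-series, tomogram and particle metadata.

The on-disk representation is the STAR hierarchy used for cryo-ET
subtomogram averaging: a global ``tilt_series.star`` with one row per tilt
series (microscope optics, handedness, a pointer to a per-series file),
per-series STAR files with one row per tilt image (acquisition values,
motion/CTF estimates, the 5 alignment parameters), a ``particles.star``
with centred-Ångstrom coordinates, and an ``optimisation_set.star`` that
bundles the tomogram and particle files for downstream jobs.

Conventions:

* All paths inside STAR files are project-root-relative with forward
  slashes ("project root" = the directory holding the global file).
* Per-series rows are stored sorted by nominal stage tilt; the acquisition
  order remains recoverable from the monotonically accumulated
  pre-exposure dose.
* Unknown (vendor) columns are preserved verbatim as strings and re-emitted
  unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path, PureWindowsPath
from typing import Callable, Iterator, Sequence

import pandas as pd

from .mdoc import MdocFile, read_mdoc
from .star import read_star, write_star

logger = logging.getLogger(__name__)

__all__ = [
    "OpticsSettings",
    "TiltImageRecord",
    "TomogramRecord",
    "TiltSeriesSet",
    "ParticleRecord",
    "OptimisationSet",
    "ValidationError",
    "import_from_mdoc",
    "write_tilt_series_set",
    "read_tilt_series_set",
    "exclude_tilt_images",
    "write_particles",
    "read_particles",
    "write_optimisation_set",
    "read_optimisation_set",
]


class ValidationError(ValueError):
    """Raised when metadata violates the schema contract."""


# ---------------------------------------------------------------------------
# records


@dataclass
class OpticsSettings:
    """Microscope optics shared by all images of a tilt series.

    ``hand`` is the defocus handedness: the sign of the slope of defocus
    over the Z coordinate (+1 or -1; -1 is the default for the microscopes
    the acquisition convention was established on).
    """

    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    movie_pixel_size_A: float = 1.0
    tilt_series_pixel_size_A: float = 1.0
    hand: int | None = -1
    optics_group_name: str = "opticsGroup1"

    def __post_init__(self) -> None:
        if self.voltage_kV <= 0 or self.movie_pixel_size_A <= 0 or self.tilt_series_pixel_size_A <= 0:
            raise ValidationError("voltage and pixel sizes must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValidationError("amplitude contrast must lie in [0, 1]")
        if self.tilt_series_pixel_size_A < self.movie_pixel_size_A - 1e-9:
            raise ValidationError(
                "tilt-series pixel size cannot be smaller than the movie pixel size"
            )
        if self.hand is not None and self.hand not in (-1, 1):
            raise ValidationError(f"hand must be -1 or +1, got {self.hand!r}")


@dataclass
class TiltImageRecord:
    """One tilt image: acquisition values plus downstream estimates.

    Only the stage tilt and accumulated pre-exposure are always present;
    motion, CTF and alignment fields appear as the pipeline fills them in.
    """

    nominal_stage_tilt_deg: float = 0.0
    pre_exposure_e_per_A2: float = 0.0
    nominal_tilt_axis_deg: float | None = None
    nominal_defocus_um: float | None = None
    movie_path: str | None = None
    frame_count: int | None = None
    micrograph_path: str | None = None
    micrograph_even_path: str | None = None
    micrograph_odd_path: str | None = None
    motion_total_A: float | None = None
    motion_early_A: float | None = None
    motion_late_A: float | None = None
    defocus_u_A: float | None = None
    defocus_v_A: float | None = None
    astigmatism_A: float | None = None
    defocus_angle_deg: float | None = None
    ctf_fom: float | None = None
    ctf_max_res_A: float | None = None
    ice_ring_density: float | None = None
    x_tilt_deg: float | None = None
    y_tilt_deg: float | None = None
    z_rot_deg: float | None = None
    x_shift_A: float | None = None
    y_shift_A: float | None = None
    ctf_scale_factor: float | None = None

    def __post_init__(self) -> None:
        if self.pre_exposure_e_per_A2 < 0:
            raise ValidationError("pre-exposure dose must be >= 0")
        if self.defocus_u_A is not None and self.defocus_v_A is not None:
            astig = abs(self.defocus_u_A - self.defocus_v_A)
            if self.astigmatism_A is None:
                self.astigmatism_A = astig
            elif abs(self.astigmatism_A - astig) > 0.1:  # loose: survives STAR rounding
                raise ValidationError(
                    "astigmatism must equal |defocusU - defocusV| "
                    f"({self.astigmatism_A} vs {astig})"
                )
        if self.ctf_scale_factor is not None and not 0.0 <= self.ctf_scale_factor <= 1.0:
            raise ValidationError("CTF scale factor must lie in [0, 1]")

    @property
    def has_alignment(self) -> bool:
        return None not in (
            self.x_tilt_deg,
            self.y_tilt_deg,
            self.z_rot_deg,
            self.x_shift_A,
            self.y_shift_A,
        )


@dataclass
class TomogramRecord:
    """One tilt series and, once reconstructed, its tomogram."""

    name: str
    optics: OpticsSettings = field(default_factory=OpticsSettings)
    tilt_images: list[TiltImageRecord] = field(default_factory=list)
    tomogram_binning: float | None = None
    size_x: int | None = None
    size_y: int | None = None
    size_z: int | None = None
    tomogram_path: str | None = None
    half1_path: str | None = None
    half2_path: str | None = None
    etomo_directive_path: str | None = None
    extra_columns: pd.DataFrame | None = None  # unknown per-image columns, verbatim

    def __len__(self) -> int:
        return len(self.tilt_images)

    def stage_tilts(self) -> list[float]:
        return [img.nominal_stage_tilt_deg for img in self.tilt_images]

    def acquisition_order(self) -> list[int]:
        """Indices of tilt images sorted by accumulated pre-exposure dose."""
        return sorted(range(len(self.tilt_images)), key=lambda i: self.tilt_images[i].pre_exposure_e_per_A2)


@dataclass
class TiltSeriesSet:
    """The global table: an ordered collection of tilt series."""

    tomograms: list[TomogramRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tomograms]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate tomogram names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.tomograms)

    def __iter__(self) -> Iterator[TomogramRecord]:
        return iter(self.tomograms)

    def __getitem__(self, name: str) -> TomogramRecord:
        for t in self.tomograms:
            if t.name == name:
                return t
        raise KeyError(name)

    def names(self) -> list[str]:
        return [t.name for t in self.tomograms]


@dataclass
class ParticleRecord:
    """One particle pick: centred-Ångstrom coordinates plus orientations."""

    tomo_name: str
    x_A: float
    y_A: float
    z_A: float
    subtomo_rot_deg: float | None = None
    subtomo_tilt_deg: float | None = None
    subtomo_psi_deg: float | None = None
    rot_deg: float | None = None
    tilt_deg: float | None = None
    psi_deg: float | None = None
    tilt_prior_deg: float | None = None
    psi_prior_deg: float | None = None
    image_path: str | None = None
    visible_image_names: list[str] | None = None

    def position(self) -> tuple[float, float, float]:
        return (self.x_A, self.y_A, self.z_A)


@dataclass
class OptimisationSet:
    """Bundle of the STAR files a refinement stage needs."""

    tomograms_path: str
    particles_path: str
    motion_path: str | None = None


# ---------------------------------------------------------------------------
# STAR label tables: (attribute, rln label, type, optional)

_GLOBAL_FIELDS = [
    ("name", "rlnTomoName", str, False),
    ("voltage_kV", "rlnVoltage", float, False),
    ("cs_mm", "rlnSphericalAberration", float, False),
    ("amplitude_contrast", "rlnAmplitudeContrast", float, False),
    ("movie_pixel_size_A", "rlnMicrographOriginalPixelSize", float, False),
    ("hand", "rlnTomoHand", int, False),
    ("optics_group_name", "rlnOpticsGroupName", str, False),
    ("tilt_series_pixel_size_A", "rlnTomoTiltSeriesPixelSize", float, False),
    ("tilt_series_star_file", "rlnTomoTiltSeriesStarFile", str, False),
    ("etomo_directive_path", "rlnEtomoDirectiveFile", str, True),
    ("tomogram_binning", "rlnTomoTomogramBinning", float, True),
    ("size_x", "rlnTomoSizeX", int, True),
    ("size_y", "rlnTomoSizeY", int, True),
    ("size_z", "rlnTomoSizeZ", int, True),
    ("tomogram_path", "rlnTomoReconstructedTomogram", str, True),
    ("half1_path", "rlnTomoReconstructedTomogramHalf1", str, True),
    ("half2_path", "rlnTomoReconstructedTomogramHalf2", str, True),
]

_OPTICS_ATTRS = {
    "voltage_kV",
    "cs_mm",
    "amplitude_contrast",
    "movie_pixel_size_A",
    "hand",
    "optics_group_name",
    "tilt_series_pixel_size_A",
}

_TILT_FIELDS = [
    ("movie_path", "rlnMicrographMovieName", str, True),
    ("frame_count", "rlnTomoTiltMovieFrameCount", int, True),
    ("nominal_stage_tilt_deg", "rlnTomoNominalStageTiltAngle", float, False),
    ("nominal_tilt_axis_deg", "rlnTomoNominalTiltAxisAngle", float, True),
    ("pre_exposure_e_per_A2", "rlnMicrographPreExposure", float, False),
    ("nominal_defocus_um", "rlnTomoNominalDefocus", float, True),
    ("micrograph_even_path", "rlnMicrographNameEven", str, True),
    ("micrograph_odd_path", "rlnMicrographNameOdd", str, True),
    ("micrograph_path", "rlnMicrographName", str, True),
    ("motion_total_A", "rlnAccumMotionTotal", float, True),
    ("motion_early_A", "rlnAccumMotionEarly", float, True),
    ("motion_late_A", "rlnAccumMotionLate", float, True),
    ("defocus_u_A", "rlnDefocusU", float, True),
    ("defocus_v_A", "rlnDefocusV", float, True),
    ("astigmatism_A", "rlnCtfAstigmatism", float, True),
    ("defocus_angle_deg", "rlnDefocusAngle", float, True),
    ("ctf_fom", "rlnCtfFigureOfMerit", float, True),
    ("ctf_max_res_A", "rlnCtfMaxResolution", float, True),
    ("ice_ring_density", "rlnCtfIceRingDensity", float, True),
    ("x_tilt_deg", "rlnTomoXTilt", float, True),
    ("y_tilt_deg", "rlnTomoYTilt", float, True),
    ("z_rot_deg", "rlnTomoZRot", float, True),
    ("x_shift_A", "rlnTomoXShiftAngst", float, True),
    ("y_shift_A", "rlnTomoYShiftAngst", float, True),
    ("ctf_scale_factor", "rlnCtfScalefactor", float, True),
]

_PARTICLE_FIELDS = [
    ("tomo_name", "rlnTomoName", str, False),
    ("x_A", "rlnCenteredCoordinateXAngst", float, False),
    ("y_A", "rlnCenteredCoordinateYAngst", float, False),
    ("z_A", "rlnCenteredCoordinateZAngst", float, False),
    ("subtomo_rot_deg", "rlnTomoSubtomogramRot", float, True),
    ("subtomo_tilt_deg", "rlnTomoSubtomogramTilt", float, True),
    ("subtomo_psi_deg", "rlnTomoSubtomogramPsi", float, True),
    ("rot_deg", "rlnAngleRot", float, True),
    ("tilt_deg", "rlnAngleTilt", float, True),
    ("psi_deg", "rlnAnglePsi", float, True),
    ("tilt_prior_deg", "rlnAngleTiltPrior", float, True),
    ("psi_prior_deg", "rlnAnglePsiPrior", float, True),
    ("image_path", "rlnImageName", str, True),
]

_VISIBLE_LABEL = "rlnTomoVisibleImages"


def _parse(value: str, typ: type):
    if typ is str:
        return value
    if typ is int:
        return int(float(value))
    return float(value)


def _records_to_frame(records: Sequence[object], field_table) -> pd.DataFrame:
    """Serialise records to a string DataFrame, omitting all-absent optional columns."""
    columns: dict[str, list[str]] = {}
    for attr, label, _typ, optional in field_table:
        values = [getattr(r, attr, None) for r in records]
        if optional and all(v is None for v in values):
            continue
        cells = []
        for v in values:
            if v is None:
                if _typ is str:
                    raise ValidationError(
                        f"column {label} present in some rows but missing in others"
                    )
                cells.append("nan")
            else:
                from .star import format_value

                cells.append(format_value(v))
        columns[label] = cells
    return pd.DataFrame(columns, dtype=str)


def _frame_to_kwargs(df: pd.DataFrame, field_table) -> tuple[list[dict], pd.DataFrame]:
    """Typed kwargs per row plus the unknown columns kept verbatim."""
    known = {label: (attr, typ) for attr, label, typ, _opt in field_table}
    rows: list[dict] = []
    for _, row in df.iterrows():
        kwargs = {}
        for label, value in row.items():
            if label in known:
                attr, typ = known[label]
                if typ is not str and isinstance(value, str) and value.lower() == "nan":
                    kwargs[attr] = None
                else:
                    kwargs[attr] = _parse(value, typ)
        rows.append(kwargs)
    extra = df[[c for c in df.columns if c not in known]]
    return rows, extra


# ---------------------------------------------------------------------------
# mdoc import


def _micrograph_for(
    section, mdoc: MdocFile, index: int, micrograph_root: Path, remap: Callable[[str], str] | None
) -> tuple[str | None, str]:
    """Resolve the per-tilt micrograph path; returns (movie_path, micrograph_path)."""
    if section.sub_frame_path:
        movie = section.sub_frame_path
        basename = PureWindowsPath(movie).name  # mdoc paths are often Windows-style
    else:
        movie = None
        basename = f"{mdoc.name}_{section.z_value:03d}.mrc"
    if remap is not None:
        basename = remap(basename)
    path = micrograph_root / basename
    if not path.exists():
        raise FileNotFoundError(
            f"micrograph for {mdoc.path.name} [ZValue = {section.z_value}] "
            f"not found: {path}"
        )
    return movie, str(path)


def import_from_mdoc(
    mdoc_paths: Sequence[str | Path],
    micrograph_root: str | Path,
    optics: OpticsSettings,
    micrograph_remap: Callable[[str], str] | None = None,
) -> TiltSeriesSet:
    """Build a :class:`TiltSeriesSet` from mdoc acquisition files.

    One tomogram record per mdoc.  The pre-exposure of image k is the sum
    of the exposure doses of all images acquired *before* k (its own dose
    excluded); the nominal defocus comes from ``TargetDefocus`` and the
    tilt-axis angle from the mdoc header.  If ``optics.hand`` is unset it
    defaults to -1.  Records are stored sorted by stage tilt.
    """
    micrograph_root = Path(micrograph_root)
    optics = replace(optics, hand=-1 if optics.hand is None else optics.hand)
    tomograms = []
    for p in mdoc_paths:
        mdoc = read_mdoc(p)
        images = []
        accumulated = 0.0
        for i, sec in enumerate(mdoc.sections):
            movie, micrograph = _micrograph_for(sec, mdoc, i, micrograph_root, micrograph_remap)
            # even/odd half-micrographs (normally written by motion
            # correction) are picked up when present alongside the full one
            mpath = Path(micrograph)
            even = mpath.with_name(mpath.stem + "_even" + mpath.suffix)
            odd = mpath.with_name(mpath.stem + "_odd" + mpath.suffix)
            images.append(
                TiltImageRecord(
                    nominal_stage_tilt_deg=sec.tilt_angle_deg,
                    pre_exposure_e_per_A2=accumulated,
                    nominal_tilt_axis_deg=mdoc.tilt_axis_angle_deg,
                    nominal_defocus_um=sec.target_defocus_um,
                    movie_path=movie,
                    frame_count=sec.num_sub_frames,
                    micrograph_path=micrograph,
                    micrograph_even_path=str(even) if even.exists() else None,
                    micrograph_odd_path=str(odd) if odd.exists() else None,
                )
            )
            accumulated += sec.exposure_dose_e_per_A2
        images.sort(key=lambda r: r.nominal_stage_tilt_deg)
        tomograms.append(TomogramRecord(name=mdoc.name, optics=optics, tilt_images=images))
    return TiltSeriesSet(tomograms=tomograms)


# ---------------------------------------------------------------------------
# STAR hierarchy I/O


def write_tilt_series_set(tss: TiltSeriesSet, out_dir: str | Path, filename: str = "tilt_series.star") -> Path:
    """Write the global file plus one per-series STAR under ``tilt_series/``."""
    out_dir = Path(out_dir)
    series_dir = out_dir / "tilt_series"
    series_dir.mkdir(parents=True, exist_ok=True)

    class _Row:  # adapter so _records_to_frame can read global attributes
        def __init__(self, tomo: TomogramRecord):
            for attr, _label, _t, _o in _GLOBAL_FIELDS:
                if attr == "tilt_series_star_file":
                    value = f"tilt_series/{tomo.name}.star"
                elif attr in _OPTICS_ATTRS:
                    value = getattr(tomo.optics, attr)
                else:
                    value = getattr(tomo, attr)
                setattr(self, attr, value)

    global_df = _records_to_frame([_Row(t) for t in tss.tomograms], _GLOBAL_FIELDS)
    write_star(out_dir / filename, {"global": global_df})

    for tomo in tss.tomograms:
        df = _records_to_frame(tomo.tilt_images, _TILT_FIELDS)
        if tomo.extra_columns is not None and len(tomo.extra_columns.columns):
            for col in tomo.extra_columns.columns:
                df[col] = list(tomo.extra_columns[col])
        write_star(series_dir / f"{tomo.name}.star", {tomo.name: df})
    return out_dir / filename


def read_tilt_series_set(path: str | Path) -> TiltSeriesSet:
    """Read a global tilt-series STAR plus its per-series files.

    Per-series paths are resolved relative to the directory holding the
    global file; a dangling reference raises, naming both the global row
    and the missing file.
    """
    path = Path(path)
    root = path.parent
    blocks = read_star(path)
    if "global" not in blocks:
        raise ValidationError(f"{path}: missing data_global block")
    gdf = blocks["global"]
    for label in ("rlnTomoName", "rlnTomoTiltSeriesStarFile"):
        if label not in gdf.columns:
            raise ValidationError(f"{path}: missing compulsory label {label}")
    grows, _gextra = _frame_to_kwargs(gdf, _GLOBAL_FIELDS)

    tomograms = []
    for kwargs in grows:
        name = kwargs["name"]
        series_rel = kwargs.pop("tilt_series_star_file")
        series_path = root / series_rel
        if not series_path.exists():
            raise ValidationError(
                f"tomogram {name!r}: per-series STAR file not found: {series_path}"
            )
        optics = OpticsSettings(**{k: v for k, v in kwargs.items() if k in _OPTICS_ATTRS})
        sblocks = read_star(series_path)
        block_name = name if name in sblocks else next(iter(sblocks))
        trows, textra = _frame_to_kwargs(sblocks[block_name], _TILT_FIELDS)
        tomograms.append(
            TomogramRecord(
                name=name,
                optics=optics,
                tilt_images=[TiltImageRecord(**kw) for kw in trows],
                extra_columns=textra if len(textra.columns) else None,
                **{
                    k: v
                    for k, v in kwargs.items()
                    if k not in _OPTICS_ATTRS and k != "name"
                },
            )
        )
    return TiltSeriesSet(tomograms=tomograms)


def exclude_tilt_images(
    tss: TiltSeriesSet, drops: dict[str, Sequence[int]]
) -> TiltSeriesSet:
    """Remove de-selected tilt images; remaining rows keep their order.

    Pre-exposure values are *not* renumbered: the dose was physically
    accumulated whether or not an image is kept.  A series emptied by the
    drop list is retained with zero rows (with a warning); stages that need
    images reject it later.
    """
    names = set(tss.names())
    unknown = set(drops) - names
    if unknown:
        raise ValidationError(f"unknown tomogram names in drop list: {sorted(unknown)}")
    out = []
    for tomo in tss.tomograms:
        if tomo.name not in drops or not len(list(drops[tomo.name])):
            out.append(tomo)
            continue
        idx = sorted(set(int(i) for i in drops[tomo.name]))
        bad = [i for i in idx if i < 0 or i >= len(tomo.tilt_images)]
        if bad:
            raise ValidationError(
                f"tomogram {tomo.name!r}: drop indices out of range: {bad} "
                f"(series has {len(tomo.tilt_images)} images)"
            )
        kept = [img for i, img in enumerate(tomo.tilt_images) if i not in set(idx)]
        extra = tomo.extra_columns
        if extra is not None and len(extra):
            extra = extra.drop(extra.index[idx]).reset_index(drop=True)
        if not kept:
            logger.warning("tomogram %r has no tilt images left after exclusion", tomo.name)
        out.append(replace(tomo, tilt_images=kept, extra_columns=extra))
    return TiltSeriesSet(tomograms=out)


# ---------------------------------------------------------------------------
# particles and optimisation sets


def write_particles(particles: Sequence[ParticleRecord], path: str | Path) -> Path:
    """Write ``particles.star`` (one ``data_particles`` table)."""
    df = _records_to_frame(particles, _PARTICLE_FIELDS)
    vis = [p.visible_image_names for p in particles]
    if any(v is not None for v in vis):
        if any(v is None for v in vis):
            raise ValidationError("visible-image arrays present for only some particles")
        df[_VISIBLE_LABEL] = ["[" + ",".join(v) + "]" for v in vis]
    return write_star(path, {"particles": df})


def read_particles(path: str | Path) -> list[ParticleRecord]:
    path = Path(path)
    blocks = read_star(path)
    if "particles" not in blocks:
        raise ValidationError(f"{path}: missing data_particles block")
    df = blocks["particles"]
    rows, _extra = _frame_to_kwargs(df, _PARTICLE_FIELDS)
    particles = [ParticleRecord(**kw) for kw in rows]
    if _VISIBLE_LABEL in df.columns:
        for p, cell in zip(particles, df[_VISIBLE_LABEL]):
            names = cell.strip()[1:-1]
            p.visible_image_names = names.split(",") if names else []
    return particles


_OPTSET_LABELS = {
    "tomograms_path": "rlnTomoTomogramsFile",
    "particles_path": "rlnTomoParticlesFile",
    "motion_path": "rlnTomoTrajectoriesFile",
}


def write_optimisation_set(
    out_path: str | Path,
    tomograms_path: str,
    particles_path: str,
    motion_path: str | None = None,
) -> Path:
    """Write ``optimisation_set.star``; referenced files must exist."""
    out_path = Path(out_path)
    root = out_path.parent
    refs = {"tomograms_path": tomograms_path, "particles_path": particles_path}
    if motion_path is not None:
        refs["motion_path"] = motion_path
    for key, rel in refs.items():
        if not (root / rel).exists():
            raise ValidationError(f"{key} refers to a missing file: {root / rel}")
    df = pd.DataFrame({_OPTSET_LABELS[k]: [v] for k, v in refs.items()}, dtype=str)
    return write_star(out_path, {"optimisation_set": df})


def read_optimisation_set(path: str | Path) -> OptimisationSet:
    """Read and validate an ``optimisation_set.star``."""
    path = Path(path)
    root = path.parent
    blocks = read_star(path)
    if "optimisation_set" not in blocks:
        raise ValidationError(f"{path}: missing data_optimisation_set block")
    df = blocks["optimisation_set"]
    kwargs = {}
    for attr, label in _OPTSET_LABELS.items():
        if label in df.columns:
            kwargs[attr] = str(df[label].iloc[0])
    for key in ("tomograms_path", "particles_path"):
        if key not in kwargs:
            raise ValidationError(f"{path}: missing {_OPTSET_LABELS[key]}")
    for key, rel in kwargs.items():
        if not (root / rel).exists():
            raise ValidationError(f"{path}: {key} refers to a missing file: {root / rel}")
    return OptimisationSet(**kwargs)


def sets_equal(a: TiltSeriesSet, b: TiltSeriesSet, rel_tol: float = 1e-6) -> bool:
    """Field-wise equality (floats compared to *rel_tol* relative)."""

    def close(x, y):
        if isinstance(x, float) or isinstance(y, float):
            if x is None or y is None:
                return x is y
            return math.isclose(float(x), float(y), rel_tol=rel_tol, abs_tol=1e-9)
        return x == y

    if a.names() != b.names():
        return False
    for ta, tb in zip(a.tomograms, b.tomograms):
        for f in dc_fields(OpticsSettings):
            if not close(getattr(ta.optics, f.name), getattr(tb.optics, f.name)):
                return False
        for attr in ("tomogram_binning", "size_x", "size_y", "size_z",
                     "tomogram_path", "half1_path", "half2_path", "etomo_directive_path"):
            if not close(getattr(ta, attr), getattr(tb, attr)):
                return False
        if len(ta.tilt_images) != len(tb.tilt_images):
            return False
        for ia, ib in zip(ta.tilt_images, tb.tilt_images):
            for f in dc_fields(TiltImageRecord):
                if not close(getattr(ia, f.name), getattr(ib, f.name)):
                    return False
    return True
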