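"""Particle picking by geometric sampling of annotated spheres and filaments.

Spheres (virus capsids, vesicles) are annotated as centre + radius and
sampled quasi-uniformly on the surface with a Fibonacci lattice at a
user-given inter-particle distance; each sample carries a subtomogram
pre-rotation that orients the particle z-axis *tangential* to the surface,
so that a 90° prior on the particle tilt angle points z along the outward
normal.  Filaments are 1D curves (natural cubic spline through control
points) sampled at fixed arc-length intervals; there the pre-rotation makes
z perpendicular to the local tangent and the 90° tilt prior aligns z with
the tangent.  Keeping the particle tilt near 90° avoids the gimbal lock of
ZYZ Euler angles at tilt = 0.

Annotations round-trip through per-tomogram STAR files in an
``annotations/`` directory; sampled picks are emitted as ``particles.star``
with centred-Ångstrom coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .geometry import matrix_to_euler_zyz
from .metadata import ParticleRecord
from .star import read_star, write_star

__all__ = [
    "SphereAnnotation",
    "FilamentAnnotation",
    "sample_sphere",
    "sample_filament",
    "remove_duplicates",
    "write_annotations",
    "read_annotations",
]


@dataclass
class SphereAnnotation:
    """A sphere pick: centre in centred Å plus a radius."""

    tomo_name: str
    centre_A: tuple[float, float, float]
    radius_A: float

    def __post_init__(self) -> None:
        if self.radius_A <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class FilamentAnnotation:
    """A filament pick: ordered control points (centred Å) along the axis."""

    tomo_name: str
    control_points_A: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.control_points_A) < 2:
            raise ValueError("a filament needs at least 2 control points")
        pts = np.asarray(self.control_points_A, dtype=float)
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive filament control points must be distinct")


def _frame_euler(x_axis: np.ndarray, z_axis: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler triple of the right-handed frame with the given x and z axes."""
    x = x_axis / np.linalg.norm(x_axis)
    z = z_axis / np.linalg.norm(z_axis)
    y = np.cross(z, x)
    r = np.column_stack([x, y, z])
    return matrix_to_euler_zyz(r)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def sample_sphere(
    sphere: SphereAnnotation,
    spacing_A: float,
    jitter_rng: np.random.Generator | None = None,
) -> list[ParticleRecord]:
    """Sample picks on a sphere surface at roughly *spacing_A* separation.

    The point count is ``round(4*pi*r^2 / d^2)`` (surface area over the area
    one particle claims).  Each record's subtomogram angles orient the
    particle z tangentially (along the +meridian direction, with the local
    x-axis on the outward normal); tilt_prior = 90° and psi_prior = 0 make
    the composed z-axis the outward surface normal.  If *jitter_rng* is
    given the lattice is randomly rotated, emulating random sampling.
    """
    if spacing_A <= 0:
        raise ValueError("spacing must be positive")
    r = sphere.radius_A
    if spacing_A >= math.pi * r:
        normals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])  # antipodal pair
    else:
        n = max(2, round(4.0 * math.pi * r * r / (spacing_A * spacing_A)))
        normals = fibonacci_sphere(n)
    if jitter_rng is not None:
        q = jitter_rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        normals = normals @ rot.T

    centre = np.asarray(sphere.centre_A, dtype=float)
    records = []
    for nrm in normals:
        pos = centre + r * nrm
        # meridian tangent: direction of increasing polar angle; fall back to
        # x-hat at the poles where the meridian is undefined
        zhat = np.array([0.0, 0.0, 1.0])
        meridian = np.cross(np.cross(nrm, zhat), nrm)
        norm = np.linalg.norm(meridian)
        tangent = np.array([1.0, 0.0, 0.0]) if norm < 1e-9 else -meridian / norm
        rot_deg, tilt_deg, psi_deg = _frame_euler(x_axis=nrm, z_axis=tangent)
        records.append(
            ParticleRecord(
                tomo_name=sphere.tomo_name,
                x_A=float(pos[0]),
                y_A=float(pos[1]),
                z_A=float(pos[2]),
                subtomo_rot_deg=rot_deg,
                subtomo_tilt_deg=tilt_deg,
                subtomo_psi_deg=psi_deg,
                rot_deg=0.0,
                tilt_deg=90.0,
                psi_deg=0.0,
                tilt_prior_deg=90.0,
                psi_prior_deg=0.0,
            )
        )
    return records


def sample_filament(filament: FilamentAnnotation, spacing_A: float) -> list[ParticleRecord]:
    """Sample picks along a filament at fixed arc-length spacing.

    The curve is a natural cubic spline through the control points,
    resampled at arc-length intervals of *spacing_A* (bisection to 1e-3 Å).
    The subtomogram angles orient the particle z perpendicular to the local
    tangent; the 90° tilt prior then points the composed z along it.
    """
    if spacing_A <= 0:
        raise ValueError("spacing must be positive")
    pts = np.asarray(filament.control_points_A, dtype=float)
    if len(pts) == 2:
        spline = None
        seg = pts[1] - pts[0]
        total = float(np.linalg.norm(seg))
    else:
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
        tt = np.linspace(0.0, chord[-1], max(1000, 20 * len(pts)))
        fine = spline(tt)
        seg_len = np.linalg.norm(np.diff(fine, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = float(arc[-1])

    n = int(math.floor(total / spacing_A)) + 1
    targets = np.arange(n) * spacing_A

    records = []
    for s in targets:
        if spline is None:
            t = s / total if total else 0.0
            pos = pts[0] + t * (pts[1] - pts[0])
            tangent = seg / total
        else:
            # invert arc length by bisection on the fine parameterisation
            lo, hi = 0.0, tt[-1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                sm = float(np.interp(mid, tt, arc))
                if sm < s:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-3 / max(1.0, total):
                    break
            t = 0.5 * (lo + hi)
            pos = spline(t)
            tangent = spline(t, 1)
            tangent = tangent / np.linalg.norm(tangent)
        # any unit vector perpendicular to the tangent serves as particle z
        ref = np.array([0.0, 0.0, 1.0])
        if abs(float(np.dot(ref, tangent))) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        perp = np.cross(tangent, ref)
        perp /= np.linalg.norm(perp)
        rot_deg, tilt_deg, psi_deg = _frame_euler(x_axis=tangent, z_axis=perp)
        records.append(
            ParticleRecord(
                tomo_name=filament.tomo_name,
                x_A=float(pos[0]),
                y_A=float(pos[1]),
                z_A=float(pos[2]),
                subtomo_rot_deg=rot_deg,
                subtomo_tilt_deg=tilt_deg,
                subtomo_psi_deg=psi_deg,
                rot_deg=0.0,
                tilt_deg=90.0,
                psi_deg=0.0,
                tilt_prior_deg=90.0,
                psi_prior_deg=0.0,
            )
        )
    return records


def remove_duplicates(
    particles: Sequence[ParticleRecord], min_dist_A: float
) -> list[ParticleRecord]:
    """Greedy duplicate removal in input order.

    A particle is dropped iff it lies within *min_dist_A* of an
    already-kept particle of the same tomogram; the output is a subsequence
    of the input and the operation is idempotent.
    """
    if min_dist_A < 0:
        raise ValueError("minimum distance must be >= 0")
    if min_dist_A == 0:
        return list(particles)
    kept: list[ParticleRecord] = []
    kept_by_tomo: dict[str, list[np.ndarray]] = {}
    for p in particles:
        pos = np.array(p.position())
        close = any(
            float(np.linalg.norm(pos - q)) < min_dist_A
            for q in kept_by_tomo.get(p.tomo_name, ())
        )
        if not close:
            kept.append(p)
            kept_by_tomo.setdefault(p.tomo_name, []).append(pos)
    return kept


# ---------------------------------------------------------------------------
# annotation files: annotations/<tomo>_spheres.star, _filaments.star


def write_annotations(
    out_dir: str | Path,
    spheres: Sequence[SphereAnnotation] = (),
    filaments: Sequence[FilamentAnnotation] = (),
) -> Path:
    """One STAR file per tomogram per geometry kind under ``annotations/``."""
    ann_dir = Path(out_dir) / "annotations"
    ann_dir.mkdir(parents=True, exist_ok=True)
    by_tomo_s: dict[str, list[SphereAnnotation]] = {}
    for s in spheres:
        by_tomo_s.setdefault(s.tomo_name, []).append(s)
    for tomo, items in by_tomo_s.items():
        df = pd.DataFrame(
            {
                "rlnCenteredCoordinateXAngst": [s.centre_A[0] for s in items],
                "rlnCenteredCoordinateYAngst": [s.centre_A[1] for s in items],
                "rlnCenteredCoordinateZAngst": [s.centre_A[2] for s in items],
                "rlnSphereRadiusAngst": [s.radius_A for s in items],
            }
        )
        write_star(ann_dir / f"{tomo}_spheres.star", {"spheres": df})
    by_tomo_f: dict[str, list[FilamentAnnotation]] = {}
    for f in filaments:
        by_tomo_f.setdefault(f.tomo_name, []).append(f)
    for tomo, items in by_tomo_f.items():
        rows = {
            "rlnFilamentID": [],
            "rlnCenteredCoordinateXAngst": [],
            "rlnCenteredCoordinateYAngst": [],
            "rlnCenteredCoordinateZAngst": [],
        }
        for fid, fil in enumerate(items):
            for p in fil.control_points_A:
                rows["rlnFilamentID"].append(fid)
                rows["rlnCenteredCoordinateXAngst"].append(p[0])
                rows["rlnCenteredCoordinateYAngst"].append(p[1])
                rows["rlnCenteredCoordinateZAngst"].append(p[2])
        write_star(ann_dir / f"{tomo}_filaments.star", {"filaments": pd.DataFrame(rows)})
    return ann_dir


def read_annotations(
    out_dir: str | Path,
) -> tuple[list[SphereAnnotation], list[FilamentAnnotation]]:
    """Read every annotation file under ``<out_dir>/annotations/``."""
    ann_dir = Path(out_dir) / "annotations"
    spheres: list[SphereAnnotation] = []
    filaments: list[FilamentAnnotation] = []
    if not ann_dir.exists():
        return spheres, filaments
    for path in sorted(ann_dir.glob("*_spheres.star")):
        tomo = path.name[: -len("_spheres.star")]
        df = read_star(path)["spheres"]
        for _, row in df.iterrows():
            spheres.append(
                SphereAnnotation(
                    tomo_name=tomo,
                    centre_A=(
                        float(row["rlnCenteredCoordinateXAngst"]),
                        float(row["rlnCenteredCoordinateYAngst"]),
                        float(row["rlnCenteredCoordinateZAngst"]),
                    ),
                    radius_A=float(row["rlnSphereRadiusAngst"]),
                )
            )
    for path in sorted(ann_dir.glob("*_filaments.star")):
        tomo = path.name[: -len("_filaments.star")]
        df = read_star(path)["filaments"]
        for fid in sorted(set(df["rlnFilamentID"]), key=lambda v: int(float(v))):
            sel = df[df["rlnFilamentID"] == fid]
            pts = [
                (
                    float(r["rlnCenteredCoordinateXAngst"]),
                    float(r["rlnCenteredCoordinateYAngst"]),
                    float(r["rlnCenteredCoordinateZAngst"]),
                )
                for _, r in sel.iterrows()
            ]
            filaments.append(FilamentAnnotation(tomo_name=tomo, control_points_A=pts))
    return spheres, filaments
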