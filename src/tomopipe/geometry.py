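"""Tilt-series projection geometry.

The projection model relating 3D positions in a tomogram to 2D positions in
a tilt image has 5 parameters per image: three extrinsic Euler angles in a
fixed microscope frame (theta_x for non-perpendicularity of the stage tilt
axis to the optical axis, theta_y for the stage tilt itself, theta_z to
align the image Y axis with the tilt axis) and two post-rotation shifts
(dx, dy, in Å).  With homogeneous coordinates centred on the tomogram,

    R = T(dx, dy) @ Rz(theta_z) @ Ry(theta_y) @ Rx(theta_x)

and the 2D image position is the (x, y) part of ``R @ (p, 1)``.  Angles are
stored in degrees (the STAR convention) and converted to radians internally.

Pixel convention: image pixels are 0-based with the centred origin at
``(nx // 2, ny // 2)``; this is a package-level contract (the metadata
standard leaves it undefined) documented for interop.

Defocus handedness: a particle at height z (in the microscope frame, after
rotation) has per-particle defocus ``defocus + hand * z``.  With hand = +1 a
particle at positive x moves closer to focus as the stage tilt increases;
hand = -1 flips the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TiltProjection",
    "ProjectionModel",
    "Pose",
    "rot_x",
    "rot_y",
    "rot_z",
    "projection_matrix",
    "project_point",
    "to_image_pixels",
    "from_image_pixels",
    "particle_defocus",
    "euler_zyz_to_matrix",
    "matrix_to_euler_zyz",
    "compose_orientation",
    "apply_tilt_offset",
]


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass(frozen=True)
class TiltProjection:
    """The 5 projection parameters of one tilt image."""

    theta_x_deg: float = 0.0
    theta_y_deg: float = 0.0
    theta_z_deg: float = 0.0
    dx_A: float = 0.0
    dy_A: float = 0.0

    def rotation(self) -> np.ndarray:
        """The 3x3 rotation part Rz @ Ry @ Rx (no shifts)."""
        return rot_z(self.theta_z_deg) @ rot_y(self.theta_y_deg) @ rot_x(self.theta_x_deg)


@dataclass
class ProjectionModel:
    """Per-image projection parameters for a whole tilt series."""

    images: list[TiltProjection]

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> TiltProjection:
        return self.images[i]

    def __iter__(self) -> Iterator[TiltProjection]:
        return iter(self.images)

    @classmethod
    def from_arrays(
        cls,
        theta_x_deg: Sequence[float],
        theta_y_deg: Sequence[float],
        theta_z_deg: Sequence[float],
        dx_A: Sequence[float],
        dy_A: Sequence[float],
    ) -> "ProjectionModel":
        return cls(
            [
                TiltProjection(*vals)
                for vals in zip(theta_x_deg, theta_y_deg, theta_z_deg, dx_A, dy_A)
            ]
        )

    @classmethod
    def from_nominal(
        cls, stage_tilts_deg: Sequence[float], tilt_axis_deg: float
    ) -> "ProjectionModel":
        """Model built from nominal values only: theta_y = stage tilt,
        theta_z = tilt-axis angle, theta_x and shifts zero."""
        return cls(
            [TiltProjection(0.0, float(t), float(tilt_axis_deg), 0.0, 0.0) for t in stage_tilts_deg]
        )


def projection_matrix(image: TiltProjection) -> np.ndarray:
    """4x4 homogeneous transform from centred 3D Å to centred 2D Å (rows 0-1)."""
    for v in (image.theta_x_deg, image.theta_y_deg, image.theta_z_deg, image.dx_A, image.dy_A):
        if not np.isfinite(v):
            raise ValueError(f"non-finite projection parameter in {image}")
    m = np.eye(4)
    m[:3, :3] = image.rotation()
    t = np.eye(4)
    t[0, 3] = image.dx_A
    t[1, 3] = image.dy_A
    return t @ m


def project_point(image: TiltProjection, p3d: np.ndarray) -> np.ndarray:
    """Map centred 3D Å coordinates to centred 2D Å image coordinates.

    *p3d* may be a single (3,) point or an (N, 3) array.
    """
    p = np.asarray(p3d, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite 3D coordinates")
    r = image.rotation()
    shift = np.array([image.dx_A, image.dy_A])
    return (p @ r.T)[..., :2] + shift


def to_image_pixels(
    p2d_A: np.ndarray, pixel_size_A: float, image_size_px: tuple[int, int]
) -> np.ndarray:
    """Centred Å -> 0-based pixels, origin at (nx // 2, ny // 2)."""
    if pixel_size_A <= 0:
        raise ValueError("pixel size must be positive")
    nx, ny = image_size_px
    centre = np.array([nx // 2, ny // 2], dtype=float)
    return np.asarray(p2d_A, dtype=float) / pixel_size_A + centre


def from_image_pixels(
    px: np.ndarray, pixel_size_A: float, image_size_px: tuple[int, int]
) -> np.ndarray:
    """Inverse of :func:`to_image_pixels`."""
    nx, ny = image_size_px
    centre = np.array([nx // 2, ny // 2], dtype=float)
    return (np.asarray(px, dtype=float) - centre) * pixel_size_A


def particle_defocus(image: TiltProjection, ctf, hand: int, p3d: np.ndarray):
    """Per-particle CTF with defocus adjusted for the particle's height.

    The adjustment is ``hand * z`` where z is the third component of the
    rotated particle position (Å); the astigmatism angle and the u/v split
    are depth-independent (only the mean defocus shifts).
    """
    if hand not in (-1, 1):
        raise ValueError(f"hand must be -1 or +1, got {hand!r}")
    p = np.asarray(p3d, dtype=float)
    z = float((image.rotation() @ p)[2])
    return replace(ctf, defocus_u_A=ctf.defocus_u_A + hand * z, defocus_v_A=ctf.defocus_v_A + hand * z)


@dataclass
class Pose:
    """Particle orientation: a subtomogram pre-rotation that orients the
    particle in the tomogram frame, composed with refinement Euler angles
    (and optional priors on tilt/psi)."""

    subtomo_rot_deg: float = 0.0
    subtomo_tilt_deg: float = 0.0
    subtomo_psi_deg: float = 0.0
    rot_deg: float = 0.0
    tilt_deg: float = 0.0
    psi_deg: float = 0.0
    tilt_prior_deg: float | None = None
    psi_prior_deg: float | None = None


def euler_zyz_to_matrix(rot_deg: float, tilt_deg: float, psi_deg: float) -> np.ndarray:
    """ZYZ Euler triple -> rotation matrix Rz(rot) @ Ry(tilt) @ Rz(psi).

    Columns are the particle-frame axes expressed in the outer frame; the
    particle z-axis maps to the spherical direction with azimuth ``rot`` and
    polar angle ``tilt``.
    """
    return rot_z(rot_deg) @ rot_y(tilt_deg) @ rot_z(psi_deg)


def matrix_to_euler_zyz(r: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_zyz_to_matrix`; degenerate tilt=0/180 resolved
    by putting the whole in-plane rotation into psi."""
    r = np.asarray(r, dtype=float)
    tilt = float(np.rad2deg(np.arccos(np.clip(r[2, 2], -1.0, 1.0))))
    if 1.0 - abs(r[2, 2]) < 1e-15:
        rot = 0.0
        psi = float(np.rad2deg(np.arctan2(r[1, 0], r[0, 0])))
        if r[2, 2] < 0:
            psi = float(np.rad2deg(np.arctan2(r[1, 0], -r[0, 0])))
        return rot, tilt, psi
    rot = float(np.rad2deg(np.arctan2(r[1, 2], r[0, 2])))
    psi = float(np.rad2deg(np.arctan2(r[2, 1], -r[2, 0])))
    return rot, tilt, psi


def compose_orientation(pose: Pose) -> np.ndarray:
    """Total rotation particle frame -> tomogram frame:
    ``R_subtomo @ R_particle`` (the particle rotation is applied first)."""
    r_sub = euler_zyz_to_matrix(pose.subtomo_rot_deg, pose.subtomo_tilt_deg, pose.subtomo_psi_deg)
    r_par = euler_zyz_to_matrix(pose.rot_deg, pose.tilt_deg, pose.psi_deg)
    return r_sub @ r_par


def apply_tilt_offset(model: ProjectionModel, offset_deg: float) -> ProjectionModel:
    """Add a constant offset to the stage-tilt angle of every image.

    Useful when tilt series were collected on pre-tilted lamellae; only
    theta_y changes.
    """
    return ProjectionModel(
        [replace(img, theta_y_deg=img.theta_y_deg + offset_deg) for img in model]
    )
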