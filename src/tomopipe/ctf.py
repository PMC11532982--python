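"""Contrast transfer function evaluation and image premultiplication.

Conventions (the package contract for interop):

* Defocus is positive for underfocus (the STAR convention); the *nominal*
  defocus in mdoc files is negative for underfocus and converted on import.
* The CTF at frequency f and azimuth a is
  ``scale * (-sqrt(1 - A^2) * sin(chi) - A * cos(chi))`` with the standard
  phase ``chi = pi*lambda*dz(a)*f^2 - (pi/2)*Cs*lambda^3*f^4`` and the
  azimuth-dependent defocus ``dz(a) = 0.5*(du + dv + (du - dv)*cos(2*(a - a0)))``.
  The first extremum is negative for underfocus.
* ``scale_factor`` is the linear scale applied to CTF values; during
  tomogram reconstruction it is the cosine of the stage tilt angle.

The electron wavelength is derived relativistically from the acceleration
voltage.  Phase plates are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CtfParams",
    "electron_wavelength_A",
    "ctf_value",
    "ctf_scale_factor",
    "premultiply_ctf",
    "ctf_image",
    "ice_ring_density",
    "defocus_search_range",
    "ctf_fit_max_resolution",
]


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV."""
    if voltage_kV <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kV * 1e3
    return 12.2639 / math.sqrt(v * (1.0 + v * 0.97845e-6))


@dataclass
class CtfParams:
    """Per-image CTF parameters (defocus in Å, positive = underfocus)."""

    defocus_u_A: float
    defocus_v_A: float
    defocus_angle_deg: float = 0.0
    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    scale_factor: float = 1.0
    b_factor_per_dose: float | None = None  # simulator-only envelope knob

    def __post_init__(self) -> None:
        if not 0.0 <= self.scale_factor <= 1.0:
            raise ValueError(f"scale_factor must lie in [0, 1], got {self.scale_factor}")

    @property
    def astigmatism_A(self) -> float:
        return abs(self.defocus_u_A - self.defocus_v_A)


def _chi(params: CtfParams, freq: np.ndarray, azimuth_rad: np.ndarray) -> np.ndarray:
    lam = electron_wavelength_A(params.voltage_kV)
    du, dv = params.defocus_u_A, params.defocus_v_A
    a0 = np.deg2rad(params.defocus_angle_deg)
    dz = 0.5 * (du + dv + (du - dv) * np.cos(2.0 * (azimuth_rad - a0)))
    cs = params.cs_mm * 1e7  # mm -> Å
    return np.pi * lam * dz * freq**2 - 0.5 * np.pi * cs * lam**3 * freq**4


def ctf_value(params: CtfParams, freq_A_inv, azimuth_deg=0.0):
    """CTF at spatial frequency |f| (1/Å) and azimuth (deg); vectorised."""
    freq = np.asarray(freq_A_inv, dtype=float)
    if np.any(freq < 0):
        raise ValueError("spatial frequency must be >= 0")
    chi = _chi(params, freq, np.deg2rad(np.asarray(azimuth_deg, dtype=float)))
    a = params.amplitude_contrast
    out = params.scale_factor * (-math.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi))
    return out if out.ndim else float(out)


def ctf_scale_factor(stage_tilt_deg: float) -> float:
    """cos(tilt): the linear CTF scale factor applied at reconstruction."""
    if abs(stage_tilt_deg) >= 90.0:
        raise ValueError(f"|tilt| must be < 90 deg, got {stage_tilt_deg}")
    return float(np.cos(np.deg2rad(stage_tilt_deg)))


def ctf_image(params: CtfParams, shape: tuple[int, int], pixel_size_A: float, rfft: bool = True):
    """Sample the CTF on the Fourier grid of an (ny, nx) image."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size_A)[:, None]
    fx = (np.fft.rfftfreq(nx, d=pixel_size_A) if rfft else np.fft.fftfreq(nx, d=pixel_size_A))[None, :]
    freq = np.hypot(fx, fy)
    azimuth = np.rad2deg(np.arctan2(fy, fx))
    return ctf_value(params, freq, azimuth)


def premultiply_ctf(image: np.ndarray, pixel_size_A: float, params: CtfParams) -> np.ndarray:
    """Multiply the image spectrum by the CTF and return the real image.

    Requires a square image with an even side so the Fourier grid is
    unambiguous.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {img.shape}")
    if img.shape[0] % 2:
        raise ValueError("image side must be even")
    spec = np.fft.rfft2(img) * ctf_image(params, img.shape, pixel_size_A, rfft=True)
    return np.fft.irfft2(spec, s=img.shape)


def ice_ring_density(
    image: np.ndarray,
    pixel_size_A: float,
    band: tuple[float, float] = (0.25, 0.28),
    flank_lo: tuple[float, float] = (0.22, 0.25),
    flank_hi: tuple[float, float] = (0.28, 0.31),
) -> float:
    """Power of the image in the amorphous-ice ring band 0.25-0.28 1/Å,
    normalised by the flanking bands.

    Returns mean in-band power spectral density divided by the mean PSD of
    the two flanking annuli, making the statistic contrast-scale-free.  If
    the band lies beyond Nyquist (pixel size too large) the value is
    undefined and NaN is returned.  A zero image gives 0.
    """
    img = np.asarray(image, dtype=float)
    nyquist = 0.5 / pixel_size_A
    if band[1] > nyquist:
        return float("nan")
    fy = np.fft.fftfreq(img.shape[0], d=pixel_size_A)[:, None]
    fx = np.fft.rfftfreq(img.shape[1], d=pixel_size_A)[None, :]
    freq = np.hypot(fx, fy)
    psd = np.abs(np.fft.rfft2(img)) ** 2 / img.size
    in_band = (freq >= band[0]) & (freq <= band[1])
    in_flank = ((freq >= flank_lo[0]) & (freq < flank_lo[1])) | (
        (freq > flank_hi[0]) & (freq <= flank_hi[1])
    )
    if not in_band.any() or not in_flank.any():
        return float("nan")
    band_power = float(psd[in_band].mean())
    flank_power = float(psd[in_flank].mean())
    if flank_power == 0.0:
        return 0.0 if band_power == 0.0 else float("inf")
    return band_power / flank_power


def defocus_search_range(nominal_defocus_um: float, half_range_um: float) -> tuple[float, float]:
    """Defocus search window (min, max) in Å around a nominal defocus.

    The nominal value follows the acquisition convention (negative =
    underfocus, in μm); the returned window is in unsigned underfocus Å,
    clamped at zero.
    """
    if half_range_um < 0:
        raise ValueError("half range must be >= 0")
    centre = abs(nominal_defocus_um) * 1e4
    half = half_range_um * 1e4
    return (max(0.0, centre - half), centre + half)


def ctf_fit_max_resolution(
    pre_exposure_e_per_A2: float,
    res_at_zero_dose_A: float,
    res_at_ref_dose_A: float,
    ref_dose_e_per_A2: float,
) -> float:
    """Dose-dependent maximum resolution for CTF fitting.

    Linear interpolation in spatial frequency (1/resolution) between the
    zero-dose and reference-dose anchors, clamped beyond the reference dose;
    the returned resolution (Å) never improves with accumulated dose.
    """
    if ref_dose_e_per_A2 <= 0:
        raise ValueError("reference dose must be positive")
    if pre_exposure_e_per_A2 < 0 or res_at_zero_dose_A <= 0 or res_at_ref_dose_A <= 0:
        raise ValueError("doses must be >= 0 and resolutions > 0")
    frac = min(pre_exposure_e_per_A2 / ref_dose_e_per_A2, 1.0)
    inv0, inv1 = 1.0 / res_at_zero_dose_A, 1.0 / res_at_ref_dose_A
    return 1.0 / (inv0 + (inv1 - inv0) * frac)
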