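"""Parser for SerialEM/Tomo5 ``.mdoc`` acquisition metadata files.

The dialect accepted here covers both programs: a ``key = value`` global
header followed by ``[ZValue = n]`` sections, one per tilt image.  The tilt
axis may be given either as an explicit ``TiltAxisAngle`` key or inside the
SerialEM free-text header line ``[T = SerialEM: ... Tilt axis angle = 85.3,
binning = ...]``; both are recognised.  ``TiltAngle`` and ``ExposureDose``
are required per section; ``TargetDefocus``, ``SubFramePath`` and
``NumSubFrames`` are optional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["MdocSection", "MdocFile", "read_mdoc", "MdocParseError"]


class MdocParseError(ValueError):
    """Raised on a malformed mdoc; the message names file and line."""


@dataclass
class MdocSection:
    """One ``[ZValue = n]`` block: a single tilt image acquisition."""

    z_value: int
    tilt_angle_deg: float
    exposure_dose_e_per_A2: float
    target_defocus_um: float | None = None
    sub_frame_path: str | None = None
    num_sub_frames: int | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class MdocFile:
    """A parsed mdoc: global header plus per-tilt sections in file order."""

    path: Path
    header: dict[str, str]
    sections: list[MdocSection]
    tilt_axis_angle_deg: float | None = None

    @property
    def name(self) -> str:
        """Tomogram name derived from the filename (``Pos1.mrc.mdoc`` -> ``Pos1``)."""
        stem = self.path.name
        for suffix in (".mdoc", ".mrc", ".st"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        return stem


_TILT_AXIS_RE = re.compile(r"Tilt\s*axis\s*angle\s*=\s*(-?\d+\.?\d*)", re.IGNORECASE)


def _require_float(sec: dict[str, str], key: str, path: Path, z: int) -> float:
    if key not in sec:
        raise MdocParseError(f"{path}: [ZValue = {z}] is missing required key {key}")
    try:
        return float(sec[key])
    except ValueError as exc:
        raise MdocParseError(f"{path}: [ZValue = {z}] bad {key}: {sec[key]!r}") from exc


def read_mdoc(path: str | Path) -> MdocFile:
    """Parse *path* into an :class:`MdocFile`; sections keep acquisition order."""
    path = Path(path)
    header: dict[str, str] = {}
    raw_sections: list[tuple[int, dict[str, str]]] = []
    tilt_axis: float | None = None
    current: dict[str, str] | None = None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise MdocParseError(f"{path}:{lineno}: unterminated section header: {raw!r}")
            inner = line[1:-1].strip()
            m = _TILT_AXIS_RE.search(inner)
            if m:
                tilt_axis = float(m.group(1))
            if inner.lower().startswith("zvalue"):
                try:
                    z = int(inner.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise MdocParseError(f"{path}:{lineno}: bad ZValue header: {raw!r}") from exc
                current = {}
                raw_sections.append((z, current))
            continue
        if "=" not in line:
            raise MdocParseError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if current is None:
            header[key] = value
        else:
            current[key] = value

    if tilt_axis is None and "TiltAxisAngle" in header:
        tilt_axis = float(header["TiltAxisAngle"])

    sections: list[MdocSection] = []
    for z, sec in raw_sections:
        known = {"TiltAngle", "ExposureDose", "TargetDefocus", "SubFramePath", "NumSubFrames"}
        sections.append(
            MdocSection(
                z_value=z,
                tilt_angle_deg=_require_float(sec, "TiltAngle", path, z),
                exposure_dose_e_per_A2=_require_float(sec, "ExposureDose", path, z),
                target_defocus_um=float(sec["TargetDefocus"]) if "TargetDefocus" in sec else None,
                sub_frame_path=sec.get("SubFramePath"),
                num_sub_frames=int(sec["NumSubFrames"]) if "NumSubFrames" in sec else None,
                extra={k: v for k, v in sec.items() if k not in known},
            )
        )
    return MdocFile(path=path, header=header, sections=sections, tilt_axis_angle_deg=tilt_axis)
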