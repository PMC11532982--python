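"""Minimal MRC-2014 volume/stack I/O.

Supports the modes this pipeline emits: 2 (float32, the default for
micrographs and tomograms) and 12 (float16, the half-precision option for
particle stacks), plus 0/1 (int8/int16) on read.  Data are stored C-ordered
as (nz, ny, nx); the voxel size is carried in the cell dimensions
(``cella = n * voxel``).  Only little-endian files are produced, with the
standard 'MAP ' magic and 0x44 machine stamp.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc", "MrcData"]

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 12: np.float16}
_DTYPE_MODES = {np.dtype(np.float32): 2, np.dtype(np.float16): 12}


@dataclass
class MrcData:
    """An MRC payload: array shaped (nz, ny, nx) plus voxel size in Å."""

    data: np.ndarray
    voxel_size_A: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def write_mrc(
    path: str | Path,
    data: np.ndarray,
    voxel_size_A: float,
    *,
    is_stack: bool = False,
) -> Path:
    """Write *data* (2D or 3D, float32/float16) to *path*.

    ``is_stack`` sets the space group to 0 (image stack) instead of 1
    (volume); readers use it to distinguish particle stacks from tomograms.
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"MRC data must be 2D or 3D, got shape {arr.shape}")
    if arr.dtype not in _DTYPE_MODES:
        arr = arr.astype(np.float32)
    mode = _DTYPE_MODES[arr.dtype]
    nz, ny, nx = arr.shape

    stats = arr.astype(np.float32)
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart/nystart/nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx,my,mz
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size_A, ny * voxel_size_A, nz * voxel_size_A
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc,mapr,maps
    struct.pack_into(
        "<3f", header, 76, float(stats.min()), float(stats.max()), float(stats.mean())
    )
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)  # ispg
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])
    struct.pack_into("<f", header, 216, float(stats.std()))
    struct.pack_into("<i", header, 220, 1)  # nlabl
    header[224 : 224 + 14] = b"tomopipe      "

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(arr).tobytes())
    return path


def read_mrc(path: str | Path) -> MrcData:
    """Read an MRC file (modes 0/1/2/12) into an (nz, ny, nx) array."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, _, _ = struct.unpack_from("<3i", header, 28)
        xlen, _, _ = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        fh.seek(_HEADER_BYTES + nsymbt)
        data = np.frombuffer(fh.read(nx * ny * nz * dtype.itemsize), dtype=dtype)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data section")
    voxel = xlen / mx if mx else 1.0
    return MrcData(data=data.reshape(nz, ny, nx).copy(), voxel_size_A=float(voxel))
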