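"""Minimal MRC2014 volume/stack I/O.

Self-contained reader/writer for the subset of MRC2014 this package needs:
mode-2 (float32) 2D images, image stacks and 3D volumes with correct cell
dimensions so that the voxel size round-trips.  Axis order on disk is the
MRC convention (section, row, column) = numpy (z, y, x).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2
# 'MAP ' + little-endian machine stamp
_MAP_ID = b"MAP "
_MACHST_LE = bytes((0x44, 0x44, 0, 0))


def write_mrc(path: str | Path, data: np.ndarray, voxel_size: float = 1.0,
              origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
              is_stack: bool = False) -> None:
    """Write a 2D image, image stack or 3D volume as float32 MRC2014.

    Parameters
    ----------
    data : ndarray
        2D ``(ny, nx)`` or 3D ``(nz, ny, nx)`` array.
    voxel_size : float
        Isotropic voxel/pixel size in Å.
    is_stack : bool
        Mark a 3D array as a stack of 2D images (ISPG 0) rather than a
        volume (ISPG 1).
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None, ...]
        is_stack = True
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    nz, ny, nx = data.shape
    ispg = 0 if is_stack else 1
    mz = 1 if is_stack else nz
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)       # MODE
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, mz)         # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * voxel_size, ny * voxel_size,
                     mz * voxel_size)                        # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))                     # DMIN DMAX DMEAN
    struct.pack_into("<i", header, 88, ispg)                # ISPG
    struct.pack_into("<i", header, 92, 0)                   # NSYMBT
    struct.pack_into("<3f", header, 196, *map(float, origin))  # ORIGIN
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(data.std()))  # RMS
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float, float]]:
    """Read an MRC file written by :func:`write_mrc` (or compatible).

    Returns
    -------
    data : ndarray
        ``(nz, ny, nx)`` float array (2D files come back with nz == 1).
    voxel_size : float
        Voxel size in Å (from CELLA / MX).
    origin : tuple of float
        ORIGIN header fields in Å.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode, = struct.unpack_from("<i", raw, 12)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt, = struct.unpack_from("<i", raw, 92)
    origin = struct.unpack_from("<3f", raw, 196)
    dtypes = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16, 12: np.float16}
    if mode not in dtypes:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    dt = np.dtype(dtypes[mode]).newbyteorder("<")
    offset = _HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dt, count=count, offset=offset)
    data = data.reshape(nz, ny, nx).astype(np.float64)
    voxel = xlen / mx if mx else 1.0
    return data, float(voxel), tuple(float(o) for o in origin)
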