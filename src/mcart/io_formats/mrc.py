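"""Minimal MRC2014 volume I/O.

Only the subset of the standard needed for tomogram grids is implemented:
modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16), little- and big-endian
files, no extended headers on write (skipped on read via ``nsymbt``).

Index convention: ``data[z, y, x]`` with x fastest, matching the on-disk
section order. Physical units in the header are ångströms.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mcart.errors import FormatError

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


@dataclass
class DensityVolume:
    """3D scalar grid with physical metadata.

    Attributes
    ----------
    data:
        Array of shape ``(nz, ny, nx)``.
    voxel_size_A:
        Isotropic voxel size in ångströms.
    origin_A:
        Physical position of the centre of voxel (0, 0, 0), as ``(x, y, z)``
        in ångströms.
    """

    data: np.ndarray
    voxel_size_A: float
    origin_A: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin_A = np.asarray(self.origin_A, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if min(self.data.shape) < 2:
            raise ValueError("grid dimensions must be >= 2 per axis")
        if not self.voxel_size_A > 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def voxel_size_nm(self) -> float:
        return self.voxel_size_A / 10.0

    @property
    def origin_nm(self) -> np.ndarray:
        return self.origin_A / 10.0

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return nx, ny, nz

    def extent_nm(self) -> np.ndarray:
        """Physical extent ``(x, y, z)`` from first to last voxel centre."""
        return (np.array(self.shape_xyz) - 1) * self.voxel_size_nm

    def index_from_nm(self, points_nm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices ``(x, y, z)`` for physical points in nm."""
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        return (pts - self.origin_nm) / self.voxel_size_nm


def _unpack_header(raw: bytes):
    machst = raw[212:216]
    if machst[:1] == b"\x11":
        endian = ">"
    else:
        endian = "<"  # 0x44 0x44 / 0x44 0x41 and legacy zeros
    ints = struct.unpack(endian + "10i", raw[:40])
    return endian, ints


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 file into a :class:`DensityVolume`.

    Anisotropic voxel sizes trigger a warning and the mean is used.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    if raw[208:211] not in (b"MAP", b"\x00\x00\x00"):
        raise FormatError(f"{path}: bad MAP magic in header word 53 (got {raw[208:212]!r})")

    endian, ints = _unpack_header(raw)
    nx, ny, nz, mode = ints[0], ints[1], ints[2], ints[3]
    mx, my, mz = ints[7], ints[8], ints[9]
    cella = struct.unpack(endian + "3f", raw[40:52])
    origin = struct.unpack(endian + "3f", raw[196:208])
    nsymbt = struct.unpack(endian + "i", raw[92:96])[0]

    for name, val in (("nx", nx), ("ny", ny), ("nz", nz)):
        if val <= 0 or val > 100_000:
            raise FormatError(f"{path}: implausible header field {name}={val}")
    if mode not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported header field mode={mode}")

    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(endian)
    count = nx * ny * nz
    start = _HEADER_SIZE + max(nsymbt, 0)
    expected = start + count * dtype.itemsize
    if len(raw) < expected:
        raise FormatError(
            f"{path}: data section truncated (header field nsymbt={nsymbt}, "
            f"need {expected} bytes, have {len(raw)})"
        )
    data = np.frombuffer(raw[start:expected], dtype=dtype).reshape(nz, ny, nx)

    grid = np.array([mx or nx, my or ny, mz or nz], dtype=float)
    vsize = np.array(cella, dtype=float) / grid
    if np.any(vsize <= 0):
        vsize = np.full(3, 1.0)
    if not np.allclose(vsize, vsize[0], rtol=1e-4):
        warnings.warn(
            f"{path}: anisotropic voxel size {tuple(np.round(vsize, 4))} A; using mean",
            stacklevel=2,
        )
    return DensityVolume(
        data=data.astype(data.dtype.newbyteorder("=")),
        voxel_size_A=float(vsize.mean()),
        origin_A=np.array(origin, dtype=float),
    )


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write a :class:`DensityVolume` as little-endian MRC2014.

    The data section is written byte-identically from the array (dtype is
    preserved for int8/int16/uint16; everything else becomes float32).
    """
    data = volume.data
    mode = {np.dtype(np.int8): 0, np.dtype(np.int16): 1, np.dtype(np.uint16): 6}.get(
        data.dtype, 2
    )
    if mode == 2:
        data = data.astype(np.float32)
    nz, ny, nx = data.shape
    cella = tuple(float(volume.voxel_size_A * n) for n in (nx, ny, nz))

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    finite = data[np.isfinite(data)]
    dmin, dmax, dmean = (
        (float(finite.min()), float(finite.max()), float(finite.mean()))
        if finite.size
        else (0.0, 0.0, 0.0)
    )
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1)  # ispg: volume stack convention
    struct.pack_into("<3f", header, 196, *[float(o) for o in volume.origin_A])
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"
    struct.pack_into("<f", header, 216, float(finite.std()) if finite.size else 0.0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())
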