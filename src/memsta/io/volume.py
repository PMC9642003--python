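"""Volume container and MRC2014 reader/writer.

Volumes are stored with ``data[x, y, z]`` indexing (x fastest on disk, as in
the MRC convention), voxel size in Angstrom, and a physical origin.  Only
mode-2 (float32) MRC files are produced; modes 0/1/2/6 are accepted on read
and promoted to float.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "read_mrc", "write_mrc"]

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


@dataclass
class VolumeGrid:
    """A 3D scalar grid (density, segmentation label, or mask)."""

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        if min(self.data.shape) < 1:
            raise ValueError("volume dimensions must each be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def write_mrc(grid: VolumeGrid, path) -> None:
    """Write a volume as MRC2014, mode 2 (float32), x fastest."""
    data = np.ascontiguousarray(grid.data.astype(np.float32))
    nx, ny, nz = data.shape
    vs = float(grid.voxel_size)
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode 2: float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    struct.pack_into("<i", header, 108, 20140)  # nversion
    struct.pack_into("<3f", header, 196, *grid.origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # file order: x fastest, z slowest
        fh.write(data.transpose(2, 1, 0).tobytes())


def read_mrc(path) -> VolumeGrid:
    """Read an MRC2014 volume; returns data indexed ``[x, y, z]``."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"truncated MRC header in {path}")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode not in _MRC_MODES:
            raise ValueError(f"unsupported MRC mode {mode} in {path}")
        mx = struct.unpack_from("<i", header, 28)[0] or nx
        cella_x = struct.unpack_from("<f", header, 40)[0]
        voxel_size = cella_x / mx if cella_x > 0 else 1.0
        origin = np.array(struct.unpack_from("<3f", header, 196))
        dtype = _MRC_MODES[mode]
        count = nx * ny * nz
        raw = np.frombuffer(fh.read(count * np.dtype(dtype).itemsize), dtype=dtype)
        if raw.size != count:
            raise ValueError(f"truncated MRC data in {path}")
    data = raw.reshape(nz, ny, nx).transpose(2, 1, 0).astype(np.float32)
    return VolumeGrid(data=data, voxel_size=voxel_size, origin=origin)
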