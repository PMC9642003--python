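"""AV3/TOM motive list (.em) reader/writer.

An EM file is a 512-byte header followed by the data.  Header bytes used
here: byte 0 machine code (6, PC/little-endian), byte 3 the data-type code
(5 = float32), bytes 4-15 three little-endian int32 dimensions.  A motive
list is a 20 x N float32 matrix, x (the 20 fields) fastest; mapped rows
(1-based):

====== ===========================
1      cross-correlation score
5      tomogram index
6      membrane-object index
7      tag
8-10   x, y, z (voxels, 1-based)
11-13  shifts dx, dy, dz
17-19  Euler triplet (ZXZ, degrees)
20     class label
====== ===========================
"""

from __future__ import annotations

import struct

import numpy as np

from ..geometry import euler_to_matrix, matrix_to_euler
from ..particles import ParticleSet

__all__ = ["read_motl", "write_motl", "read_em_matrix", "write_em_matrix"]

_EM_FLOAT32 = 5


def write_em_matrix(matrix: np.ndarray, path) -> None:
    """Write a 2D (or 3D) float32 matrix in EM format, x fastest."""
    data = np.atleast_3d(np.asarray(matrix, dtype=np.float32))
    xdim, ydim, zdim = data.shape
    header = bytearray(512)
    header[0] = 6  # machine: PC
    header[3] = _EM_FLOAT32
    struct.pack_into("<3i", header, 4, xdim, ydim, zdim)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def read_em_matrix(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(512)
        if len(header) < 512:
            raise ValueError(f"truncated EM header in {path}")
        dtype_code = header[3]
        if dtype_code != _EM_FLOAT32:
            raise ValueError(
                f"{path}: unsupported EM data-type code {dtype_code} (expect 5 = float32)"
            )
        xdim, ydim, zdim = struct.unpack_from("<3i", header, 4)
        count = xdim * ydim * zdim
        raw = np.frombuffer(fh.read(count * 4), dtype="<f4")
        if raw.size != count:
            raise ValueError(f"truncated EM data in {path}")
    return raw.reshape(zdim, ydim, xdim).transpose(2, 1, 0).squeeze(axis=2)


def read_motl(path, voxel_size: float = 1.0) -> ParticleSet:
    m = read_em_matrix(path)
    if m.ndim == 1:  # single column squeezed
        m = m[:, None]
    if m.shape[0] != 20:
        raise ValueError(
            f"{path}: motive list must be 20 x N, got first dimension {m.shape[0]}"
        )
    n = m.shape[1]
    if n == 0:
        return ParticleSet.empty(voxel_size)
    matrices = np.array([euler_to_matrix(tri, "dynamo_zxz") for tri in m[16:19].T])
    pset = ParticleSet(
        tags=m[6].astype(np.int64),
        tomo_id=m[4].astype(np.int64),
        object_id=m[5].astype(np.int64),
        positions=m[7:10].T - 1.0,  # motive lists are 1-based
        shifts=m[10:13].T,
        matrices=matrices,
        cc=m[0].astype(float),
        class_label=m[19].astype(np.int64),
        voxel_size=voxel_size,
    )
    pset.log(f"read_motl: {len(pset)} particles from {path}")
    return pset


def write_motl(pset: ParticleSet, path) -> None:
    n = len(pset)
    m = np.zeros((20, n), dtype=np.float32)
    if n:
        eulers = np.array([matrix_to_euler(mat, "dynamo_zxz") for mat in pset.matrices])
        m[0] = pset.cc
        m[4] = pset.tomo_id
        m[5] = pset.object_id
        m[6] = pset.tags
        m[7:10] = (pset.positions + 1.0).T
        m[10:13] = pset.shifts.T
        m[16:19] = eulers.T
        m[19] = pset.class_label
    write_em_matrix(m, path)
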