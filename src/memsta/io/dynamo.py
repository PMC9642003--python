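"""Dynamo table (.tbl) reader/writer.

A Dynamo table is whitespace-separated ASCII, one row per particle, at
least 26 columns.  Mapped columns (1-based, as in Dynamo's documentation):

====== =======================================
1      tag
4-6    shift dx, dy, dz (voxels)
7-9    tdrot, tilt, narot (degrees, ZXZ)
10     cross-correlation score
20     tomogram index
21     membrane-object (region) index
24-26  x, y, z coordinate (voxels, 1-based)
====== =======================================

Coordinates are converted to the package's 0-based convention on read and
back to 1-based on write.  Unmapped columns of a table that was read from
disk are preserved verbatim when the same set is written again.
"""

from __future__ import annotations

import numpy as np

from ..geometry import euler_to_matrix, matrix_to_euler
from ..particles import ParticleSet

__all__ = ["read_dynamo_table", "write_dynamo_table", "DYNAMO_NCOLS"]

DYNAMO_NCOLS = 35  # columns written for a freshly created table
_INT_COLS = {0, 1, 2, 19, 20, 21, 22}  # 0-based: tag, aligned, averaged, tomo, reg, ...


def read_dynamo_table(path, voxel_size: float = 1.0) -> ParticleSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 26:
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields)} columns, need >= 26"
                )
            rows.append([float(v) for v in fields])
    if not rows:
        raise ValueError(f"{path}: empty Dynamo table")
    width = max(len(r) for r in rows)
    raw = np.zeros((len(rows), width))
    for i, r in enumerate(rows):
        raw[i, : len(r)] = r

    matrices = np.array(
        [euler_to_matrix(tri, "dynamo_zxz") for tri in raw[:, 6:9]]
    )
    pset = ParticleSet(
        tags=raw[:, 0].astype(np.int64),
        tomo_id=raw[:, 19].astype(np.int64),
        object_id=raw[:, 20].astype(np.int64),
        positions=raw[:, 23:26] - 1.0,  # Dynamo is 1-based
        shifts=raw[:, 3:6],
        matrices=matrices,
        cc=raw[:, 9],
        voxel_size=voxel_size,
    )
    pset.log(f"read_dynamo_table: {len(pset)} particles from {path}")
    # stash raw table so unmapped columns survive a rewrite
    pset._dynamo_raw = raw  # type: ignore[attr-defined]
    return pset


def write_dynamo_table(pset: ParticleSet, path) -> None:
    if len(pset) == 0:
        raise ValueError("refusing to write an empty Dynamo table")
    raw = getattr(pset, "_dynamo_raw", None)
    if raw is not None and raw.shape[0] == len(pset):
        table = raw.copy()
    else:
        table = np.zeros((len(pset), DYNAMO_NCOLS))
        table[:, 1] = 1.0  # aligned flag
    eulers = np.array(
        [matrix_to_euler(m, "dynamo_zxz") for m in pset.matrices]
    )
    table[:, 0] = pset.tags
    table[:, 3:6] = pset.shifts
    table[:, 6:9] = eulers
    table[:, 9] = pset.cc
    table[:, 19] = pset.tomo_id
    table[:, 20] = pset.object_id
    table[:, 23:26] = pset.positions + 1.0

    with open(path, "w") as fh:
        for row in table:
            fields = [
                str(int(round(v))) if j in _INT_COLS else f"{v:.6f}"
                for j, v in enumerate(row)
            ]
            fh.write(" ".join(fields) + "\n")
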