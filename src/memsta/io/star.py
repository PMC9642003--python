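"""RELION particle STAR reader/writer.

One dialect is pinned: a ``data_optics`` block recording the pixel size and
a ``data_particles`` loop with 0-based coordinates in voxels, ZYZ Euler
angles in degrees, and origins in Angstrom.  Orientation conversion always
goes through rotation matrices (never direct angle arithmetic), so a
Dynamo -> STAR -> Dynamo round trip preserves every rotation matrix.

RELION's origin columns (``rlnOriginXAngst`` ...) are offsets *subtracted*
from the coordinate, whereas the internal shift is *added* to the position;
the sign is flipped at this boundary.
"""

from __future__ import annotations

import numpy as np

from ..geometry import euler_to_matrix, matrix_to_euler
from ..particles import ParticleSet

__all__ = ["read_star", "write_star"]

_PARTICLE_COLS = [
    "rlnTomoName",
    "rlnTomoParticleId",
    "rlnObjectNumber",
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnOriginXAngst",
    "rlnOriginYAngst",
    "rlnOriginZAngst",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnAutopickFigureOfMerit",
    "rlnClassNumber",
]

_REQUIRED = [
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
]


def write_star(pset: ParticleSet, path) -> None:
    eulers = np.array(
        [matrix_to_euler(m, "relion_zyz") for m in pset.matrices]
    ).reshape(len(pset), 3)
    with open(path, "w") as fh:
        fh.write("\ndata_optics\n\nloop_\n")
        fh.write("_rlnOpticsGroup #1\n_rlnImagePixelSize #2\n")
        fh.write(f"1 {pset.voxel_size:.6f}\n")
        fh.write("\ndata_particles\n\nloop_\n")
        for i, col in enumerate(_PARTICLE_COLS, start=1):
            fh.write(f"_{col} #{i}\n")
        for i in range(len(pset)):
            x, y, z = pset.positions[i]
            dx, dy, dz = pset.shifts[i] * pset.voxel_size
            rot, tilt, psi = eulers[i]
            fh.write(
                f"tomo_{pset.tomo_id[i]} {pset.tags[i]} {pset.object_id[i]} "
                f"{x:.6f} {y:.6f} {z:.6f} "
                f"{-dx:.6f} {-dy:.6f} {-dz:.6f} "
                f"{rot:.6f} {tilt:.6f} {psi:.6f} "
                f"{pset.cc[i]:.6f} {pset.class_label[i]}\n"
            )


def _parse_star_blocks(path) -> dict[str, dict]:
    """Minimal STAR parser: every block is returned as {column: list-of-str}."""
    blocks: dict[str, dict] = {}
    block_name = None
    columns: list[str] = []
    rows: list[list[str]] = []
    state = "idle"  # idle | in_block | in_loop_header | in_loop_rows

    def flush():
        if block_name is not None and columns:
            blocks[block_name] = {
                c: [r[j] for r in rows] for j, c in enumerate(columns)
            }

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                block_name = line[5:]
                columns, rows = [], []
                state = "in_block"
            elif line == "loop_":
                state = "in_loop_header"
            elif line.startswith("_"):
                name = line.split()[0].lstrip("_")
                if state == "in_loop_header":
                    columns.append(name)
                else:  # simple key-value pair
                    columns.append(name)
                    rows = rows or [[]]
                    rows[0].append(line.split()[1])
            else:
                if state == "in_loop_header":
                    state = "in_loop_rows"
                fields = line.split()
                if columns and len(fields) == len(columns):
                    rows.append(fields)
    flush()
    return blocks


def read_star(path, voxel_size: float | None = None) -> ParticleSet:
    blocks = _parse_star_blocks(path)
    if "particles" not in blocks:
        raise ValueError(f"{path}: no data_particles block")
    part = blocks["particles"]
    missing = [c for c in _REQUIRED if c not in part]
    if missing:
        raise ValueError(f"{path}: missing required STAR columns: {', '.join(missing)}")
    if voxel_size is None:
        optics = blocks.get("optics", {})
        if "rlnImagePixelSize" in optics:
            voxel_size = float(optics["rlnImagePixelSize"][0])
        else:
            voxel_size = 1.0

    n = len(part["rlnCoordinateX"])
    as_f = lambda col, default=0.0: (
        np.array([float(v) for v in part[col]]) if col in part else np.full(n, default)
    )
    positions = np.stack(
        [as_f("rlnCoordinateX"), as_f("rlnCoordinateY"), as_f("rlnCoordinateZ")], axis=1
    )
    shifts = (
        -np.stack(
            [as_f("rlnOriginXAngst"), as_f("rlnOriginYAngst"), as_f("rlnOriginZAngst")],
            axis=1,
        )
        / voxel_size
    )
    eulers = np.stack([as_f("rlnAngleRot"), as_f("rlnAngleTilt"), as_f("rlnAnglePsi")], axis=1)
    matrices = np.array([euler_to_matrix(tri, "relion_zyz") for tri in eulers])

    if "rlnTomoName" in part:
        tomo_id = np.array(
            [int(v.rsplit("_", 1)[-1]) if "_" in v else 0 for v in part["rlnTomoName"]]
        )
    else:
        tomo_id = np.zeros(n, dtype=np.int64)
    tags = (
        np.array([int(float(v)) for v in part["rlnTomoParticleId"]])
        if "rlnTomoParticleId" in part
        else np.arange(1, n + 1)
    )
    object_id = (
        np.array([int(float(v)) for v in part["rlnObjectNumber"]])
        if "rlnObjectNumber" in part
        else np.ones(n, dtype=np.int64)
    )
    pset = ParticleSet(
        tags=tags,
        tomo_id=tomo_id,
        object_id=object_id,
        positions=positions,
        shifts=shifts,
        matrices=matrices,
        cc=as_f("rlnAutopickFigureOfMerit"),
        class_label=as_f("rlnClassNumber", 1.0).astype(np.int64),
        voxel_size=voxel_size,
    )
    pset.log(f"read_star: {len(pset)} particles from {path}")
    return pset
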