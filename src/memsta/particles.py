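"""Particle and ParticleSet containers.

A :class:`ParticleSet` is the in-memory form of a Dynamo table / AV3 motive
list: positions and alignment shifts in voxels (0-based internally),
orientations as rotation matrices, cross-correlation scores, and the
tomogram / membrane-object bookkeeping every cleaning stage groups by.
Columns are stored as parallel numpy arrays so the cleaning algorithms can
stay vectorised; :class:`Particle` is a convenience record view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Orientation

__all__ = ["Particle", "ParticleSet"]


@dataclass
class Particle:
    """A single subtomogram record (row view of a :class:`ParticleSet`)."""

    tag: int
    tomo_id: int
    object_id: int
    position: np.ndarray
    shift: np.ndarray
    orientation: Orientation
    cc: float = 0.0
    cc_adj: float | None = None
    class_label: int = 1


@dataclass
class ParticleSet:
    """An ordered collection of particles with shared metadata.

    Attributes
    ----------
    tags : (N,) int array, unique positive identifiers
    tomo_id, object_id : (N,) int arrays, tomogram and membrane-object indices
    positions : (N, 3) float array, voxels, 0-based
    shifts : (N, 3) float array, voxels (refined offset to add to position)
    matrices : (N, 3, 3) float array, particle->tomogram rotation matrices
    cc : (N,) float array, cross-correlation scores
    cc_adj : (N,) float array or None, theta-normalised scores
    class_label : (N,) int array
    voxel_size : float, Angstrom per voxel
    provenance : list of str, log of operations applied
    """

    tags: np.ndarray
    tomo_id: np.ndarray
    object_id: np.ndarray
    positions: np.ndarray
    shifts: np.ndarray
    matrices: np.ndarray
    cc: np.ndarray
    cc_adj: np.ndarray | None = None
    class_label: np.ndarray | None = None
    voxel_size: float = 1.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.tags)
        self.tags = np.asarray(self.tags, dtype=np.int64)
        self.tomo_id = np.asarray(self.tomo_id, dtype=np.int64)
        self.object_id = np.asarray(self.object_id, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.shifts = np.asarray(self.shifts, dtype=float).reshape(n, 3)
        self.matrices = np.asarray(self.matrices, dtype=float).reshape(n, 3, 3)
        self.cc = np.asarray(self.cc, dtype=float).reshape(n)
        if self.cc_adj is not None:
            self.cc_adj = np.asarray(self.cc_adj, dtype=float).reshape(n)
        if self.class_label is None:
            self.class_label = np.ones(n, dtype=np.int64)
        else:
            self.class_label = np.asarray(self.class_label, dtype=np.int64).reshape(n)
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls, voxel_size: float = 1.0) -> "ParticleSet":
        return cls(
            tags=np.empty(0, dtype=np.int64),
            tomo_id=np.empty(0, dtype=np.int64),
            object_id=np.empty(0, dtype=np.int64),
            positions=np.empty((0, 3)),
            shifts=np.zeros((0, 3)),
            matrices=np.empty((0, 3, 3)),
            cc=np.empty(0),
            voxel_size=voxel_size,
        )

    @classmethod
    def from_particles(cls, particles, voxel_size: float = 1.0) -> "ParticleSet":
        particles = list(particles)
        if not particles:
            return cls.empty(voxel_size)
        return cls(
            tags=np.array([p.tag for p in particles]),
            tomo_id=np.array([p.tomo_id for p in particles]),
            object_id=np.array([p.object_id for p in particles]),
            positions=np.array([p.position for p in particles], dtype=float),
            shifts=np.array([p.shift for p in particles], dtype=float),
            matrices=np.array([p.orientation.matrix for p in particles]),
            cc=np.array([p.cc for p in particles], dtype=float),
            cc_adj=(
                np.array([p.cc_adj for p in particles], dtype=float)
                if all(p.cc_adj is not None for p in particles)
                else None
            ),
            class_label=np.array([p.class_label for p in particles]),
            voxel_size=voxel_size,
        )

    # -- contracts --------------------------------------------------------

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(np.unique(self.tags)) != len(self.tags):
            raise ValueError("particle tags must be unique within a set")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("particle positions must be finite")
        if not np.all(np.isfinite(self.cc)):
            raise ValueError("cc scores must be finite")

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tags)

    def __getitem__(self, i: int) -> Particle:
        return Particle(
            tag=int(self.tags[i]),
            tomo_id=int(self.tomo_id[i]),
            object_id=int(self.object_id[i]),
            position=self.positions[i].copy(),
            shift=self.shifts[i].copy(),
            orientation=Orientation(self.matrices[i]),
            cc=float(self.cc[i]),
            cc_adj=None if self.cc_adj is None else float(self.cc_adj[i]),
            class_label=int(self.class_label[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def subset(self, index) -> "ParticleSet":
        """New set with rows selected by an integer or boolean index array."""
        return ParticleSet(
            tags=self.tags[index],
            tomo_id=self.tomo_id[index],
            object_id=self.object_id[index],
            positions=self.positions[index],
            shifts=self.shifts[index],
            matrices=self.matrices[index],
            cc=self.cc[index],
            cc_adj=None if self.cc_adj is None else self.cc_adj[index],
            class_label=self.class_label[index],
            voxel_size=self.voxel_size,
            provenance=list(self.provenance),
        )

    def copy(self) -> "ParticleSet":
        return self.subset(slice(None))

    def groups(self):
        """Yield ((tomo_id, object_id), row-index array) per membrane object."""
        keys = np.stack([self.tomo_id, self.object_id], axis=1)
        uniq = np.unique(keys, axis=0)
        for tomo, obj in uniq:
            idx = np.nonzero((self.tomo_id == tomo) & (self.object_id == obj))[0]
            yield (int(tomo), int(obj)), idx

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tag": self.tags,
                "tomo_id": self.tomo_id,
                "object_id": self.object_id,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "dx": self.shifts[:, 0],
                "dy": self.shifts[:, 1],
                "dz": self.shifts[:, 2],
                "cc": self.cc,
                "class_label": self.class_label,
            }
        )
        if self.cc_adj is not None:
            df["cc_adj"] = self.cc_adj
        return df
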