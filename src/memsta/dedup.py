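"""Duplicate removal after coarse alignment.

Oversampled picks that contain the same particle converge to (nearly) the
same refined coordinates; a minimum "separation in tomogram" then flags the
redundant copies.  The filter is greedy by descending cross-correlation,
per membrane object, so the best-scoring pick of each converged cluster is
the one retained.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .particles import ParticleSet

__all__ = ["apply_shifts", "remove_duplicates"]


def apply_shifts(pset: ParticleSet) -> ParticleSet:
    """Fold refined shifts into positions (position += shift; shift = 0)."""
    out = pset.copy()
    out.positions = out.positions + out.shifts
    out.shifts = np.zeros_like(out.shifts)
    out.log("apply_shifts")
    return out


def remove_duplicates(
    pset: ParticleSet,
    min_separation: float,
    group_by_object: bool = True,
) -> ParticleSet:
    """Greedily keep the best-scoring particle of every converged cluster.

    Within each (tomo_id, object_id) group, particles are visited in order
    of decreasing cc (ties broken by lower tag) and accepted iff they lie at
    least ``min_separation`` voxels from every already-accepted particle.
    The returned set preserves the original row order.

    ``group_by_object=False`` pools all particles of a tomogram, for cases
    where distinct membrane objects can converge to the same coordinates.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if np.any(np.abs(pset.shifts) > 1e-9):
        warnings.warn(
            "particles carry non-zero shifts; run apply_shifts first so "
            "duplicates are measured at their converged positions",
            stacklevel=2,
        )
    keep = np.zeros(len(pset), dtype=bool)
    if group_by_object:
        group_keys = list(pset.groups())
    else:
        group_keys = [
            (int(t), np.nonzero(pset.tomo_id == t)[0]) for t in np.unique(pset.tomo_id)
        ]
    for _, idx in group_keys:
        order = idx[np.lexsort((pset.tags[idx], -pset.cc[idx]))]
        accepted: list[int] = []
        pos = pset.positions
        tree = None
        for i in order:
            if accepted:
                if tree is None or len(accepted) % 256 == 0:
                    tree = cKDTree(pos[accepted])
                    tree_size = len(accepted)
                ok = not tree.query_ball_point(pos[i], min_separation - 1e-12)
                if ok and len(accepted) > tree_size:
                    d = np.linalg.norm(pos[accepted[tree_size:]] - pos[i], axis=1)
                    ok = bool(np.all(d >= min_separation))
                if not ok:
                    continue
            accepted.append(i)
        keep[accepted] = True
    out = pset.subset(keep)
    out.log(
        f"remove_duplicates: min_separation={min_separation}, kept {len(out)}/{len(pset)}"
    )
    return out
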