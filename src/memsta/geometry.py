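"""Rotation and Euler-angle mathematics for particle orientations.

Orientations are stored internally as 3x3 rotation matrices that map
particle-frame vectors into tomogram-frame vectors (column-vector action).
Euler triplets exist only at the I/O boundaries, where the two conventions
used by the supported subtomogram-averaging packages are interpreted as:

``dynamo_zxz``
    triplet (tdrot, tilt, narot), R = Rz(narot) @ Rx(tilt) @ Rz(tdrot)

``relion_zyz``
    triplet (rot, tilt, psi), R = Rz(rot) @ Ry(tilt) @ Rz(psi)

with the elementary Rz(a) rotating +x toward +y for positive a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Orientation",
    "euler_to_matrix",
    "matrix_to_euler",
    "theta_of",
    "normal_to_orientation",
    "random_rotation_matrix",
    "CONVENTIONS",
]

CONVENTIONS = ("dynamo_zxz", "relion_zyz")

_ORTHO_TOL = 1e-9
# |sin(tilt)| below this is treated as gimbal lock; kept tiny because the
# atan2-based extraction stays accurate arbitrarily close to lock, and a
# loose threshold would itself inject error above the 1e-9 round-trip
# contract just outside it
_GIMBAL_EPS = 1e-12


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class Orientation:
    """A proper rotation mapping particle-frame vectors to tomogram-frame vectors.

    The particle z-axis (third matrix column) is, by construction throughout
    this package, the local membrane normal.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"orientation matrix must be 3x3, got {m.shape}")
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
            raise ValueError("orientation matrix is not orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("orientation matrix is a reflection (det < 0)")
        object.__setattr__(self, "matrix", m)

    @property
    def z_axis(self) -> np.ndarray:
        """Particle z-axis (membrane normal) in tomogram coordinates."""
        return self.matrix[:, 2]

    def compose(self, other: "Orientation") -> "Orientation":
        return Orientation(self.matrix @ other.matrix)


def euler_to_matrix(angles, convention: str) -> np.ndarray:
    """Compose a rotation matrix from an Euler triplet in degrees.

    Parameters
    ----------
    angles : sequence of 3 floats, degrees
    convention : {"dynamo_zxz", "relion_zyz"}
    """
    a1, a2, a3 = (float(a) for a in angles)
    if convention == "dynamo_zxz":
        return _rot_z(a3) @ _rot_x(a2) @ _rot_z(a1)
    if convention == "relion_zyz":
        return _rot_z(a1) @ _rot_y(a2) @ _rot_z(a3)
    raise ValueError(
        f"unknown Euler convention {convention!r}; supported: {', '.join(CONVENTIONS)}"
    )


def matrix_to_euler(matrix: np.ndarray, convention: str) -> tuple[float, float, float]:
    """Decompose a rotation matrix into an Euler triplet in degrees.

    At gimbal lock (|sin tilt| < 1e-8) the third element of the triplet is
    set to 0 and the full in-plane spin is folded into the first element, so
    the decomposition is deterministic.
    """
    m = np.asarray(matrix, dtype=float)
    if convention == "dynamo_zxz":
        # R = Rz(narot) Rx(tilt) Rz(tdrot); R[2,2] = cos(tilt),
        # hypot(R[2,0], R[2,1]) = sin(tilt) — atan2 keeps precision near lock
        ct = np.clip(m[2, 2], -1.0, 1.0)
        st = float(np.hypot(m[2, 0], m[2, 1]))
        tilt = np.degrees(np.arctan2(st, ct))
        if st < _GIMBAL_EPS:
            if ct > 0:  # R = Rz(narot + tdrot)
                tdrot = np.degrees(np.arctan2(m[1, 0], m[0, 0]))
                tilt = 0.0
            else:  # R = Rz(narot - tdrot) Rx(180); with narot=0: Rz(-tdrot) Rx(180)
                tdrot = np.degrees(np.arctan2(-m[0, 1], m[0, 0]))
                tilt = 180.0
            return (tdrot, tilt, 0.0)
        tdrot = np.degrees(np.arctan2(m[2, 0], m[2, 1]))
        narot = np.degrees(np.arctan2(m[0, 2], -m[1, 2]))
        return (tdrot, tilt, narot)
    if convention == "relion_zyz":
        # R = Rz(rot) Ry(tilt) Rz(psi); R[2,2] = cos(tilt)
        ct = np.clip(m[2, 2], -1.0, 1.0)
        st = float(np.hypot(m[2, 0], m[2, 1]))
        tilt = np.degrees(np.arctan2(st, ct))
        if st < _GIMBAL_EPS:
            if ct > 0:  # R = Rz(rot + psi)
                rot = np.degrees(np.arctan2(m[1, 0], m[0, 0]))
                tilt = 0.0
            else:  # R = Rz(rot - psi) Ry(180); with psi=0: [[-c, -s, 0], [-s, c, 0], ...]
                rot = np.degrees(np.arctan2(-m[1, 0], -m[0, 0]))
                tilt = 180.0
            return (rot, tilt, 0.0)
        rot = np.degrees(np.arctan2(m[1, 2], m[0, 2]))
        psi = np.degrees(np.arctan2(m[2, 1], -m[2, 0]))
        return (rot, tilt, psi)
    raise ValueError(
        f"unknown Euler convention {convention!r}; supported: {', '.join(CONVENTIONS)}"
    )


def theta_of(orientation) -> float:
    """Latitude angle theta in degrees, in [0, 90].

    Theta is the angle between the particle z-axis (membrane normal) and the
    tomogram beam axis (0, 0, 1): 0 for top/bottom views, 90 for side views.
    The missing wedge penalises views symmetrically above and below the
    equator, so normals at theta and 180-theta are folded together by taking
    |cos theta|.
    """
    m = orientation.matrix if isinstance(orientation, Orientation) else np.asarray(orientation)
    return float(np.degrees(np.arccos(min(1.0, abs(float(m[2, 2]))))))


def theta_of_matrices(matrices: np.ndarray) -> np.ndarray:
    """Vectorised :func:`theta_of` for an (N, 3, 3) stack."""
    zz = np.abs(np.asarray(matrices)[..., 2, 2])
    return np.degrees(np.arccos(np.clip(zz, 0.0, 1.0)))


# deterministic fallback references when the requested one is (near-)parallel
# to the normal: global +Z first, then +X
_FALLBACK_REFS = (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))


def normal_to_orientation(normal, in_plane_reference=None) -> Orientation:
    """Build an orientation whose z-axis is the given membrane normal.

    The first column (particle x-axis) is ``in_plane_reference`` projected
    onto the plane perpendicular to the normal and renormalised; the second
    column completes a right-handed frame.  When the reference is missing or
    nearly parallel to the normal the fallback order is global +Z, then +X.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("zero-length normal")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"normal must be unit length (got |n| = {norm:.3g})")
    n = n / norm

    candidates = []
    if in_plane_reference is not None:
        candidates.append(np.asarray(in_plane_reference, dtype=float))
    candidates.extend(_FALLBACK_REFS)

    for ref in candidates:
        x = ref - np.dot(ref, n) * n
        nx = np.linalg.norm(x)
        if nx > 1e-6:
            x = x / nx
            y = np.cross(n, x)
            return Orientation(np.column_stack([x, y, n]))
    raise AssertionError("unreachable: fallback references span R^3")


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation via quaternion sampling."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
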