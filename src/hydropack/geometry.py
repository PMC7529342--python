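"""Small vector-geometry helpers used throughout the package.

All coordinates are in Angstroms, in a right-handed Cartesian frame
(the PDB convention).  Angles are in degrees at the API surface and in
radians internally.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "norm",
    "unit",
    "angle_deg",
    "dihedral_deg",
    "rotation_about_axis",
    "rotation_align",
    "place_atom",
    "fibonacci_sphere",
    "rotation_angle_between",
    "quaternion_from_matrix",
]


def norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return np.asarray(v, dtype=float) / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u = unit(np.asarray(a, float) - b)
    v = unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about `axis`."""
    u = unit(axis)
    t = np.radians(angle_deg_)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)


def rotation_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction `a` onto direction `b`."""
    a = unit(a)
    b = unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D bonded to c.

    D is placed at distance `bond` from c, with angle b-c-D = `angle`
    (degrees) and dihedral a-b-c-D = `dihedral` (degrees).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    th = np.radians(angle)
    ph = np.radians(dihedral)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = ga * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def quaternion_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for a rotation matrix."""
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        w = 0.25 * s
        x = (R[2, 1] - R[1, 2]) / s
        y = (R[0, 2] - R[2, 0]) / s
        z = (R[1, 0] - R[0, 1]) / s
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1e-12, 1.0 + R[i, i] - R[j, j] - R[k, k])) * 2
        q = [0.0, 0.0, 0.0, 0.0]
        q[0] = (R[k, j] - R[j, k]) / s
        q[i + 1] = 0.25 * s
        q[j + 1] = (R[j, i] + R[i, j]) / s
        q[k + 1] = (R[k, i] + R[i, k]) / s
        w, x, y, z = q
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def rotation_angle_between(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic rotation angle (degrees) between two rotations."""
    R = Ra.T @ Rb
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
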