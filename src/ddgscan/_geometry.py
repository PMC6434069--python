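"""Small 3-D geometry helpers (angles, dihedrals, NeRF atom placement,
Kabsch superposition, ring planes).  All coordinates in Å, angles in degrees
unless noted."""

from __future__ import annotations

import numpy as np


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(-y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position of atom d with |cd| = bond_length,
    angle(b,c,d) = bond_angle and dihedral(a,b,c,d) = torsion."""
    bond_angle = np.radians(bond_angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * np.cos(bond_angle),
        bond_length * np.sin(bond_angle) * np.cos(torsion),
        bond_length * np.sin(bond_angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit-normalized internally) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target
    (row vectors; apply as x @ R.T + t)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = tc - mc @ r.T
    return r, t


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the least-squares plane through points."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def angular_difference(a: float, b: float) -> float:
    """Absolute circular difference between two angles in degrees (0..180)."""
    return abs(wrap_angle(a - b))
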