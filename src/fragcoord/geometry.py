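"""Small 3D geometry helpers shared by the builder and the evaluation metrics.

Everything here is plain NumPy on (n, 3) float64 arrays; angles are in
degrees at the API surface and radians internally.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "rotation_about_axis",
    "rotation_aligning",
    "angle_deg",
    "dihedral_deg",
    "circular_diff_deg",
    "kabsch_rmsd",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on (near-)zero input."""
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return np.asarray(v, dtype=float) / n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about *axis* (Rodrigues)."""
    k = unit(axis)
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector *a* onto unit vector *b*.

    The antiparallel case rotates 180 degrees about a deterministic
    perpendicular axis so repeated runs are bit-identical.
    """
    a = unit(a)
    b = unit(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # any perpendicular axis works; pick one deterministically
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, probe)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, probe))
        return rotation_about_axis(axis, np.pi)
    axis = np.cross(a, b)
    angle = np.arctan2(float(np.linalg.norm(axis)), c)
    return rotation_about_axis(axis, angle)


def angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = unit(np.asarray(p0) - np.asarray(p1))
    v = unit(np.asarray(p2) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def circular_diff_deg(a: float, b: float) -> float:
    """Absolute difference between two angles mapped to [0, 180]."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between point sets *p* and *q* (same ordering) over
    rigid superposition (optimal rotation + translation, least squares)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # proper rotation only: flip the smallest singular direction if needed
    e = np.array([1.0, 1.0, d])
    msd = (np.sum(pc**2) + np.sum(qc**2) - 2.0 * float(np.sum(s * e))) / len(p)
    return float(np.sqrt(max(msd, 0.0)))
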