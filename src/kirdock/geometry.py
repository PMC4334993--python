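"""Internal-coordinate geometry helpers (dihedrals, NeRF atom placement)."""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "bond_angle", "place_atom", "rotation_about_axis"]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle: float, torsion: float,
) -> np.ndarray:
    """Natural-extension placement of atom D bonded to ``c``.

    ``length`` = |D-c|, ``angle`` = angle(b, c, D) in degrees and
    ``torsion`` = dihedral(a, b, c, D) in degrees.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    angle_r = np.radians(angle)
    torsion_r = -np.radians(torsion)  # sign matches :func:`dihedral`
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # collinear reference frame: pick an arbitrary perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-6:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(angle_r),
        length * np.sin(angle_r) * np.cos(torsion_r),
        length * np.sin(angle_r) * np.sin(torsion_r),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis through the origin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
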