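"""Small geometry kernel: atom placement, dihedrals, Euler frames."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["place_atom", "dihedral", "bond_angle", "wrap_angle",
           "euler_to_matrix", "matrix_to_euler"]


def place_atom(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom from three reference positions (NeRF).

    ``bond`` is the a3-new distance, ``angle`` the a2-a3-new angle and
    ``torsion`` the a1-a2-a3-new dihedral; angles in radians.
    """
    b1 = a2 - a1
    b2 = a3 - a2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear reference frame: pick any perpendicular
        n = np.cross(b2, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(b2, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, b2n)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return a3 + d[0] * b2n + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians, in (-pi, pi]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in radians."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    w = np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return float(w) if np.isscalar(a) else w


def euler_to_matrix(euler: np.ndarray) -> np.ndarray:
    """Intrinsic z-y-x Euler triple (radians) -> rotation matrix."""
    return Rotation.from_euler("ZYX", euler).as_matrix()


def matrix_to_euler(mat: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(mat).as_euler("ZYX")
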