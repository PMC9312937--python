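"""Small internal geometry helpers (vectors in Angstrom, angles in degrees)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors."""
    c = float(np.dot(unit(a), unit(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0 = p0 - p1
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom D given A-B-C, |C-D|, angle(B,C,D), torsion(A,B,C,D).

    Standard natural-extension (NeRF) construction.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation by ``angle`` degrees about ``axis`` (Rodrigues formula)."""
    k = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
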