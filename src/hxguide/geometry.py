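"""Low-level vector geometry: dihedrals, internal-coordinate atom placement,
Kabsch superposition. All coordinates are (n, 3) float64 arrays in Angstrom,
all angles in degrees unless noted."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) p0-p1-p2-p3 in degrees, IUPAC convention.

    Accepts single points or stacked (n, 3) arrays (vectorized).
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 at vertex p1, degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom D from reference frame atoms a-b-c (NeRF construction).

    D is at distance `bond` from c, with angle(b, c, D) = `angle` and
    dihedral(a, b, c, D) = `dihedral_deg`.
    """
    ang = np.radians(angle)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                      angle_deg: float) -> np.ndarray:
    """Rotate coords by angle_deg about the line through `origin` along `axis`
    (right-hand rule)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(coords - origin) + origin


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between point sets after optimal rigid superposition of b onto a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # collinear/planar point sets leave the rotation underdetermined,
        # but the residual (all we use) is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
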