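"""Low-level vector geometry shared by the builders and analyses.

All routines are pure numpy and operate on coordinates in nm and angles in
degrees (matching the dihedral-box conventions used throughout).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral_angle",
    "bond_angle",
    "place_atom",
    "kabsch",
    "superpose_coords",
]


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (degrees, in (-180, 180]) for four points.

    Accepts stacked coordinates with shape (..., 3); broadcasts over leading
    dimensions.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Angle at p1 (degrees) for the triplet p0-p1-p2."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |CD| = bond_length, angle(B,C,D) = angle_deg and
    dihedral(A,B,C,D) = torsion_deg (natural extension reference frame)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # colinear reference; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * np.cos(angle),
        bond_length * np.sin(angle) * np.cos(torsion),
        -bond_length * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation, rmsd).  Applying
    ``coords @ R.T + t`` maps mobile coordinates into the reference frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    moved = x @ rot.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Superpose and return (transformed mobile coordinates, rmsd)."""
    rot, trans, rmsd = kabsch(mobile, reference)
    return np.asarray(mobile) @ rot.T + trans, rmsd
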