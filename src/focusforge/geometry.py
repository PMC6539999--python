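"""Rigid-body geometry primitives.

Internal-coordinate atom placement (NeRF), dihedral/angle measurement with the
IUPAC sign convention, axis rotations, and least-squares (Kabsch) superposition.
All angles are degrees; dihedrals live in [-180, 180).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_angle(deg: float) -> float:
    """Map an angle in degrees onto [-180, 180)."""
    return float((deg + 180.0) % 360.0 - 180.0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a, b, c) -> float:
    """Angle a-b-c at vertex b, in degrees [0, 180]."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float))
    w = _unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d (IUPAC convention), degrees in [-180, 180)."""
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(float(np.degrees(np.arctan2(-y, x))))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom d from internal coordinates relative to chain a-b-c.

    ``bond`` = |c-d|, ``angle`` = angle(b, c, d), ``dihedral`` = dihedral(a, b, c, d);
    angles in degrees.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    theta = np.radians(angle)
    chi = np.radians(dihedral)  # sign matches dihedral_deg's IUPAC convention
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotate_about_axis(coords: np.ndarray, origin, axis, angle: float) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis`` by ``angle`` deg."""
    coords = np.asarray(coords, float)
    origin = np.asarray(origin, float)
    rot = Rotation.from_rotvec(np.radians(angle) * _unit(np.asarray(axis, float)))
    return rot.apply(coords - origin) + origin


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with the transform x -> R @ x + t applied to mobile
    coordinates, and the post-fit RMSD in the units of the inputs.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without re-superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    if a.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
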