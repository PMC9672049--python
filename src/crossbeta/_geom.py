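"""Rigid-body and small-geometry primitives shared across modules."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .core import GeometryError


def kabsch(mobile: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns (R, t, rmsd) with ``R @ mobile_i + t ~ target_i`` and R a proper
    rotation (reflections are disallowed by flipping the smallest singular
    direction, the standard Kabsch correction).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("superposition requires two equal-length (n,3) coordinate sets")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def screw_decompose(R: np.ndarray, t: np.ndarray, ref_axis: np.ndarray
                    ) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """Decompose a rigid transform into screw parameters.

    The rotation angle is signed relative to ``ref_axis`` (positive =
    right-handed about it). Returns (angle_deg, rise, axis_dir, axis_point)
    where ``rise`` is the translation component along the axis and
    ``axis_point`` a point on the screw axis (least-squares for near-identity
    rotations, where the axis position is weakly conditioned).
    """
    R = np.asarray(R, float)
    t = np.asarray(t, float)
    ref = np.asarray(ref_axis, float)
    ref = ref / np.linalg.norm(ref)

    # axis direction from the skew-symmetric part; falls back to the
    # eigenvector for angles near 180 deg where the skew part vanishes
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
    sin_th = np.linalg.norm(w)
    cos_th = (np.trace(R) - 1.0) / 2.0
    cos_th = float(np.clip(cos_th, -1.0, 1.0))
    if sin_th > 1e-12:
        u = w / sin_th
    else:
        # identity or half-turn: take eigenvector of eigenvalue 1
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        u = vecs[:, np.argmax(vals)]
        u = u / np.linalg.norm(u)
    # orient along the reference axis so the sign of the angle is meaningful
    if np.dot(u, ref) < 0:
        u = -u
        sin_th = -sin_th
    angle = np.degrees(np.arctan2(sin_th, cos_th))

    rise = float(np.dot(t, u))
    # axis point: solve (I - R) p = t_perp in the plane normal to u
    t_perp = t - rise * u
    A = np.eye(3) - R
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - np.dot(p, u) * u  # report the point in the normal plane through origin
    return float(angle), rise, u, p


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit direction of largest variance of a point cloud."""
    X = np.asarray(points, float)
    if X.shape[0] < 2:
        raise GeometryError("need at least 2 points for a principal axis")
    X0 = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X0, full_matrices=False)
    v = Vt[0]
    return v / np.linalg.norm(v)


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of points a-b-c, degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
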