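"""Low-level rigid-body and internal-coordinate geometry helpers.

Everything here operates on plain ``(n, 3)`` numpy arrays in Å.  Rotations are
3x3 orthonormal matrices; a rigid transform is the pair ``(R, t)`` acting as
``x -> x @ R.T + t``.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

Array = np.ndarray


def unit(v: Array) -> Array:
    """Return v / |v|; raises on a zero vector."""
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return np.asarray(v, dtype=float) / n


def angle_between(u: Array, v: Array) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    c = float(np.dot(unit(u), unit(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def rotation_about_z(degrees: float) -> Array:
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_aligning(a: Array, b: Array) -> Array:
    """Rotation matrix sending direction ``a`` onto direction ``b``."""
    a = unit(a)
    b = unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = unit(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def apply_rigid(coords: Array, R: Array, t: Array) -> Array:
    return np.asarray(coords, dtype=float) @ np.asarray(R, dtype=float).T + np.asarray(t, dtype=float)


def kabsch(mobile: Array, reference: Array) -> tuple[Array, Array]:
    """Least-squares rigid transform (R, t) superposing ``mobile`` onto ``reference``.

    Returns (R, t) such that ``mobile @ R.T + t`` best fits ``reference``.
    Proper rotation enforced (no reflection).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def rmsd(a: Array, b: Array) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def nerf(a: Array, b: Array, c: Array, bond: float, angle_deg: float, dihedral_deg: float) -> Array:
    """Place atom D from three reference atoms by internal coordinates.

    ``bond`` = |C-D|, ``angle_deg`` = angle B-C-D, ``dihedral_deg`` = dihedral
    A-B-C-D.  This is the standard natural-extension reference frame
    construction used for building side chains from dihedral tables.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: Array, p1: Array, p2: Array, p3: Array) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


# ---------------------------------------------------------------------------
# Minimum enclosing ball (Welzl).  Used by the translation solver: for balls of
# equal radius r centered at points C, the intersection is nonempty iff the
# min enclosing ball of C has radius <= r, and the MEB center is a witness.
# ---------------------------------------------------------------------------


def _ball_from(points: list[Array]) -> tuple[Array, float]:
    k = len(points)
    if k == 0:
        return np.zeros(3), 0.0
    if k == 1:
        return points[0], 0.0
    if k == 2:
        c = (points[0] + points[1]) / 2.0
        return c, float(np.linalg.norm(points[0] - c))
    if k == 3:
        return _circumsphere3(points[0], points[1], points[2])
    return _circumsphere4(points[0], points[1], points[2], points[3])


def _circumsphere3(a: Array, b: Array, c: Array) -> tuple[Array, float]:
    # circumcenter of a triangle, lying in its plane
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    nn = float(np.dot(n, n))
    if nn < 1e-18:  # degenerate: fall back to farthest pair
        pts = [a, b, c]
        best = (np.zeros(3), -1.0)
        for i in range(3):
            for j in range(i + 1, 3):
                cen = (pts[i] + pts[j]) / 2.0
                r = float(np.linalg.norm(pts[i] - cen))
                if r > best[1]:
                    best = (cen, r)
        return best
    rel = (
        np.dot(ab, ab) * np.cross(ac, n) + np.dot(ac, ac) * np.cross(n, ab)
    ) / (2.0 * nn)
    center = a + rel
    return center, float(np.linalg.norm(center - a))


def _circumsphere4(a: Array, b: Array, c: Array, d: Array) -> tuple[Array, float]:
    A = 2.0 * np.array([b - a, c - a, d - a])
    if abs(np.linalg.det(A)) < 1e-12:
        # nearly coplanar; treat as 3-point case on the extreme triple
        cen, r = _circumsphere3(a, b, c)
        r = max(r, float(np.linalg.norm(d - cen)))
        return cen, r
    rhs = np.array(
        [
            np.dot(b, b) - np.dot(a, a),
            np.dot(c, c) - np.dot(a, a),
            np.dot(d, d) - np.dot(a, a),
        ]
    )
    center = np.linalg.solve(A, rhs)
    return center, float(np.linalg.norm(center - a))


def _welzl(points: list[Array], boundary: list[Array]) -> tuple[Array, float]:
    if not points or len(boundary) == 4:
        return _ball_from(boundary)
    p = points[-1]
    center, radius = _welzl(points[:-1], boundary)
    if np.linalg.norm(p - center) <= radius + 1e-9:
        return center, radius
    return _welzl(points[:-1], boundary + [p])


def min_enclosing_ball(points: Iterable[Sequence[float]]) -> tuple[Array, float]:
    """Exact minimum enclosing ball of a small 3D point set.

    Points are shuffled deterministically (fixed permutation) so the recursion
    depth stays shallow without introducing run-to-run nondeterminism.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    if not pts:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    pts = [pts[i] for i in order]
    return _welzl(pts, [])
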