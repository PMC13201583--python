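"""Rigid-body geometry primitives: centroids, superposition, RMSD, torsions.

All routines operate on plain ``(N, 3)`` float arrays of coordinates in
ångströms and are free of any file-format or biology dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "centroid",
    "superpose",
    "rmsd",
    "dihedral",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation``.

    The rotation is a 3x3 proper orthogonal matrix (det = +1); reflections
    are never produced by :func:`superpose`.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GeometryError("rotation matrix must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def centroid(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean of a non-empty point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise GeometryError("centroid of an empty point set is undefined")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite coordinates")
    return pts.mean(axis=0)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of two paired point sets (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("point sets must have identical shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(reference: np.ndarray, moving: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of ``moving`` onto ``reference``.

    Uses the closed-form Kabsch solution with a determinant guard so the
    returned rotation is always proper: a mirror-image point set keeps a
    non-zero residual rather than being reflected away.

    Returns the optimal :class:`RigidTransform` and the minimal RMSD in Å.

    Raises
    ------
    GeometryError
        If fewer than 3 points are given, the sets differ in size, or
        either set is degenerate (all points collinear).
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or mov.shape != ref.shape:
        raise GeometryError("expected two N x 3 arrays of equal shape")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 point pairs")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(mov))):
        raise GeometryError("non-finite coordinates")

    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    P = ref - cr
    Q = mov - cm

    for label, X in (("reference", P), ("moving", Q)):
        s = np.linalg.svd(X, compute_uv=False)
        # collinear: at most one significant singular value
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"{label} point set is collinear (rotation underdetermined)")

    H = Q.T @ P
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    xform = RigidTransform(R, t)
    return xform, rmsd(ref, xform.apply(mov))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, +180].

    Sign convention: if ``p4`` is generated by rotating ``p1`` about the
    ``p2 -> p3`` axis by +x degrees (right-hand rule), the torsion is +x.
    A planar cis arrangement gives 0 and trans gives 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise GeometryError("central bond p2-p3 has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), np.linalg.norm(b3), 1e-12) * nb2
    if np.linalg.norm(n1) < 1e-10 * scale or np.linalg.norm(n2) < 1e-10 * scale:
        raise GeometryError("collinear triple; torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into the interval (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a
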