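"""Rigid-body and surface-distance primitives.

Everything downstream — membrane placement, orientation search, template
ligand placement, domain-rotation quantification — reduces to the operations
here: least-squares superposition (Kabsch, with reflection guard), axis–angle
extraction, and signed distances to planes and cylinders.  All distances are
in Å; nm inputs are converted at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "RigidTransform",
    "PlaneModel",
    "CylinderModel",
    "superpose",
    "rotation_angle",
    "signed_plane_distance",
    "cylinder_surface_distance",
]


class GeometryError(ValueError):
    """Degenerate geometric input (too few points, collinear sets, ...)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation Å-preserving, det=+1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("improper rotation (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def about_axis(axis: np.ndarray, angle_deg: float, translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` (through the origin)."""
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        th = np.radians(angle_deg)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return RigidTransform(R, np.zeros(3) if translation is None else np.asarray(translation, float))


@dataclass(frozen=True)
class PlaneModel:
    """Oriented membrane reference plane ``{x : normal·x = offset}``.

    The normal points from the protein interior toward the membrane; positive
    signed distances are on the membrane side of the headgroup plane.
    ``headgroup_half_thickness`` (Å) describes the headgroup layer an
    amphipathic anchor sits in.
    """

    normal: np.ndarray
    offset: float
    headgroup_half_thickness: float = 3.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(n)
        if not np.isfinite(nrm) or nrm < 1e-12:
            raise GeometryError("plane normal must be non-zero")
        if self.headgroup_half_thickness < 0:
            raise GeometryError("headgroup half-thickness must be >= 0")
        object.__setattr__(self, "normal", n / nrm)
        object.__setattr__(self, "offset", float(self.offset))

    def transformed(self, t: RigidTransform) -> "PlaneModel":
        n = t.rotation @ self.normal
        return PlaneModel(n, self.offset + float(n @ t.translation), self.headgroup_half_thickness)


@dataclass(frozen=True)
class CylinderModel:
    """Infinite cylinder: point on axis, unit axis direction, radius in Å.

    Models the ciliary membrane as seen from inside the cilium (a 250 nm
    diameter tube is radius 1250 Å)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        p = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            raise GeometryError("cylinder axis direction must be non-zero")
        if self.radius <= 0:
            raise GeometryError("cylinder radius must be positive")
        object.__setattr__(self, "axis_point", p)
        object.__setattr__(self, "axis_direction", d / nrm)


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the proper rigid transform minimising the RMS deviation and the
    minimised RMSD (Å).  The SVD solution carries a reflection guard: the
    determinant of the rotation is forced to +1 so chirality is preserved.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centred set
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = P0 @ R.T - Q0
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return RigidTransform(R, t), rmsd


def rotation_angle(t: RigidTransform) -> float:
    """Axis–angle rotation magnitude of the rotation part, in degrees [0, 180]."""
    tr = float(np.trace(t.rotation))
    c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def rotation_axis(t: RigidTransform) -> np.ndarray:
    """Unit rotation axis (undefined direction for the identity; returns z)."""
    w, v = np.linalg.eig(t.rotation)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    nrm = np.linalg.norm(axis)
    return axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])


def signed_plane_distance(point: np.ndarray, plane: PlaneModel) -> float:
    """Signed distance from ``point`` to the plane; positive on the normal
    (membrane) side."""
    return float(np.dot(plane.normal, np.asarray(point, dtype=float)) - plane.offset)


def cylinder_surface_distance(point: np.ndarray, cyl: CylinderModel) -> float:
    """Radial distance from the cylinder wall; negative inside, positive beyond."""
    p = np.asarray(point, dtype=float) - cyl.axis_point
    radial = p - np.dot(p, cyl.axis_direction) * cyl.axis_direction
    return float(np.linalg.norm(radial) - cyl.radius)
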