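"""Rigid transforms: least-squares superposition and rotation algebra.

The workhorse is Kabsch superposition (SVD of the cross-covariance with the
determinant correction that excludes reflections), the angle extraction
``theta = arccos((tr R - 1)/2)``, and the screw (Chasles) decomposition of a
transform into a rotation about, plus a translation along, a unique axis.
All angles are degrees; all lengths are Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_ORTHO_TOL = 1e-9


class GeometryError(Exception):
    """Base class for superposition/decomposition failures."""


class InsufficientPairsError(GeometryError):
    pass


class DegenerateCloudError(GeometryError):
    pass


class InvalidTransformError(GeometryError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x -> R x + t."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def validate(self, tol: float = 1e-6) -> "RigidTransform":
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=tol) or not np.isclose(
                np.linalg.det(R), 1.0, atol=tol):
            raise InvalidTransformError("rotation matrix is not proper-orthonormal")
        return self

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RigidTransform":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit of a moving onto a fixed point set."""

    transform: RigidTransform
    rmsd: float
    n_pairs: int


@dataclass(frozen=True)
class ScrewDecomposition:
    """Chasles form of a rigid transform.

    ``axis_point`` is the point on the screw axis nearest the origin.  For a
    near-zero rotation angle the axis is undefined and ``axis_defined`` is
    False (the transform is then a pure translation).
    """

    axis_direction: np.ndarray
    axis_point: np.ndarray
    angle: float                    # degrees, [0, 180]
    translation_along_axis: float   # Å
    axis_defined: bool = True


def rotation_about_axis(angle_deg: float, axis: np.ndarray,
                        point: np.ndarray | None = None,
                        extra_translation: np.ndarray | None = None) -> RigidTransform:
    """Rotation by *angle_deg* about *axis* through *point*, plus optional translation.

    Convenience constructor used heavily by the synthetic generators to build
    ground-truth motions (Rodrigues' formula).
    """
    n = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("zero axis")
    n = n / norm
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    t = np.zeros(3)
    if point is not None:
        p = np.asarray(point, dtype=float)
        t = p - R @ p
    if extra_translation is not None:
        t = t + np.asarray(extra_translation, dtype=float)
    return RigidTransform(R, t)


def kabsch_superpose(fixed: np.ndarray, moving: np.ndarray) -> SuperpositionResult:
    """Least-squares proper-rotation superposition of *moving* onto *fixed*.

    Minimizes the RMSD over all rigid transforms; if the unconstrained
    optimum is a reflection, the singular direction with the smallest
    singular value is flipped (standard determinant correction), because
    physical motions are proper rotations.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise GeometryError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    n = fixed.shape[0]
    if n < 3:
        raise InsufficientPairsError(f"need >= 3 pairs, got {n}")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateCloudError("point cloud is collinear or degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(R, t)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(transform, rmsd, n)


def rotation_angle(t: RigidTransform) -> float:
    """Rotation angle of a transform in degrees, in [0, 180]."""
    t.validate()
    c = (np.trace(t.rotation) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_axis(t: RigidTransform) -> np.ndarray:
    """Unit rotation axis (sign follows the right-hand rule for the positive angle)."""
    R = t.rotation
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    n = v[:, np.argmax(w)]  # eigenvector for eigenvalue 1
    n = n / np.linalg.norm(n)
    # orient by the skew part: R - R^T = 2 sin(theta) [n]_x
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if skew @ n < 0:
        n = -n
    return n


def screw_decompose(t: RigidTransform) -> ScrewDecomposition:
    """Decompose a rigid transform into rotation about + translation along one axis.

    ``axis_point`` is chosen as the axis point nearest the origin, so the
    decomposition is unique for angle > 0.  Angles below ~1e-6 deg yield a
    pure-translation result with ``axis_defined=False``; the translation is
    then reported along its own direction.
    """
    angle = rotation_angle(t)
    if angle < 1e-6:
        tr = t.translation
        norm = np.linalg.norm(tr)
        direction = tr / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return ScrewDecomposition(direction, np.zeros(3), 0.0, float(norm), axis_defined=False)
    n = rotation_axis(t)
    d_along = float(t.translation @ n)
    t_perp = t.translation - d_along * n
    # axis point c solves (I - R) c = t_perp; restrict to the plane normal to n
    A = np.eye(3) - t.rotation
    c, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    c = c - (c @ n) * n  # nearest the origin
    return ScrewDecomposition(n, c, angle, d_along)


def recompose(s: ScrewDecomposition) -> RigidTransform:
    """Rebuild the rigid transform from its screw parameters."""
    if not s.axis_defined:
        return RigidTransform(np.eye(3), s.translation_along_axis * s.axis_direction)
    return rotation_about_axis(
        s.angle, s.axis_direction, point=s.axis_point,
        extra_translation=s.translation_along_axis * s.axis_direction)
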