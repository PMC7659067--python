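"""Planes, reflections, rigid transforms and the (weighted) orthogonal
Procrustes solver.

All coordinates are in millimetres.  A :class:`Plane` is stored in Hessian
normal form (``normal . x = offset``) with a canonical sign so that a plane
and its flipped representation compare equal.  Rigid transforms keep scale
fixed at 1; the improper (orientation-reversing) counterpart is used to
represent "mirror then rigidly move" maps, whose −1 eigendirection yields a
symmetry plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# Numerical tolerances (module constants, overridable by callers that need
# looser/tighter behaviour).
UNIT_NORM_TOL = 1e-12          # ‖normal‖ == 1 after construction
ORTHOGONALITY_TOL = 1e-10      # RᵀR == I for (im)proper transforms
CANONICAL_SIGN_EPS = 1e-9      # first normal component larger than this fixes the sign
DEGENERATE_NORMAL_EPS = 1e-9   # shorter normals are rejected
ROTARY_COMPONENT_TOL = 1e-3    # deviation from a pure reflection that triggers a warning


class DegenerateConfigurationError(ValueError):
    """Point configuration too degenerate (too few points / collinear)."""


class RotaryReflectionWarning(UserWarning):
    """The improper map has a significant rotary component; the extracted
    plane is the least-squares projection onto pure reflections."""


@dataclass(frozen=True, eq=False)
class Plane:
    """Oriented plane ``normal . x = offset`` (normal unit, offset in mm)."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.normal - self.offset

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_distance(points))

    def to_dict(self) -> dict:
        return {"normal": [float(c) for c in self.normal], "offset": float(self.offset)}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return make_plane(np.asarray(d["normal"], dtype=float), float(d["offset"]))


def make_plane(normal, offset: float) -> Plane:
    """Build a canonicalized plane from any (non-zero) normal and offset.

    The normal is normalized to unit length and its sign fixed so that the
    first component with magnitude above ``CANONICAL_SIGN_EPS`` is positive;
    the offset is rescaled/flipped accordingly.
    """
    n = np.asarray(normal, dtype=float).reshape(3)
    length = float(np.linalg.norm(n))
    if length <= DEGENERATE_NORMAL_EPS:
        raise ValueError(f"plane normal has near-zero length {length:g}")
    n = n / length
    d = float(offset) / length
    for component in n:
        if abs(component) > CANONICAL_SIGN_EPS:
            if component < 0:
                n, d = -n, -d
            break
    n.setflags(write=False)
    return Plane(normal=n, offset=d)


def reflect_points(points, plane: Plane) -> np.ndarray:
    """Reflect points across a plane: ``x - 2 (n.x - d) n``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts - 2.0 * plane.signed_distance(pts)[:, None] * plane.normal
    return out if np.asarray(points).ndim == 2 else out[0]


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Dihedral angle between two planes in degrees, in [0, 90].

    Orientation-independent: flipping either plane's normal leaves the
    result unchanged.
    """
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` with det(R) = +1, scale 1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(R.T @ R - np.eye(3)).max() > ORTHOGONALITY_TOL:
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > ORTHOGONALITY_TOL:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True, eq=False)
class ImproperTransform:
    """Orientation-reversing isometry ``x -> A x + t`` with det(A) = −1."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.linear, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(A.T @ A - np.eye(3)).max() > ORTHOGONALITY_TOL:
            raise ValueError("linear part is not orthogonal")
        if abs(np.linalg.det(A) + 1.0) > ORTHOGONALITY_TOL:
            raise ValueError("improper transform must have determinant −1")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "translation", t)

    @classmethod
    def reflection(cls, plane: Plane) -> "ImproperTransform":
        n = plane.normal
        return cls(np.eye(3) - 2.0 * np.outer(n, n), 2.0 * plane.offset * n)

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation


def compose_rigid_improper(rigid: RigidTransform, improper: ImproperTransform) -> ImproperTransform:
    """Return rigid ∘ improper (the improper map applied first)."""
    return ImproperTransform(
        rigid.rotation @ improper.linear,
        rigid.rotation @ improper.translation + rigid.translation,
    )


def validate_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float).reshape(-1)
    if w.shape[0] != n:
        raise ValueError(f"expected {n} weights, got {w.shape[0]}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and strictly positive")
    return w


def _weighted_cross_covariance(source, target, weights):
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("source and target must be matching N×3 arrays")
    n = X.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need at least 3 points, got {n}")
    w = np.full(n, 1.0 / n) if weights is None else validate_weights(weights, n)
    w = w / w.sum()
    xc = w @ X
    yc = w @ Y
    Xc = X - xc
    Yc = Y - yc
    # Collinear configurations leave the in-plane rotation undetermined.
    for pts, which in ((Xc, "source"), (Yc, "target")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateConfigurationError(f"{which} points are (near-)collinear")
    H = Xc.T @ (w[:, None] * Yc)   # maps source directions onto target directions
    return H, xc, yc


def _constrained_orthogonal(H: np.ndarray, det_sign: float) -> np.ndarray:
    """Orthogonal matrix of prescribed determinant maximizing tr(MᵀH).

    When the unconstrained optimum has the wrong determinant, the sign of
    the singular direction with the smallest singular value is flipped
    (minimal-perturbation correction; ties broken by lowest index).
    """
    U, s, Vt = np.linalg.svd(H)
    d = np.ones(3)
    if np.sign(np.linalg.det(Vt.T @ U.T)) != np.sign(det_sign):
        d[int(np.argmin(s))] = -1.0
    return Vt.T @ np.diag(d) @ U.T


def procrustes_rigid(source, target, weights=None) -> RigidTransform:
    """Weighted rigid Procrustes: the motion Q minimizing
    ``Σ w_i ‖target_i − Q(source_i)‖²`` (Kabsch solve, scale fixed at 1).

    ``weights=None`` gives the uniform (standard PA) solution.  Weights are
    per corresponding pair, positive; rescaling all weights by a constant
    leaves the result unchanged.
    """
    H, xc, yc = _weighted_cross_covariance(source, target, weights)
    R = _constrained_orthogonal(H, +1.0)
    return RigidTransform(R, yc - R @ xc)


def best_reflection(source, target, weights=None) -> ImproperTransform:
    """Best orientation-reversing isometry (det = −1) in the same weighted
    least-squares sense as :func:`procrustes_rigid`."""
    H, xc, yc = _weighted_cross_covariance(source, target, weights)
    A = _constrained_orthogonal(H, -1.0)
    return ImproperTransform(A, yc - A @ xc)


def transform_objective(transform, source, target, weights=None) -> float:
    """Σ w_i ‖target_i − T(source_i)‖² for a rigid or improper transform."""
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    w = np.ones(X.shape[0]) if weights is None else validate_weights(weights, X.shape[0])
    r = np.linalg.norm(Y - transform.apply(X), axis=1)
    return float(np.sum(w * r**2))


def plane_from_improper(transform: ImproperTransform) -> Plane:
    """Symmetry plane of an improper isometry.

    The linear part of any improper orthogonal map has an exact eigenvalue
    −1; its eigendirection is the mirror normal, computed here as the
    nullspace of ``A + I`` (smallest singular direction).  For a pure
    reflection ``x -> (I − 2nnᵀ)x + 2dn`` this returns exactly (n, d).  If
    the map also carries a rotary component about the mirror axis
    (``‖A − (I − 2nnᵀ)‖ > ROTARY_COMPONENT_TOL``, i.e. a rotary angle
    above about 0.06°), a :class:`RotaryReflectionWarning` is issued and
    the returned plane is the projection onto pure reflections.
    """
    A = transform.linear
    _, _, Vt = np.linalg.svd(A + np.eye(3))
    normal = Vt[-1]
    deviation = float(np.abs(A - (np.eye(3) - 2.0 * np.outer(normal, normal))).max())
    if deviation > ROTARY_COMPONENT_TOL:
        warnings.warn(
            f"improper map has rotary component (deviation {deviation:.3e} from a pure reflection)",
            RotaryReflectionWarning,
            stacklevel=2,
        )
    offset = float(normal @ transform.translation) / 2.0
    return make_plane(normal, offset)


def transform_plane(plane: Plane, rigid: RigidTransform) -> Plane:
    """Image of a plane under a rigid motion."""
    n = rigid.rotation @ plane.normal
    return make_plane(n, plane.offset + float(n @ rigid.translation))


def random_rigid_transform(rng: np.random.Generator,
                           max_rotation_deg: float = 180.0,
                           max_translation_mm: float = 50.0) -> RigidTransform:
    """Uniform-axis random rotation (angle ≤ max) plus a random translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)
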