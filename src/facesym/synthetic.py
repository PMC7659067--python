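"""Synthetic landmark-annotated faces with a known symmetry plane.

Emulates a mandibular-deviation cohort: a bilaterally symmetric template
head (landmarks plus a closed ellipsoidal head mesh with a nose) whose
lower third can be displaced laterally by a prescribed chin deviation,
with per-landmark Gaussian digitization noise and a small random rigid
pose on top.  The construction plane (the template's x = 0 sagittal
plane, carried along by the pose) is exact ground truth, so parameter
recovery of every pipeline stage can be tested without patient data.

Template coordinates are fixed constants (mm, natural-head-position
frame: x lateral with the anatomical left at x > 0, y vertical, z
anterior); randomness enters only through noise, pose and cohort
sampling seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import Plane, RigidTransform, random_rigid_transform, transform_plane
from .landmarks import LandmarkSet, Region, TriMesh, canonical_schema
from .symmetry import SAGITTAL_PLANE

# -- template landmark table (mm) -------------------------------------------
# Midline landmarks sit exactly on x = 0; bilateral pairs are mirror-exact
# (right at -x, left at +x).  Values are anthropometrically plausible for an
# adult face roughly 180 mm tall, centered near the head's centre of mass.
_MIDLINE_MM = {
    "trichion":         (0.0,  80.0, 60.0),
    "glabella":         (0.0,  45.0, 78.0),
    "nasion":           (0.0,  35.0, 72.0),
    "pronasale":        (0.0,   5.0, 95.0),
    "subnasale":        (0.0,  -5.0, 82.0),
    "labiale_superius": (0.0, -22.0, 80.0),
    "labiale_inferius": (0.0, -38.0, 78.0),
    "sublabiale":       (0.0, -48.0, 72.0),
    "pogonion":         (0.0, -62.0, 70.0),
    "gnathion":         (0.0, -72.0, 58.0),
}
# (|x|, y, z) for the left member; the right member mirrors x.
_BILATERAL_MM = {
    "superciliary_ridge": (22.0,  48.0, 70.0),
    "endocanthion":       (16.0,  30.0, 65.0),
    "exocanthion":        (44.0,  29.0, 52.0),
    "pupil":              (30.0,  30.0, 60.0),
    "alare":              (17.0,  -3.0, 70.0),
    "subalare":           (12.0,  -8.0, 72.0),
    "zygion":             (62.0,  15.0, 20.0),
    "tragion":            (68.0,   8.0, -10.0),
    "cheilion":           (26.0, -28.0, 65.0),
    "gonion":             (52.0, -50.0,  5.0),
    "crista_philtri":     ( 6.0, -18.0, 80.0),
}

# Head mesh: ellipsoid semi-axes (mm) and grid resolution.
_HEAD_SEMI_AXES = (70.0, 95.0, 85.0)   # lateral, vertical, anterior
_N_LAT, _N_LON = 41, 60                # (41-2)*60 + 2 = 2342 vertices

# Chin-centred Gaussian falloff (mm) blending the lateral deviation into
# the mesh so ICP sees a smooth, non-piecewise surface.
_CHIN_FALLOFF_SIGMA_MM = 40.0

#: Default landmark digitization noise (mm): the scanner's stated 0.1 mm
#: accuracy plus expert digitization variability.
DEFAULT_NOISE_SD_MM = 0.3

#: Default residual natural-head-position pose error.
DEFAULT_POSE_ROTATION_DEG = 5.0
DEFAULT_POSE_TRANSLATION_MM = 10.0


@dataclass(frozen=True, eq=False)
class SyntheticCase:
    mesh: TriMesh
    landmarks: LandmarkSet
    true_plane: Plane
    deviation_mm: float = 0.0
    deviation_side: Optional[str] = None
    noise_sd_mm: float = 0.0
    pose: RigidTransform = None  # type: ignore[assignment]
    seed: Optional[int] = None

    def __post_init__(self):
        if self.pose is None:
            object.__setattr__(self, "pose", RigidTransform.identity())


def _template_landmarks() -> LandmarkSet:
    table = dict(_MIDLINE_MM)
    for base, (x, y, z) in _BILATERAL_MM.items():
        table[f"{base}_left"] = (x, y, z)
        table[f"{base}_right"] = (-x, y, z)
    positions = [table[d.name] for d in canonical_schema()]
    return LandmarkSet(canonical_schema(), positions)


def _head_mesh() -> TriMesh:
    """Closed, face-like ellipsoid with a nose bump, mirror-symmetric in x.

    Built on a latitude/longitude grid whose longitudes come in ±φ pairs,
    so every vertex has an exact partner across the x = 0 plane.
    """
    a, c, b = _HEAD_SEMI_AXES
    lats = np.linspace(-np.pi / 2, np.pi / 2, _N_LAT)
    lons = -np.pi + 2 * np.pi * np.arange(_N_LON) / _N_LON  # even count → ±φ pairs

    verts = [np.array([0.0, -c, 0.0]), np.array([0.0, c, 0.0])]  # poles
    ring_start = {}
    for i, psi in enumerate(lats[1:-1], start=1):
        ring_start[i] = len(verts)
        for phi in lons:
            x = a * np.cos(psi) * np.sin(phi)
            y = c * np.sin(psi)
            z = b * np.cos(psi) * np.cos(phi)
            # Nose: forward bump centred on the midline, slightly below
            # eye level; even in phi so symmetry is exact.
            bump = 16.0 * np.exp(-((phi / 0.30) ** 2 + ((psi - 0.05) / 0.22) ** 2))
            z += bump if z > 0 else 0.0
            verts.append(np.array([x, y, z]))
    verts = np.asarray(verts)

    faces = []
    n = _N_LON
    # pole fans
    for k in range(n):
        faces.append([0, ring_start[1] + (k + 1) % n, ring_start[1] + k])
        top = ring_start[_N_LAT - 2]
        faces.append([1, top + k, top + (k + 1) % n])
    # quad strips
    for i in range(1, _N_LAT - 2):
        r0, r1 = ring_start[i], ring_start[i + 1]
        for k in range(n):
            k2 = (k + 1) % n
            faces.append([r0 + k, r0 + k2, r1 + k])
            faces.append([r0 + k2, r1 + k2, r1 + k])
    mesh = TriMesh(verts, np.asarray(faces))
    # Centre of gravity at the origin (x is already symmetric, so the
    # ground-truth plane stays x = 0 exactly).
    shift = mesh.centroid()
    assert abs(shift[0]) < 1e-9
    return mesh.with_vertices(mesh.vertices - shift)


def make_template(seed: Optional[int] = None) -> SyntheticCase:
    """The symmetric, noise-free, unposed template case.

    The template is deterministic; ``seed`` is only recorded so that the
    downstream noise/pose stages of a case share a provenance seed.
    """
    return SyntheticCase(
        mesh=_head_mesh(),
        landmarks=_template_landmarks(),
        true_plane=SAGITTAL_PLANE,
        seed=seed,
    )


def apply_deviation(case: SyntheticCase, deviation_mm: float, side: str = "left",
                    mode: str = "translate") -> SyntheticCase:
    """Displace the lower facial third laterally by a chin deviation.

    ``translate`` shifts every lower-third landmark by ``deviation_mm``
    toward ``side``; ``rotate`` swings the lower face about an
    anterior-posterior axis through the subnasale so that the pogonion's
    lateral offset equals ``deviation_mm``.  The mesh is deformed with a
    smooth chin-centred Gaussian falloff; upper/middle landmarks and the
    ground-truth plane are untouched.
    """
    if deviation_mm < 0:
        raise ValueError("deviation must be non-negative")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if case.deviation_mm != 0:
        raise ValueError("deviation must be applied to an undeviated template case")
    if deviation_mm == 0:
        return replace(case, deviation_side=side)

    direction = 1.0 if side == "left" else -1.0   # left is +x in the template
    lm = case.landmarks
    lower_idx = [i for i, d in enumerate(lm.definitions) if d.region == Region.LOWER]
    chin = lm.position_of("pogonion")
    w_mesh = np.exp(-np.sum((case.mesh.vertices - chin) ** 2, axis=1)
                    / (2 * _CHIN_FALLOFF_SIGMA_MM ** 2))

    positions = lm.positions.copy()
    vertices = case.mesh.vertices.copy()
    if mode == "translate":
        positions[lower_idx, 0] += direction * deviation_mm
        vertices[:, 0] += direction * deviation_mm * w_mesh
    elif mode == "rotate":
        pivot = lm.position_of("subnasale")
        lever = abs(chin[1] - pivot[1])
        theta = direction * np.arcsin(min(deviation_mm / lever, 1.0))

        def rot_xy(pts, angles):
            rel = pts - pivot
            cos, sin = np.cos(angles), np.sin(angles)
            out = pts.copy()
            out[:, 0] = pivot[0] + cos * rel[:, 0] - sin * rel[:, 1]
            out[:, 1] = pivot[1] + sin * rel[:, 0] + cos * rel[:, 1]
            return out

        # pogonion sits below the pivot (rel y = -lever), so rotating by
        # +theta moves the chin by lever*sin(theta) toward +x (the left)
        positions[lower_idx] = rot_xy(positions[lower_idx], np.full(len(lower_idx), theta))
        vertices = rot_xy(vertices, theta * w_mesh)
    else:
        raise ValueError("mode must be 'translate' or 'rotate'")

    return replace(
        case,
        mesh=case.mesh.with_vertices(vertices),
        landmarks=lm.with_positions(positions),
        deviation_mm=float(deviation_mm),
        deviation_side=side,
    )


def add_noise(case: SyntheticCase, noise_sd_mm: float, seed: int,
              mesh_noise_sd_mm: float = 0.0) -> SyntheticCase:
    """Add isotropic Gaussian digitization noise to every landmark
    (and optionally to mesh vertices); reproducible under ``seed``."""
    if noise_sd_mm < 0 or mesh_noise_sd_mm < 0:
        raise ValueError("noise sd must be non-negative")
    if noise_sd_mm == 0 and mesh_noise_sd_mm == 0:
        return case
    rng = np.random.default_rng(seed)
    lm = case.landmarks.with_positions(
        case.landmarks.positions + rng.normal(0.0, 1.0, (len(case.landmarks), 3)) * noise_sd_mm
    )
    mesh = case.mesh
    if mesh_noise_sd_mm > 0:
        mesh = mesh.with_vertices(
            mesh.vertices + rng.normal(0.0, mesh_noise_sd_mm, mesh.vertices.shape))
    return replace(case, mesh=mesh, landmarks=lm, noise_sd_mm=float(noise_sd_mm))


def apply_pose(case: SyntheticCase, transform: Optional[RigidTransform] = None,
               seed: Optional[int] = None,
               max_rotation_deg: float = DEFAULT_POSE_ROTATION_DEG,
               max_translation_mm: float = DEFAULT_POSE_TRANSLATION_MM) -> SyntheticCase:
    """Rigidly move the whole case (mesh, landmarks AND ground-truth plane).

    Pass an explicit transform, or a seed to sample a small residual
    head-positioning error (rotation ≤ ``max_rotation_deg``, translation
    ≤ ``max_translation_mm`` per axis).
    """
    if transform is None:
        if seed is None:
            raise ValueError("provide a transform or a seed")
        transform = random_rigid_transform(np.random.default_rng(seed),
                                           max_rotation_deg, max_translation_mm)
    return replace(
        case,
        mesh=case.mesh.with_vertices(transform.apply(case.mesh.vertices)),
        landmarks=case.landmarks.with_positions(transform.apply(case.landmarks.positions)),
        true_plane=transform_plane(case.true_plane, transform),
        pose=transform.compose(case.pose),
    )


def make_cohort(n: int, deviation_range_mm: tuple[float, float] = (5.0, 23.0),
                noise_sd_mm: float = DEFAULT_NOISE_SD_MM, seed: int = 0,
                mode: str = "translate", pose: bool = True) -> list[SyntheticCase]:
    """A reproducible cohort of deviated, noisy, posed synthetic cases.

    Deviations are evenly spaced across ``deviation_range_mm`` (the range
    of chin deviations the clinical cohort spans); sides alternate and
    noise/pose seeds derive from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = deviation_range_mm
    if hi < lo:
        raise ValueError("empty deviation range")
    deviations = np.linspace(lo, hi, n) if n > 1 else np.array([lo])
    rng = np.random.default_rng(seed)
    cases = []
    for i, dev in enumerate(deviations):
        side = "left" if i % 2 == 0 else "right"
        case = make_template(seed=seed)
        case = apply_deviation(case, float(dev), side, mode)
        case = add_noise(case, noise_sd_mm, seed=int(rng.integers(0, 2**31 - 1)))
        if pose:
            case = apply_pose(case, seed=int(rng.integers(0, 2**31 - 1)))
        cases.append(case)
    return cases
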