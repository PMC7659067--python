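"""Point-to-point iterative closest point (ICP) registration.

Used twice in the symmetry-plane workflow: a *global* pass that rigidly
re-aligns the mirrored face to the original (mirror floated, original
fixed), and a *regional* pass restricted to a vertex subset with good
left-right symmetry, which serves as the professional-standard reference.

Correspondence is nearest-neighbour over the fixed model's vertices via a
k-d tree; each iteration solves a uniform-weight rigid Procrustes update.
The recorded per-iteration RMS residuals are non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, procrustes_rigid
from .landmarks import TriMesh, LandmarkSet, Region

_RMS_FLOOR = 1e-12  # an RMS below this counts as exact overlap


@dataclass
class ICPParams:
    max_iterations: int = 100
    relative_tolerance: float = 1e-6
    source_mask: Optional[np.ndarray] = None  # indices or boolean over floating vertices

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.relative_tolerance <= 0:
            raise ValueError("relative_tolerance must be > 0")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_history: list[float]
    converged: bool
    iterations_run: int


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, TriMesh):
        return obj.vertices
    if isinstance(obj, LandmarkSet):
        return obj.positions
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an N×3 point array, TriMesh or LandmarkSet")
    return pts


def _resolve_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.arange(n)
    m = np.asarray(mask)
    idx = np.flatnonzero(m) if m.dtype == bool else m.astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("mask index out of range")
    return idx


def icp_align(floating, fixed, params: Optional[ICPParams] = None) -> ICPResult:
    """Rigidly align ``floating`` onto ``fixed`` (fixed stays put).

    Returns the cumulative :class:`RigidTransform` mapping the *original*
    floating coordinates into the fixed frame.  The floating point set may
    be restricted with ``params.source_mask``; the transform still applies
    to the whole floating model.  Centroids of the (masked) floating set
    and the fixed set are pre-aligned before iterating.
    """
    params = params or ICPParams()
    float_pts = _as_points(floating)
    fixed_pts = _as_points(fixed)
    if fixed_pts.shape[0] == 0:
        raise ValueError("fixed point set is empty")
    idx = _resolve_mask(params.source_mask, float_pts.shape[0])
    if idx.size < 3:
        raise ValueError(f"mask selects {idx.size} floating points; need at least 3")

    tree = cKDTree(fixed_pts)
    current = float_pts[idx]
    t0 = fixed_pts.mean(axis=0) - current.mean(axis=0)
    cumulative = RigidTransform(np.eye(3), t0)
    current = current + t0

    rms_history: list[float] = []
    converged = False
    for _ in range(params.max_iterations):
        _, nn = tree.query(current)
        matched = fixed_pts[nn]
        step = procrustes_rigid(current, matched)
        current = step.apply(current)
        cumulative = step.compose(cumulative)
        # RMS after the update, against the same correspondences: this makes
        # the history provably non-increasing across iterations.
        rms = float(np.sqrt(np.mean(np.sum((matched - current) ** 2, axis=1))))
        prev = rms_history[-1] if rms_history else None
        rms_history.append(rms)
        if rms < _RMS_FLOOR:
            converged = True
            break
        if prev is not None and abs(prev - rms) < params.relative_tolerance * max(prev, _RMS_FLOOR):
            converged = True
            break
    return ICPResult(cumulative, rms_history, converged, len(rms_history))


def regional_icp_align(floating, fixed, region_mask, params: Optional[ICPParams] = None) -> ICPResult:
    """ICP with correspondences restricted to a floating-vertex subset.

    The returned transform nevertheless applies to the whole floating
    model.  With ``region_mask`` covering all vertices this reduces exactly
    to :func:`icp_align`.
    """
    params = params or ICPParams()
    n = _as_points(floating).shape[0]
    idx = _resolve_mask(region_mask, n)
    if idx.size < 3:
        raise ValueError(f"region mask selects {idx.size} vertices; need at least 3")
    local = ICPParams(params.max_iterations, params.relative_tolerance, source_mask=idx)
    return icp_align(floating, fixed, local)


def symmetric_region_mask(mesh: TriMesh, landmarks: LandmarkSet,
                          include=(Region.UPPER, Region.MIDDLE)) -> np.ndarray:
    """Programmatic stand-in for an expert-selected symmetric face region.

    Marks each vertex whose nearest landmark among the included facial
    thirds is closer than its nearest landmark among the excluded thirds
    (default: keep upper+middle, drop the mandibular lower third).
    """
    landmarks.require_canonical()
    include = {Region(r) for r in include}
    inc_pts = np.vstack([landmarks.partition(r).positions for r in sorted(include, key=lambda r: r.value)])
    exc_regions = [r for r in Region if r not in include]
    if not exc_regions:
        return np.ones(len(mesh.vertices), dtype=bool)
    exc_pts = np.vstack([landmarks.partition(r).positions for r in exc_regions])
    d_inc, _ = cKDTree(inc_pts).query(mesh.vertices)
    d_exc, _ = cKDTree(exc_pts).query(mesh.vertices)
    return d_inc < d_exc
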