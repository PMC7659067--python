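"""Symmetry reference plane (SRP) extraction by original-mirror alignment.

The face model is reflected across the nominal sagittal (YZ) plane, the
reflected copy is rigidly re-aligned to the original, and the SRP is the
plane of the best pure reflection mapping the original onto the aligned
mirror.  Three alignment strategies are provided:

* ``pa``   — uniform-weight rigid Procrustes on the 32 landmark pairs,
* ``wpa``  — weighted Procrustes; each pair is weighted by the reciprocal
  of its distance after the initial global ICP, so symmetric landmarks
  dominate and strongly asymmetric ones (e.g. a deviated chin) are
  down-weighted,
* ``reference`` — region-restricted ICP on a symmetric face region, the
  professional-standard ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    ImproperTransform,
    Plane,
    RigidTransform,
    best_reflection,
    compose_rigid_improper,
    make_plane,
    plane_from_improper,
    procrustes_rigid,
    reflect_points,
    transform_objective,
)
from .landmarks import LandmarkSet, TriMesh
from .registration import ICPParams, icp_align, regional_icp_align

#: Reciprocal-distance weights are clamped at 1/EPS_CLAMP_MM so that an
#: exactly coincident landmark pair keeps the weight finite.
EPS_CLAMP_MM = 1e-6

#: The mirroring plane: the nominal sagittal plane of the centered
#: natural-head-position frame (x = 0).
SAGITTAL_PLANE = make_plane((1.0, 0.0, 0.0), 0.0)


class WeightClampWarning(UserWarning):
    pass


@dataclass
class SRPParams:
    """Tunable parameters of the SRP extraction pipeline."""

    icp: ICPParams = field(default_factory=ICPParams)
    region_mask: Optional[np.ndarray] = None      # floating-vertex subset (reference method)
    eps_clamp_mm: float = EPS_CLAMP_MM
    reweight_iterations: int = 0                  # optional iterative reweighting, off by default


@dataclass
class SRPResult:
    plane: Plane
    method: str
    mirror_transform: ImproperTransform
    weights: Optional[np.ndarray]
    diagnostics: dict


def mirror_model(model: Optional[TriMesh], landmarks: LandmarkSet
                 ) -> tuple[Optional[TriMesh], LandmarkSet]:
    """Reflect a model and its landmarks across the YZ plane.

    Triangle winding is flipped so surface orientation is preserved, and
    left/right landmark names are swapped: the mirrored left cheilion lies
    where a right cheilion should, so after the swap same-named landmarks
    in the original and mirror sets are anatomical correspondents, which is
    what makes the pair distance a per-landmark asymmetry measure.
    """
    mirrored_mesh = None
    if model is not None:
        v = reflect_points(model.vertices, SAGITTAL_PLANE)
        f = model.faces[:, [0, 2, 1]] if model.faces.size else model.faces
        mirrored_mesh = TriMesh(v, f)

    reflected = reflect_points(landmarks.positions, SAGITTAL_PLANE)
    new_positions = {}
    for definition, pos in zip(landmarks.definitions, reflected):
        target = definition.pair_name if definition.pair_name else definition.name
        new_positions[target] = pos
    order = [new_positions[d.name] for d in landmarks.definitions]
    return mirrored_mesh, landmarks.with_positions(np.asarray(order))


def compute_weights(org: LandmarkSet, mir_aligned: LandmarkSet,
                    eps_clamp_mm: float = EPS_CLAMP_MM) -> np.ndarray:
    """Reciprocal-distance weights w_i = 1 / max(d_i, eps) in mm⁻¹.

    ``d_i`` is the distance between same-named landmarks of the original
    set and the mirror set after initial global alignment; near-symmetric
    pairs therefore receive large weights.
    """
    if org.names != mir_aligned.names:
        raise ValueError("landmark sets must share names and order")
    d = np.linalg.norm(org.positions - mir_aligned.positions, axis=1)
    clamped = np.maximum(d, eps_clamp_mm)
    if np.any(d < eps_clamp_mm):
        warnings.warn(
            f"{int(np.sum(d < eps_clamp_mm))} landmark pair(s) closer than "
            f"{eps_clamp_mm} mm; weights clamped",
            WeightClampWarning,
            stacklevel=2,
        )
    return 1.0 / clamped


def fit_union_plane(org_points, mir_points, weights=None) -> Plane:
    """Least-squares symmetry plane of corresponding point pairs.

    Fits the orientation-reversing isometry that best maps ``org_points``
    onto ``mir_points`` and extracts its mirror plane.  When the mirror
    points are an exact reflection of the originals the construction plane
    is recovered exactly; any rotary component triggers a diagnostic
    warning inside :func:`plane_from_improper`.
    """
    improper = best_reflection(org_points, mir_points, weights)
    return plane_from_improper(improper)


def mirror_landmarks_across(landmarks: LandmarkSet, plane: Plane) -> LandmarkSet:
    """Reflect every landmark across a plane, names unchanged.

    No left/right swap here: downstream position-error metrics compare
    same-named points mirrored by different candidate planes.
    """
    return landmarks.with_positions(reflect_points(landmarks.positions, plane))


METHODS = ("pa", "wpa", "reference")


def extract_srp(model: Optional[TriMesh], landmarks: LandmarkSet, method: str,
                params: Optional[SRPParams] = None) -> SRPResult:
    """Run one full SRP extraction pipeline.

    Steps: mirror across the YZ plane → global ICP (mirror floated,
    original fixed) → method-specific refinement (landmark Procrustes for
    pa/wpa, regional ICP for reference) → least-squares reflection plane
    over the union of the original and the fully transformed mirror model.

    ``model`` may be None, in which case the landmark positions serve as
    the point set for ICP and plane extraction.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    params = params or SRPParams()
    landmarks.require_canonical()

    mir_mesh, mir_lmk = mirror_model(model, landmarks)
    org_points = model.vertices if model is not None else landmarks.positions
    mir_points = mir_mesh.vertices if mir_mesh is not None else mir_lmk.positions

    icp_res = icp_align(mir_points, org_points, params.icp)
    mir_points_icp = icp_res.transform.apply(mir_points)
    mir_lmk_icp = mir_lmk.with_positions(icp_res.transform.apply(mir_lmk.positions))

    diagnostics: dict = {
        "icp_rms_history": list(icp_res.rms_history),
        "icp_converged": icp_res.converged,
    }

    weights = None
    if method == "pa":
        refine = procrustes_rigid(mir_lmk_icp.positions, landmarks.positions)
    elif method == "wpa":
        weights = compute_weights(landmarks, mir_lmk_icp, params.eps_clamp_mm)
        refine = procrustes_rigid(mir_lmk_icp.positions, landmarks.positions, weights)
        for _ in range(params.reweight_iterations):
            moved = mir_lmk_icp.with_positions(refine.apply(mir_lmk_icp.positions))
            weights = compute_weights(landmarks, moved, params.eps_clamp_mm)
            refine = procrustes_rigid(mir_lmk_icp.positions, landmarks.positions, weights)
        diagnostics["weight_summary"] = {
            "min": float(weights.min()), "max": float(weights.max()),
            "mean": float(weights.mean()),
        }
    else:  # reference
        if params.region_mask is None:
            raise ValueError("method='reference' requires params.region_mask")
        reg = regional_icp_align(mir_points_icp, org_points, params.region_mask, params.icp)
        refine = reg.transform
        diagnostics["regional_icp_rms_history"] = list(reg.rms_history)

    cumulative_rigid = refine.compose(icp_res.transform)
    mirror_transform = compose_rigid_improper(
        cumulative_rigid, ImproperTransform.reflection(SAGITTAL_PLANE)
    )
    final_mir_points = refine.apply(mir_points_icp)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        plane = fit_union_plane(org_points, final_mir_points)
    diagnostics["warnings"] = [str(w.message) for w in caught]
    diagnostics["reflection_residual_rms_mm"] = float(np.sqrt(
        transform_objective(ImproperTransform.reflection(plane), org_points,
                            final_mir_points) / len(org_points)))
    return SRPResult(plane, method, mirror_transform, weights, diagnostics)
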