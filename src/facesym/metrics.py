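"""Evaluation metrics for candidate symmetry reference planes.

Three quantities compare a test SRP with the reference (ground-truth) SRP:

* **angle error** — dihedral angle between the two planes (degrees);
* **mirrored-landmark position error** — the original landmarks are
  reflected across the test plane and across the reference plane, and the
  mean distance between same-named images is reported, globally over all
  32 landmarks and per facial third (4/17/11);
* **facial asymmetry index (FAI)** — for a given plane, the sum of the 10
  midline landmarks' distances to the plane plus the 11 bilateral pairs'
  absolute right-minus-left distance differences; the FAI *error* is the
  test-plane FAI minus the reference-plane FAI (signed and absolute).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .geometry import Plane, angle_between_planes
from .landmarks import LandmarkSet, Region
from .symmetry import SRPResult, mirror_landmarks_across

REGIONS = ("upper", "middle", "lower")


def _plane_of(obj: Union[Plane, SRPResult]) -> Plane:
    return obj.plane if isinstance(obj, SRPResult) else obj


def angle_error(test: Union[Plane, SRPResult], ref: Union[Plane, SRPResult]) -> float:
    """Angle between a test SRP and the reference SRP, degrees in [0, 90]."""
    return angle_between_planes(_plane_of(test), _plane_of(ref))


def position_error(landmarks: LandmarkSet, test_plane: Union[Plane, SRPResult],
                   ref_plane: Union[Plane, SRPResult], region: str = "all") -> float:
    """Mean distance between landmarks mirrored by the test vs reference plane.

    The *same* original landmark set is reflected across both planes; the
    error is the mean Euclidean distance between same-named images over
    the whole face (``region='all'``, 32 landmarks) or one facial third.
    """
    landmarks.require_canonical()
    test_img = mirror_landmarks_across(landmarks, _plane_of(test_plane))
    ref_img = mirror_landmarks_across(landmarks, _plane_of(ref_plane))
    d = np.linalg.norm(test_img.positions - ref_img.positions, axis=1)
    if region == "all":
        return float(d.mean())
    keep = [i for i, dfn in enumerate(landmarks.definitions)
            if dfn.region == Region(region)]
    return float(d[keep].mean())


def fai(landmarks: LandmarkSet, plane: Union[Plane, SRPResult]) -> float:
    """Facial asymmetry index (mm) of a landmark set w.r.t. a plane.

    ``Σ_midline d_i + Σ_pairs |d_right − d_left|`` with unsigned
    point-to-plane distances; zero iff every midline landmark lies on the
    plane and every bilateral pair is equidistant from it.
    """
    landmarks.require_canonical()
    p = _plane_of(plane)
    total = float(p.distance(landmarks.midline().positions).sum())
    for right, left in landmarks.bilateral_pairs():
        rd = float(p.distance(landmarks.position_of(right)[None, :])[0])
        ld = float(p.distance(landmarks.position_of(left)[None, :])[0])
        total += abs(rd - ld)
    return total


def fai_error(test_fai: float, ref_fai: float) -> tuple[float, float]:
    """(signed, absolute) difference between a test FAI and the reference FAI."""
    signed = float(test_fai - ref_fai)
    return signed, abs(signed)


@dataclass
class EvaluationReport:
    """All per-case evaluation quantities for the PA and WPA pipelines."""

    case_id: Optional[str]
    angle_error_deg: dict          # method -> degrees
    position_error_mm: dict        # method -> {"global"/"upper"/"middle"/"lower": mm}
    fai_mm: dict                   # method (incl. "reference") -> mm
    fai_error_mm: dict             # method -> {"signed": mm, "absolute": mm}

    def __post_init__(self):
        for m, e in self.fai_error_mm.items():
            if abs(e["absolute"] - abs(e["signed"])) > 1e-12:
                raise ValueError(f"inconsistent FAI error for {m}")

    def to_row(self) -> dict:
        """Flat per-case row (one column per metric) for cohort tables."""
        row: dict = {"subject": self.case_id}
        for m in ("wpa", "pa"):
            row[f"err_lmk_{m}"] = self.position_error_mm[m]["global"]
            for region in REGIONS:
                row[f"err_lmk_{m}_{region[:3]}"] = self.position_error_mm[m][region]
            row[f"err_ang_{m}"] = self.angle_error_deg[m]
            row[f"fai_{m}"] = self.fai_mm[m]
            row[f"err_fai_{m}_signed"] = self.fai_error_mm[m]["signed"]
            row[f"err_fai_{m}_abs"] = self.fai_error_mm[m]["absolute"]
        row["fai_ref"] = self.fai_mm["reference"]
        return row


def evaluate_case(model, landmarks: LandmarkSet, srp_pa: SRPResult,
                  srp_wpa: SRPResult, srp_ref: SRPResult,
                  case_id: Optional[str] = None) -> EvaluationReport:
    """Assemble the full evaluation report for one case.

    All three SRPs must come from the same case (same original model and
    landmark set, which stays fixed across the test and reference groups).
    """
    landmarks.require_canonical()
    angle = {m: angle_error(srp, srp_ref) for m, srp in (("pa", srp_pa), ("wpa", srp_wpa))}
    position = {
        m: {
            "global": position_error(landmarks, srp, srp_ref, "all"),
            **{r: position_error(landmarks, srp, srp_ref, r) for r in REGIONS},
        }
        for m, srp in (("pa", srp_pa), ("wpa", srp_wpa))
    }
    fai_vals = {
        "pa": fai(landmarks, srp_pa),
        "wpa": fai(landmarks, srp_wpa),
        "reference": fai(landmarks, srp_ref),
    }
    fai_err = {}
    for m in ("pa", "wpa"):
        signed, absolute = fai_error(fai_vals[m], fai_vals["reference"])
        fai_err[m] = {"signed": signed, "absolute": absolute}
    return EvaluationReport(case_id, angle, position, fai_vals, fai_err)
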