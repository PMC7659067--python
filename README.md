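# facesym

Extraction and evaluation of the **symmetry reference plane (SRP)** of a 3D
facial surface scan — the estimated midsagittal plane against which left–right
facial symmetry is diagnosed and treatment is planned in orthodontics,
prosthodontics and maxillofacial surgery. The package targets the hard case:
patients with **mandibular deviation**, where a laterally displaced chin drags
naive symmetry estimates toward the asymmetry (the "Pinocchio effect").

## Method

All estimators follow the *original–mirror alignment* scheme: reflect the face
model across the nominal sagittal (YZ) plane, rigidly re-align the mirror copy
to the original, and read the SRP off the best pure reflection mapping one onto
the other.

Given the 32 anatomical landmarks of the original model, `LMK_Org`, and of the
mirror model after initial global ICP alignment, `LMK_Mir`, the standard
**Procrustes analysis (PA)** superimposition solves

    min_Q  Σᵢ ‖LMK_Orgᵢ − Q · LMK_Mirᵢ‖²

over rigid motions Q (scale fixed at 1). **Weighted Procrustes analysis
(WPA)** — the core of this package — first scores each landmark pair by its
residual distance after the initial alignment,

    wᵢ = 1 / ‖LMK_Orgᵢ − LMK_Mirᵢ‖ ,

and solves the weighted problem

    min_Q  Σᵢ wᵢ ‖LMK_Orgᵢ − Q · LMK_Mirᵢ‖² .

Landmark pairs that are nearly symmetric (small distance, large weight) steer
the superimposition; strongly asymmetric pairs — the deviated lower third —
are automatically down-weighted, mimicking how a clinician discounts the
deformed region. Both solves are closed-form weighted Kabsch (SVD) solutions.
A **regional ICP** estimator (correspondences restricted to a symmetric
upper+middle face region) provides the professional-standard reference plane.

Evaluation metrics: plane **angle error** (degrees), **mirrored-landmark
position error** (mean distance between the original landmarks reflected
across the test vs the reference plane; global and per facial third), and the
**facial asymmetry index** `FAI = Σ₁⁰ Mdᵢ + Σ₁¹¹ |Rdᵢ − Ldᵢ|` over 10 midline
landmarks and 11 bilateral pairs, with its signed/absolute error.

Because no public scan corpus exists, the package ships a first-class
synthetic-face generator: a symmetric landmark-annotated head with exact
ground-truth plane, parametric chin deviation (3–23 mm), Gaussian digitization
noise and random head pose.

## Worked example

Run the full synthetic experiment — 15 cases, chin deviations evenly spaced
over 5–23 mm, 0.3 mm landmark noise, random pose — and compare the three SRP
estimators:

```
$ facesym experiment --seed 1
err_ang_wpa: 1.37 ± 1.23
err_ang_pa: 4.74 ± 1.90
err_lmk_wpa: 2.26 ± 1.64
err_lmk_pa: 10.02 ± 4.29
err_fai_wpa_abs: 12.27 ± 15.35
err_fai_pa_abs: 21.68 ± 13.70
```

Reading: the WPA plane deviates from the regional-ICP reference by 1.37° on
average versus 4.74° for unweighted PA; its mirrored-landmark position error
(2.26 mm vs 10.02 mm) and absolute FAI error (12.3 mm vs 21.7 mm) are likewise
smaller — the reciprocal-distance weighting keeps the estimate anchored to the
symmetric upper face instead of being dragged by the deviated chin.

The same pipeline is scriptable:

```python
import facesym as fs

case = fs.apply_deviation(fs.make_template(), 10.0, side="left")
srp = fs.extract_srp(case.mesh, case.landmarks, "wpa")
print(fs.angle_between_planes(srp.plane, case.true_plane))  # 0.709°
```

Individual steps are exposed on the CLI as `facesym simulate` (write a cohort
as OBJ + landmark CSV + true-plane JSON), `facesym srp` (one plane from one
scan) and `facesym evaluate` (metrics from saved planes).

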