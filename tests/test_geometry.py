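"""Planes, reflections and the (weighted) rigid/improper Procrustes solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from facesym.geometry import (
    DegenerateConfigurationError,
    ImproperTransform,
    RigidTransform,
    RotaryReflectionWarning,
    angle_between_planes,
    best_reflection,
    make_plane,
    plane_from_improper,
    procrustes_rigid,
    random_rigid_transform,
    reflect_points,
    transform_objective,
)

finite_coords = st.floats(-100, 100, allow_nan=False)
point_sets = arrays(float, st.tuples(st.integers(4, 12), st.just(3)),
                    elements=finite_coords)


def random_points(rng, n=8, scale=50.0):
    return rng.normal(0.0, scale, (n, 3))


class TestMakePlane:
    @pytest.mark.parametrize("normal,offset,exp_n,exp_d", [
        ((2, 0, 0), 4, (1, 0, 0), 2.0),            # normalization
        ((-1, 0, 0), 3, (1, 0, 0), -3.0),          # sign canonicalization
        ((0, -3, 0), 6, (0, 1, 0), -2.0),          # first significant component
    ])
    def test_canonicalization(self, normal, offset, exp_n, exp_d):
        p = make_plane(normal, offset)
        assert np.allclose(p.normal, exp_n, atol=1e-12)
        assert p.offset == pytest.approx(exp_d, abs=1e-12)
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ValueError):
            make_plane((0, 0, 1e-12), 0.0)

    def test_flip_equivalence(self, rng):
        n = rng.normal(size=3)
        d = rng.normal()
        a, b = make_plane(n, d), make_plane(-n, -d)
        assert np.allclose(a.normal, b.normal) and a.offset == pytest.approx(b.offset)


class TestReflection:
    def test_coordinate_flip(self):
        p = make_plane((1, 0, 0), 0)
        assert np.allclose(reflect_points(np.array([1.0, 2.0, 3.0]), p), [-1, 2, 3])

    def test_fixed_point_on_plane(self):
        p = make_plane((0, 1, 0), 5)
        pt = np.array([3.0, 5.0, -2.0])
        assert np.allclose(reflect_points(pt, p), pt)

    @settings(deadline=None, max_examples=50)
    @given(pts=point_sets, n=arrays(float, 3, elements=st.floats(-1, 1)),
           d=st.floats(-50, 50))
    def test_involution_and_isometry(self, pts, n, d):
        if np.linalg.norm(n) < 1e-3:
            n = np.array([1.0, 0.0, 0.0])
        plane = make_plane(n, d)
        refl = reflect_points(pts, plane)
        assert np.allclose(reflect_points(refl, plane), pts, atol=1e-9)
        orig_d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        refl_d = np.linalg.norm(refl[:, None] - refl[None], axis=-1)
        assert np.allclose(orig_d, refl_d, atol=1e-7)


class TestProcrustesRigid:
    def test_identity_on_equal_sets(self, rng):
        pts = random_points(rng)
        T = procrustes_rigid(pts, pts, weights=rng.uniform(0.5, 2.0, len(pts)))
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.translation, 0, atol=1e-9)

    def test_exact_recovery(self, rng):
        pts = random_points(rng)
        truth = random_rigid_transform(rng)
        T = procrustes_rigid(pts, truth.apply(pts))
        assert np.allclose(T.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(T.translation, truth.translation, atol=1e-9)

    def test_uniform_weights_match_unweighted(self, rng):
        src, tgt = random_points(rng), random_points(rng)
        a = procrustes_rigid(src, tgt)
        b = procrustes_rigid(src, tgt, weights=np.full(len(src), 3.7))
        assert np.allclose(a.rotation, b.rotation, atol=1e-12)
        assert np.allclose(a.translation, b.translation, atol=1e-12)

    def test_weight_scale_invariance(self, rng):
        src, tgt = random_points(rng), random_points(rng)
        w = rng.uniform(0.1, 5.0, len(src))
        a = procrustes_rigid(src, tgt, w)
        b = procrustes_rigid(src, tgt, 100.0 * w)
        assert np.allclose(a.rotation, b.rotation, atol=1e-12)
        assert np.allclose(a.translation, b.translation, atol=1e-12)

    def test_optimality_spot_check(self, rng):
        src, tgt = random_points(rng), random_points(rng)
        w = rng.uniform(0.1, 5.0, len(src))
        best = transform_objective(procrustes_rigid(src, tgt, w), src, tgt, w)
        assert best <= transform_objective(RigidTransform.identity(), src, tgt, w) + 1e-9
        for _ in range(100):
            T = random_rigid_transform(rng)
            assert best <= transform_objective(T, src, tgt, w) + 1e-9

    def test_degenerate_inputs_rejected(self, rng):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            procrustes_rigid(line, random_points(rng, 5))
        with pytest.raises(DegenerateConfigurationError):
            procrustes_rigid(random_points(rng, 2), random_points(rng, 2))

    def test_nonpositive_weight_rejected(self, rng):
        src, tgt = random_points(rng), random_points(rng)
        with pytest.raises(ValueError):
            procrustes_rigid(src, tgt, weights=np.r_[np.ones(len(src) - 1), -1.0])


class TestBestReflection:
    def test_exact_reflection_recovered(self, rng):
        plane = make_plane(rng.normal(size=3), rng.normal() * 10)
        src = random_points(rng)
        M = best_reflection(src, reflect_points(src, plane))
        expected = ImproperTransform.reflection(plane)
        assert np.allclose(M.linear, expected.linear, atol=1e-9)
        assert np.allclose(M.translation, expected.translation, atol=1e-9)
        assert transform_objective(M, src, reflect_points(src, plane)) < 1e-18

    def test_symmetric_set_gives_sagittal_eigenvector(self, rng):
        # narrow lateral spread, as for self-correspondence the optimal
        # improper map flips the least-variance direction
        half = random_points(rng, 6)
        half[:, 0] = rng.normal(0.0, 3.0, 6)
        src = np.vstack([half, half * [-1, 1, 1]])
        M = best_reflection(src, src)
        vals, vecs = np.linalg.eig(M.linear)
        i = np.argmin(np.abs(vals + 1))
        v = np.abs(np.real(vecs[:, i]))
        assert np.allclose(v, [1, 0, 0], atol=1e-9)

    def test_determinants(self, rng):
        src, tgt = random_points(rng), random_points(rng)
        assert np.linalg.det(best_reflection(src, tgt).linear) == pytest.approx(-1.0)
        assert np.linalg.det(procrustes_rigid(src, tgt).rotation) == pytest.approx(1.0)


class TestPlaneFromImproper:
    def test_pure_reflection_closed_form(self):
        plane = make_plane((0, 1, 0), 5.0)
        out = plane_from_improper(ImproperTransform.reflection(plane))
        assert np.allclose(out.normal, plane.normal, atol=1e-12)
        assert out.offset == pytest.approx(5.0, abs=1e-12)

    def test_yz_reflection(self):
        out = plane_from_improper(ImproperTransform.reflection(make_plane((1, 0, 0), 0)))
        assert np.allclose(out.normal, [1, 0, 0]) and out.offset == 0

    def test_conjugated_reflection_recovers_rotated_plane(self, rng):
        # T ∘ Refl(plane) ∘ T⁻¹ is the reflection across T(plane): recovering
        # the plane from the composed map must give exactly T(plane).
        from facesym.geometry import transform_plane
        for _ in range(500):
            plane = make_plane(rng.normal(size=3), rng.normal() * 20)
            T = random_rigid_transform(rng)
            refl = ImproperTransform.reflection(plane)
            R, t, A, b = T.rotation, T.translation, refl.linear, refl.translation
            M = ImproperTransform(R @ A @ R.T, -R @ A @ R.T @ t + R @ b + t)
            got = plane_from_improper(M)
            want = transform_plane(plane, T)
            assert np.allclose(got.normal, want.normal, atol=1e-9)
            assert got.offset == pytest.approx(want.offset, abs=1e-9)

    def test_rotary_component_warns(self):
        # reflection across x=0 composed with a 1° rotation about x
        th = np.radians(1.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        M = ImproperTransform(rot @ np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        with pytest.warns(RotaryReflectionWarning):
            plane = plane_from_improper(M)
        assert np.allclose(plane.normal, [1, 0, 0], atol=1e-9)


class TestPlaneAngles:
    @pytest.mark.parametrize("a,b,expected", [
        (((1, 0, 0), 0), ((1, 0, 0), 5), 0.0),
        (((1, 0, 0), 0), ((0, 1, 0), 0), 90.0),
        (((1, 0, 0), 0), ((-1, 0, 0), 0), 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert angle_between_planes(make_plane(*a), make_plane(*b)) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(n1=arrays(float, 3, elements=st.floats(-1, 1)),
           n2=arrays(float, 3, elements=st.floats(-1, 1)))
    def test_symmetry_and_range(self, n1, n2):
        if np.linalg.norm(n1) < 1e-3 or np.linalg.norm(n2) < 1e-3:
            return
        a, b = make_plane(n1, 0), make_plane(n2, 1)
        ang = angle_between_planes(a, b)
        assert 0 <= ang <= 90
        assert ang == pytest.approx(angle_between_planes(b, a), abs=1e-12)
        if ang < 1e-9:
            assert np.allclose(a.normal, b.normal, atol=1e-7)
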