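"""Centerline resampling, plane placement and multiplanar reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carotid_xsec.geometry import (
    Centerline,
    PlaneSpec,
    Volume,
    extract_mpr,
    normalize_patch,
    place_planes,
    place_stenosis_plane,
    plane_frame,
    resample_centerline,
)


def _line_centerline(length=20.0, step=1.0):
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length]])
    return resample_centerline(pts, step)


class TestResampleCenterline:
    def test_straight_line_unit_tangents(self):
        cl = _line_centerline(10.0, 1.0)
        assert len(cl.points) == 11
        assert np.allclose(cl.tangents, [0, 0, 1])
        assert np.allclose(np.diff(cl.arclength), 1.0)

    def test_circle_arc_tangent_orthogonal_to_radius(self):
        th = np.linspace(0, np.pi / 2, 200)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)])
        cl = resample_centerline(pts, 0.5)
        radial = cl.points / np.linalg.norm(cl.points, axis=1, keepdims=True)
        dots = np.abs(np.sum(radial * cl.tangents, axis=1))
        assert np.all(dots[1:-1] < 1e-3)

    def test_arclength_matches_analytic_circle(self):
        th = np.linspace(0, np.pi / 2, 500)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)])
        cl = resample_centerline(pts, 0.25)
        analytic = 10 * np.pi / 2
        assert abs(cl.arclength[-1] - analytic) / analytic < 0.005

    def test_duplicate_points_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 5]], dtype=float)
        with pytest.raises(ValueError, match="duplicate"):
            resample_centerline(pts, 1.0)

    def test_bifurcating_input_sets_fd_marker(self):
        raw = {
            "CCA": np.array([[0, 0, 0], [0, 0, 10.0]]),
            "ICA": np.array([[0, 0, 10.0], [1.0, 0, 20.0]]),
            "ECA": np.array([[0, 0, 10.0], [-2.0, 0, 18.0]]),
        }
        cl = resample_centerline(raw, 0.5)
        assert cl.markers["FD"] == pytest.approx(10.0)
        assert set(cl.present_branches()) == {"CCA", "ICA", "ECA"}


class TestPlaneFrame:
    def test_axis_aligned_hint(self):
        cl = _line_centerline()
        p = plane_frame(cl, 5.0, up_hint=np.array([1.0, 0, 0]))
        assert np.allclose(p.axis_u, [1, 0, 0])
        assert np.allclose(p.axis_v, [0, 1, 0])
        assert np.allclose(p.normal, [0, 0, 1])

    def test_oblique_hint_gram_schmidt(self):
        cl = _line_centerline()
        p = plane_frame(cl, 5.0, up_hint=np.array([1.0, 0, 1.0]))
        assert np.allclose(p.axis_u, [1, 0, 0], atol=1e-12)

    def test_parallel_hint_falls_back(self, caplog):
        cl = _line_centerline()
        p = plane_frame(cl, 5.0, up_hint=np.array([0.0, 0, 1.0]))
        assert abs(p.axis_u @ p.normal) < 1e-9

    def test_deterministic(self):
        cl = _line_centerline()
        a = plane_frame(cl, 7.0)
        b = plane_frame(cl, 7.0)
        assert np.array_equal(a.axis_u, b.axis_u) and np.array_equal(a.axis_v, b.axis_v)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_orthonormal_triad_property(self, tangent, hint):
        t = np.asarray(tangent)
        h = np.asarray(hint)
        if np.linalg.norm(t) < 0.1 or np.linalg.norm(h) < 0.1:
            return
        t = t / np.linalg.norm(t)
        pts = np.array([-5 * t, 5 * t])
        cl = resample_centerline(pts, 1.0)
        p = plane_frame(cl, 5.0, up_hint=h)
        assert abs(p.axis_u @ p.normal) < 1e-9
        assert abs(p.axis_v @ p.normal) < 1e-9
        assert np.allclose(np.cross(p.axis_u, p.axis_v), p.normal, atol=1e-9)


class TestPlacePlanes:
    @pytest.fixture
    def bifurcated(self):
        raw = {
            "CCA": np.array([[0, 0, 0], [0, 0, 20.0]]),
            "ICA": np.array([[0, 0, 20.0], [2.0, 0, 40.0]]),
            "ECA": np.array([[0, 0, 20.0], [-3.0, 0, 30.0]]),
        }
        return resample_centerline(raw, 0.25)

    def test_eight_planes_two_cca_five_ica_one_eca(self, bifurcated):
        planes = place_planes(bifurcated)
        assert [p.plane_id for p in planes] == list(range(1, 9))
        cca = [p for p in planes if p.center[2] < 20 - 1e-6]
        assert len(cca) == 2
        eca = [p for p in planes if p.center[0] < -1e-6]
        assert len(eca) == 1  # remaining five are ICA

    def test_planes_perpendicular_to_tangent(self, bifurcated):
        for p in place_planes(bifurcated):
            d = np.linalg.norm(p.center - np.array([0, 0, 17.5]))
            # normal must be a unit tangent of one of the straight branches
            assert any(
                abs(abs(p.normal @ t) - 1) < 1e-6
                for t in (
                    [0, 0, 1],
                    np.array([2, 0, 20]) / np.linalg.norm([2, 0, 20]),
                    np.array([-3, 0, 10]) / np.linalg.norm([-3, 0, 10]),
                )
            )

    def test_short_branch_raises(self):
        raw = {
            "CCA": np.array([[0, 0, 0], [0, 0, 20.0]]),
            "ICA": np.array([[0, 0, 20.0], [0.5, 0, 25.0]]),  # 5 mm: too short
            "ECA": np.array([[0, 0, 20.0], [-3.0, 0, 30.0]]),
        }
        cl = resample_centerline(raw, 0.25)
        with pytest.raises(ValueError, match="ICA"):
            place_planes(cl)


class TestStenosisPlane:
    def test_plane_at_thickness_maximum(self):
        cl = _line_centerline(40.0, 0.5)

        def profile(branch, s):
            return 1.0 + np.exp(-0.5 * ((s - 20.0) / 3.0) ** 2)

        p = place_stenosis_plane(cl, profile)
        assert abs(p.center[2] - 20.0) <= 0.5

    def test_flat_profile_picks_proximal(self):
        cl = _line_centerline(10.0, 1.0)
        p = place_stenosis_plane(cl, lambda b, s: 1.0)
        assert p.center[2] == pytest.approx(0.0)

    def test_equal_bumps_pick_proximal(self):
        cl = _line_centerline(40.0, 0.5)

        def profile(branch, s):
            return 1.0 + np.exp(-0.5 * ((s - 10) / 2) ** 2) + np.exp(-0.5 * ((s - 30) / 2) ** 2)

        p = place_stenosis_plane(cl, profile)
        assert abs(p.center[2] - 10.0) <= 0.5


class TestExtractMPR:
    def _plane(self, center=(10, 10, 10), n_px=32, pixel_mm=0.5):
        return PlaneSpec(
            np.asarray(center, float),
            np.array([0.0, 0, 1]),
            np.array([1.0, 0, 0]),
            np.array([0.0, 1, 0]),
            fov_mm=n_px * pixel_mm,
            pixel_mm=pixel_mm,
            n_px=n_px,
        )

    def test_constant_volume(self):
        vol = Volume(np.full((40, 40, 40), 3.25), 0.5)
        cs = extract_mpr(vol, self._plane())
        assert np.allclose(cs.image, 3.25)

    def test_linear_field_is_exact(self):
        shape = (40, 40, 40)
        x = np.arange(shape[0])[:, None, None] * 0.5
        vol = Volume(np.broadcast_to(x, shape).copy(), 0.5)
        plane = self._plane()
        cs = extract_mpr(vol, plane)
        expected = plane.pixel_world_positions()[..., 0]
        assert np.allclose(cs.image, expected, atol=1e-9)

    def test_shift_along_normal_invariant_in_constant_volume(self):
        vol = Volume(np.full((40, 40, 40), 7.0), 0.5)
        a = extract_mpr(vol, self._plane((10, 10, 10)))
        b = extract_mpr(vol, self._plane((10, 10, 10.5)))
        assert np.array_equal(a.image, b.image)

    def test_nonfinite_volume_rejected(self):
        data = np.zeros((10, 10, 10))
        data[3, 3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            extract_mpr(Volume(data, 1.0), self._plane((5, 5, 5), n_px=8, pixel_mm=0.5))

    def test_pixel_roundtrip_identity(self):
        plane = self._plane()
        ij = np.array([[3.0, 4.0], [17.25, 30.5]])
        assert np.allclose(plane.mm_to_pixel(plane.pixel_to_mm(ij)), ij, atol=1e-9)


class TestNormalizePatch:
    def test_mean_zero_std_one(self):
        rng = np.random.default_rng(0)
        plane = TestExtractMPR()._plane()
        from carotid_xsec.geometry import CrossSection

        cs = CrossSection(rng.normal(5, 3, (32, 32)), plane)
        out = normalize_patch(cs)
        assert abs(out.image.mean()) < 1e-6
        assert abs(out.image.std() - 1) < 1e-6
        assert out.normalized

    def test_constant_patch_returns_zeros(self):
        from carotid_xsec.geometry import CrossSection

        plane = TestExtractMPR()._plane()
        out = normalize_patch(CrossSection(np.full((32, 32), 9.0), plane))
        assert np.all(out.image == 0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        from carotid_xsec.geometry import CrossSection

        plane = TestExtractMPR()._plane()
        img = rng.normal(0, 1, (32, 32))
        a = normalize_patch(CrossSection(img, plane))
        b = normalize_patch(CrossSection(2.5 * img + 7.0, plane))
        assert np.allclose(a.image, b.image, atol=1e-9)
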