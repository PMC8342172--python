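"""Axis detection, reflection transforms, and the symmetry energy."""

import numpy as np
import pytest

from symseg import evolution, phantom, symmetry
from symseg.edge_prior import EdgeProbabilityMap
from symseg.exceptions import DegenerateInputError, TipNotFoundError
from symseg.symmetry import (
    HarrisParams,
    axis_from_points,
    detect_axis,
    detect_tip,
    gradient_centroid,
    harris_response,
    reflect_field,
    reflection_matrix,
    sct_energy,
    tip_fallback,
)


def _em(values):
    return EdgeProbabilityMap(np.asarray(values, dtype=float), "ground-truth-synthetic")


class TestGradientCentroid:
    def test_point_mass(self):
        vals = np.zeros((8, 8))
        vals[5, 3] = 0.7  # (x, y) = (3, 5)
        assert gradient_centroid(_em(vals)) == pytest.approx((3.0, 5.0))

    def test_two_equal_masses(self):
        vals = np.zeros((4, 12))
        vals[0, 0] = vals[0, 10] = 0.5
        assert gradient_centroid(_em(vals)) == pytest.approx((5.0, 0.0))

    def test_uniform_map_closed_form(self):
        h, w = 9, 13
        assert gradient_centroid(_em(np.full((h, w), 0.2))) == pytest.approx(
            ((w - 1) / 2.0, (h - 1) / 2.0)
        )

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = np.zeros((32, 32))
        vals[4:12, 6:14] = rng.uniform(size=(8, 8))
        c0 = gradient_centroid(_em(vals))
        shifted = np.roll(np.roll(vals, 7, axis=0), 5, axis=1)
        c1 = gradient_centroid(_em(shifted))
        assert c1 == pytest.approx((c0[0] + 5, c0[1] + 7), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            gradient_centroid(_em(np.zeros((8, 8))))


class TestAxisFromPoints:
    def test_vertical_axis_coefficients(self):
        ax = axis_from_points((0.0, 0.0), (0.0, 10.0), (11, 11))
        assert (ax.A, ax.B, ax.C) == (-10.0, 0.0, 0.0)  # line x = 0

    def test_diagonal_midpoint(self):
        ax = axis_from_points((0.0, 0.0), (10.0, 10.0), (11, 11))
        assert ax.midpoint == pytest.approx((5.0, 5.0))

    def test_defining_points_on_line(self):
        ax = axis_from_points((3.0, 4.0), (7.5, 9.25), (32, 32))
        for x, y in (ax.centroid, ax.tip):
            assert abs(ax.A * x + ax.B * y + ax.C) < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            axis_from_points((2.0, 2.0), (2.0, 2.0), (16, 16))


class TestReflectionMatrix:
    def test_vertical_axis_formula(self):
        ax = axis_from_points((20.0, 0.0), (20.0, 31.0), (32, 32))  # x = 20
        m = reflection_matrix(ax)
        xr, yr = m.transform_points([5.0, 20.0], [7.0, 3.0])
        assert xr == pytest.approx([35.0, 20.0])
        assert yr == pytest.approx([7.0, 3.0])

    def test_horizontal_axis_formula(self):
        ax = axis_from_points((0.0, 12.0), (31.0, 12.0), (32, 32))  # y = 12
        m = reflection_matrix(ax)
        xr, yr = m.transform_points(4.0, 2.0)
        assert (float(xr), float(yr)) == pytest.approx((4.0, 22.0))

    @pytest.mark.parametrize(
        "p1, p2", [((0.0, 0.0), (10.0, 13.0)), ((3.0, 27.0), (19.0, 2.0)), ((15.5, 0.0), (15.5, 20.0))]
    )
    def test_involution_isometry_fixed_line(self, p1, p2):
        ax = axis_from_points(p1, p2, (32, 32))
        m = reflection_matrix(ax)
        assert np.allclose(m.M @ m.M, np.eye(3), atol=1e-9)
        # fixed points on the axis
        for t in (0.0, 0.3, 1.0):
            x = p1[0] + t * (p2[0] - p1[0])
            y = p1[1] + t * (p2[1] - p1[1])
            xr, yr = m.transform_points(x, y)
            assert (float(xr), float(yr)) == pytest.approx((x, y), abs=1e-9)
        # isometry: pairwise distances preserved
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 31, size=(5, 2))
        xr, yr = m.transform_points(pts[:, 0], pts[:, 1])
        d0 = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        d1 = np.hypot(xr[:, None] - xr[None, :], yr[:, None] - yr[None, :])
        assert np.allclose(d0, d1, atol=1e-9)


class TestReflectField:
    def test_symmetric_field_fixed(self, vertical_reflection):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        f = np.exp(-(((xx - 31.5) / 10) ** 2) - (((yy - 20) / 8) ** 2))
        assert np.abs(reflect_field(f, vertical_reflection) - f).max() < 1e-3

    def test_double_reflection_recovers(self, vertical_reflection):
        rng = np.random.default_rng(5)
        f = rng.uniform(size=(64, 64))
        f_sm = np.asarray(f)
        from symseg.raster_core import gaussian_smooth

        f_sm = gaussian_smooth(f, 1.5)
        back = reflect_field(reflect_field(f_sm, vertical_reflection), vertical_reflection)
        assert np.abs(back - f_sm).max() < 2e-3

    def test_impulse_moves_to_mirror(self, vertical_reflection):
        f = np.zeros((64, 64))
        f[20, 53] = 1.0  # mirror of x=10 about 31.5
        out = reflect_field(f, vertical_reflection)
        assert out[20, 10] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)


class TestHarrisAndTip:
    def test_constant_image_flat_response(self):
        r = harris_response(np.full((32, 32), 0.5))
        assert np.abs(r).max() < 1e-12

    def test_square_corner_is_maximal(self):
        img = np.zeros((64, 64))
        img[20:50, 20:50] = 1.0
        r = harris_response(img)
        iy, ix = np.unravel_index(np.argmax(r), r.shape)
        corners = np.array([[20, 20], [20, 49], [49, 20], [49, 49]])
        assert np.min(np.hypot(corners[:, 0] - iy, corners[:, 1] - ix)) <= 2.0

    def test_straight_edge_nonpositive(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        r = harris_response(img)
        assert r[10:54, 30:34].max() <= 1e-12

    def test_tip_mean_of_candidates(self):
        resp = np.zeros((128, 128))
        resp[90, 40] = 1.0
        em = _em(np.full((128, 128), 0.5))
        assert detect_tip(em, resp, HarrisParams(search_halfwidth_k=40)) == (40.0, 90.0)
        resp[88, 38] = resp[92, 42] = 1.0
        resp[90, 40] = 0.0
        assert detect_tip(em, resp, HarrisParams(search_halfwidth_k=40)) == (40.0, 90.0)

    def test_tip_not_found_raises(self):
        em = _em(np.full((64, 64), 0.5))
        with pytest.raises(TipNotFoundError):
            detect_tip(em, np.zeros((64, 64)), HarrisParams())

    def test_fallback_lowest_strong_edge(self):
        vals = np.zeros((64, 64))
        vals[10, 30] = 1.0
        vals[50, 33] = 0.9
        em = _em(vals)
        assert tip_fallback(em, HarrisParams(search_halfwidth_k=10)) == (33.0, 50.0)

    def test_phantom_tip_accuracy(self):
        """Detected tip within 3 px of the stored apex on ≥ 18/20 phantoms."""
        hits = 0
        for ph in phantom.phantom_suite("clean", 20, 11):
            ax = detect_axis(ph.image, ph.edges)
            if np.hypot(ax.tip[0] - ph.apex[0], ax.tip[1] - ph.apex[1]) < 3.0:
                hits += 1
        assert hits >= 18


class TestSctEnergy:
    def test_symmetric_inputs_zero(self, notched_circle):
        phi, _, m, g = notched_circle
        assert sct_energy(phi, g, m, eta=1.0, epsilon=1.5) < 1e-6 * phi.size

    def test_notch_increases_energy_and_eta_scales(self, notched_circle):
        phi, phi_notched, m, g = notched_circle
        e_sym = sct_energy(phi, g, m, 1.0, 1.5)
        e_notch = sct_energy(phi_notched, g, m, 1.0, 1.5)
        assert e_notch > e_sym + 1.0
        assert sct_energy(phi_notched, g, m, 2.5, 1.5) == pytest.approx(2.5 * e_notch)
        assert sct_energy(phi_notched, g, m, 0.0, 1.5) == 0.0
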