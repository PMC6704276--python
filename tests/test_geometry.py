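"""Affine fitting, transform algebra, and registration-error arithmetic."""

import math

import numpy as np
import pytest
from _oracles import affine_normal_equations
from conftest import random_invertible_affine
from hypothesis import given, settings
from hypothesis import strategies as st

from msi2lmd import (
    AffineTransform2D,
    ControlPointSet,
    DegenerateGeometryError,
    FrameChainError,
    InsufficientPointsError,
    RegistrationError,
    compose,
    dpi_to_micrometers,
    estimate_error,
    fit_affine,
    propagate_errors,
    self_consistency_error,
)


def cps(pairs, src="source", dst="target"):
    return ControlPointSet.from_pairs(pairs, src, dst)


class TestFitAffine:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            # identity from the three unit landmarks
            ([((0, 0), (0, 0)), ((1, 0), (1, 0)), ((0, 1), (0, 1))],
             (1, 0, 0, 0, 1, 0)),
            # uniform 2x scaling plus translation (2, 3), solved by hand
            ([((0, 0), (2, 3)), ((1, 0), (4, 3)), ((0, 1), (2, 5))],
             (2, 0, 2, 0, 2, 3)),
        ],
    )
    def test_three_point_closed_form(self, pairs, expected):
        t = fit_affine(cps(pairs))
        assert t.params == pytest.approx(expected, abs=1e-12)

    def test_three_points_interpolate_exactly(self, rng):
        for _ in range(20):
            src = rng.uniform(-10, 10, (3, 2))
            u, v = src[1] - src[0], src[2] - src[0]
            if 0.5 * abs(u[0] * v[1] - u[1] * v[0]) < 1e-3:
                continue
            dst = rng.uniform(-10, 10, (3, 2))
            t = fit_affine(ControlPointSet("a", "b", src, dst))
            assert np.allclose(t.apply(src), dst, atol=1e-9)

    def test_noiseless_recovery(self, rng):
        for _ in range(20):
            truth = random_invertible_affine(rng)
            src = rng.uniform(-50, 50, (6, 2))
            t = fit_affine(ControlPointSet("a", "b", src, truth.apply(src)))
            assert np.allclose(t.params, truth.params, atol=1e-6)

    def test_overdetermined_matches_normal_equations_oracle(self, rng):
        truth = random_invertible_affine(rng)
        src = rng.uniform(-20, 20, (5, 2))
        dst = truth.apply(src) + rng.normal(0, 0.5, (5, 2))
        t = fit_affine(ControlPointSet("a", "b", src, dst))
        assert np.allclose(t.params, affine_normal_equations(src, dst), atol=1e-8)

    def test_least_squares_beats_ground_truth_on_noisy_points(self, rng):
        truth = random_invertible_affine(rng)
        src = rng.uniform(-20, 20, (8, 2))
        dst = truth.apply(src) + rng.normal(0, 1.0, (8, 2))
        fitted = fit_affine(ControlPointSet("a", "b", src, dst))
        rss = lambda t: ((t.apply(src) - dst) ** 2).sum()
        assert rss(fitted) <= rss(truth) + 1e-9

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            fit_affine(cps([((0, 0), (0, 0)), ((1, 1), (1, 1))]))

    def test_collinear_sources(self):
        with pytest.raises(DegenerateGeometryError):
            fit_affine(cps([((0, 0), (0, 1)), ((1, 1), (2, 2)), ((2, 2), (3, 3))]))

    def test_read_csv(self, tmp_path):
        f = tmp_path / "points.csv"
        f.write_text("src_x,src_y,dst_x,dst_y\n0,0,2,3\n1,0,4,3\n0,1,2,5\n")
        t = fit_affine(ControlPointSet.read_csv(f, "msi", "optical"))
        assert t.params == pytest.approx((2, 0, 2, 0, 2, 3))
        assert (t.source_frame, t.target_frame) == ("msi", "optical")


class TestTransformAlgebra:
    @pytest.mark.parametrize(
        "params, point, expected",
        [
            ((1, 0, 0, 0, 1, 0), (5, 7), (5, 7)),
            ((1, 0, 3, 0, 1, 4), (0, 0), (3, 4)),
            ((2, 0, 2, 0, 2, 3), (1, 1), (4, 5)),
        ],
    )
    def test_apply(self, params, point, expected):
        t = AffineTransform2D(params)
        assert t.apply([point])[0] == pytest.approx(expected)

    def test_round_trip_inverse(self, rng):
        t = random_invertible_affine(rng)
        pts = rng.uniform(-100, 100, (50, 2))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_compose_identity_and_translations(self):
        t = AffineTransform2D((2, 1, 3, 0, 2, 4), "a", "b")
        ident = AffineTransform2D.identity("b")
        assert compose(ident, t).params == pytest.approx(t.params)
        t1 = AffineTransform2D.translation(0, 1, "a", "b")
        t2 = AffineTransform2D.translation(1, 0, "b", "c")
        assert compose(t2, t1).params == pytest.approx((1, 0, 1, 0, 1, 1))

    def test_compose_scale_after_translate(self):
        translate = AffineTransform2D.translation(3, 4, "a", "b")
        scale2 = AffineTransform2D((2, 0, 0, 0, 2, 0), "b", "c")
        chained = compose(scale2, translate)
        assert chained.apply([(1, 1)])[0] == pytest.approx((8, 10))

    def test_compose_equals_sequential_application(self, rng):
        inner = random_invertible_affine(rng)
        outer = random_invertible_affine(rng)
        outer.source_frame = inner.target_frame
        pts = rng.uniform(-10, 10, (20, 2))
        assert np.allclose(
            compose(outer, inner).apply(pts), outer.apply(inner.apply(pts)), atol=1e-9
        )

    def test_compose_is_associative(self, rng):
        a, b, c = (random_invertible_affine(rng) for _ in range(3))
        b.source_frame = c.target_frame = "m1"
        a.source_frame = b.target_frame = "m2"
        c.source_frame, a.target_frame = "start", "end"
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        assert np.allclose(left.params, right.params, atol=1e-9)

    def test_inverse_of_composition(self, rng):
        inner = random_invertible_affine(rng)
        outer = random_invertible_affine(rng)
        outer.source_frame = inner.target_frame
        lhs = compose(outer, inner).inverse()
        rhs = compose(inner.inverse(), outer.inverse())
        assert np.allclose(lhs.params, rhs.params, atol=1e-9)

    def test_frame_mismatch(self):
        t1 = AffineTransform2D.identity("a")
        t2 = AffineTransform2D.identity("b")
        with pytest.raises(FrameChainError):
            compose(t2, t1)

    def test_json_round_trip(self, rng, tmp_path):
        t = random_invertible_affine(rng)
        t.source_frame, t.target_frame = "msi", "optical"
        t.write_json(tmp_path / "t.json")
        back = AffineTransform2D.read_json(tmp_path / "t.json")
        assert back.params == t.params
        assert (back.source_frame, back.target_frame) == ("msi", "optical")


finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


class TestTransformProperties:
    @settings(derandomize=True, max_examples=50)
    @given(a=finite, b=finite, c=finite, d=finite, tx=finite, ty=finite,
           px=finite, py=finite)
    def test_inverse_round_trips_any_invertible_transform(
        self, a, b, c, d, tx, ty, px, py
    ):
        if abs(a * d - b * c) < 1e-3:
            return
        t = AffineTransform2D((a, b, tx, c, d, ty))
        out = t.inverse().apply(t.apply([(px, py)]))[0]
        assert out == pytest.approx((px, py), abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(dx=st.lists(finite, min_size=1, max_size=20),
           dy=st.lists(finite, min_size=1, max_size=20))
    def test_error_summary_is_nonnegative_and_sign_invariant(self, dx, dy):
        n = min(len(dx), len(dy))
        dev = list(zip(dx[:n], dy[:n]))
        e = estimate_error(dev)
        flipped = estimate_error([(-x, -y) for x, y in dev])
        assert e.mean_x >= 0 and e.sd_x >= 0
        assert e.mean_x == pytest.approx(flipped.mean_x, rel=1e-12, abs=1e-12)
        assert e.sd_y == pytest.approx(flipped.sd_y, rel=1e-12, abs=1e-12)


class TestErrorEstimation:
    def test_zero_residuals(self):
        e = estimate_error([(0, 0), (0, 0)])
        assert (e.mean_x, e.mean_y, e.sd_x, e.sd_y) == (0, 0, 0, 0)

    def test_absolute_deviation_summary(self):
        # |dx| = {2, 2, 4}: mean 8/3, sample SD sqrt(4/3)
        e = estimate_error([(2, 0), (-2, 0), (4, 0)])
        assert e.mean_x == pytest.approx(8 / 3)
        assert e.sd_x == pytest.approx(math.sqrt(4 / 3))
        assert e.n == 3

    def test_single_landmark_has_zero_sd(self):
        e = estimate_error([(5, -3)])
        assert (e.mean_x, e.mean_y, e.sd_x, e.sd_y, e.n) == (5, 3, 0, 0, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_error([])

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([(1, 2), (3, 4)], [(1, 2), (3, 4)], 0.0),
            ([(0, 0)], [(3, 4)], 5.0),
            ([(0, 0), (1, 1)], [(3, 4), (1, 1)], 2.5),
        ],
    )
    def test_self_consistency_error(self, a, b, expected):
        assert self_consistency_error(a, b) == pytest.approx(expected)

    def test_self_consistency_length_mismatch(self):
        with pytest.raises(ValueError):
            self_consistency_error([(0, 0)], [(0, 0), (1, 1)])


class TestErrorPropagation:
    def test_single_step_is_identity(self):
        step = RegistrationError(5, 5, 1, 1, 3)
        out = propagate_errors([step])
        assert (out.mean_x, out.sd_x) == (5, 1)

    def test_means_add_and_sds_combine_in_quadrature(self):
        steps = [
            RegistrationError(7.89, 3.96, 4.06, 4.32, 3),
            RegistrationError(1.39, 1.39, 0.33, 0.50, 5),
            RegistrationError(3.46, 7.39, 2.62, 3.78, 3),
        ]
        out = propagate_errors(steps)
        assert round(out.mean_x, 2) == 12.74
        assert round(out.mean_y, 2) == 12.74
        assert round(out.sd_x, 2) == 4.84
        assert round(out.sd_y, 2) == 5.76

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            propagate_errors([])


class TestDpiConversion:
    @pytest.mark.parametrize(
        "dpi, expected", [(12235, 2.076), (12189, 2.084), (25400, 1.0)]
    )
    def test_known_values(self, dpi, expected):
        assert round(dpi_to_micrometers(dpi), 3) == expected

    @pytest.mark.parametrize("dpi", [0, -100])
    def test_nonpositive_rejected(self, dpi):
        with pytest.raises(ValueError):
            dpi_to_micrometers(dpi)
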