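import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gkvol.dosefield import DoseField, isodose_points, isodose_radius
from gkvol.profiles import ErfSumModel, evaluate_profile


def make_field(z_skew=0.0):
    """Simple elliptical field: equal x/y profiles, shorter z profile.

    ``z_skew`` shifts the falling-edge widths of the z model to make it
    asymmetric about the XY plane.
    """
    xy = ErfSumModel(A=[-50.0], a=[-5.0], b=[1.5], c0=50.0, symmetric=True)
    z = ErfSumModel(A=[50.0, -50.0], a=[4.0, -4.0],
                    b=[1.2 * (1 - z_skew), 1.2 * (1 + z_skew)], c0=0.0,
                    symmetric=False)
    return DoseField(field_size_mm=8, model_x=xy, model_y=xy, model_z=z)


class TestEvaluate:
    def test_center_is_exactly_one(self):
        f = make_field()
        assert f.evaluate([0.0, 0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("axis,unit", [("x", (1, 0, 0)), ("y", (0, 1, 0)),
                                           ("z", (0, 0, 1))])
    def test_on_axis_matches_normalized_1d_profile(self, axis, unit):
        f = make_field(z_skew=0.2)
        model = getattr(f, f"model_{axis}")
        d0 = evaluate_profile(model, 0.0)
        for d in (0.5, 2.0, 4.5, 7.0):
            pt = np.asarray(unit, float) * d
            expected = evaluate_profile(model, d) / d0
            assert f.evaluate(pt) == pytest.approx(expected, abs=1e-9)

    def test_negative_z_uses_signed_profile_argument(self):
        f = make_field(z_skew=0.3)
        d0 = evaluate_profile(f.model_z, 0.0)
        up = f.evaluate([0, 0, 3.5])
        down = f.evaluate([0, 0, -3.5])
        assert up == pytest.approx(evaluate_profile(f.model_z, 3.5) / d0, abs=1e-9)
        assert down == pytest.approx(evaluate_profile(f.model_z, -3.5) / d0, abs=1e-9)
        assert up != pytest.approx(down, abs=1e-4)

    @settings(derandomize=True, deadline=None)
    @given(st.tuples(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10))
           .filter(lambda p: any(abs(c) > 1e-6 for c in p)))
    def test_uniform_profiles_give_exactly_one(self, point):
        # weight closure: (dx^2+dy^2+dz^2)/rho^2 == 1
        const = lambda k: np.full_like(np.asarray(k, float), 100.0)
        f = DoseField(field_size_mm=16, model_x=const, model_y=const, model_z=const)
        assert f.evaluate(np.array(point)) == pytest.approx(1.0, abs=1e-12)

    def test_xy_dose_depends_only_on_radius_when_x_equals_y(self):
        f = make_field()
        rho = 4.2
        vals = [f.evaluate([rho * np.cos(t), rho * np.sin(t), 0.0])
                for t in np.linspace(0, 2 * np.pi, 17)]
        assert np.ptp(vals) < 1e-12

    def test_continuity_toward_center(self):
        f = make_field(z_skew=0.2)
        u = np.array([0.3, -0.5, 0.81])
        u /= np.linalg.norm(u)
        for r, tol in ((1e-2, 1e-2), (1e-4, 1e-4), (1e-7, 1e-6)):
            assert f.evaluate(r * u) == pytest.approx(1.0, abs=tol)


class TestIsodose:
    def test_level_on_x_axis_matches_1d_bisection_oracle(self):
        from scipy.optimize import brentq
        f = make_field()
        d0 = evaluate_profile(f.model_x, 0.0)
        oracle = brentq(lambda k: evaluate_profile(f.model_x, k) / d0 - 0.5,
                        1e-6, 30.0, xtol=1e-12)
        assert isodose_radius(f, (1, 0, 0), 0.5) == pytest.approx(oracle, abs=1e-8)

    def test_points_lie_on_surface(self):
        f = make_field(z_skew=0.2)
        pts = isodose_points(f, 0.5, n_samples=40, seed=3)
        doses = f.evaluate(pts)
        np.testing.assert_allclose(doses, 0.5, atol=1e-6)

    def test_symmetric_xy_extents_equal(self):
        f = make_field()
        rx = isodose_radius(f, (1, 0, 0), 0.5)
        ry = isodose_radius(f, (0, 1, 0), 0.5)
        assert rx == pytest.approx(ry, abs=1e-6)

    def test_high_level_collapses_to_center(self):
        f = make_field()
        pts = isodose_points(f, 0.999, n_samples=10, seed=0)
        assert np.linalg.norm(pts, axis=1).max() < isodose_radius(f, (1, 0, 0), 0.5)

    def test_xy_circular_xz_elliptical(self):
        # 50 % isodose: circular XY cross-section, elliptical XZ section
        f = make_field()
        rx = isodose_radius(f, (1, 0, 0), 0.5)
        rxy = isodose_radius(f, (1, 1, 0), 0.5)
        rz = isodose_radius(f, (0, 0, 1), 0.5)
        assert rxy == pytest.approx(rx, abs=1e-6)
        assert abs(rz - rx) > 0.5  # distinct z profile -> not circular in XZ

    def test_invalid_level(self):
        f = make_field()
        with pytest.raises(ValueError):
            isodose_radius(f, (1, 0, 0), 1.5)


def test_serialization_round_trip(tmp_path):
    f = make_field(z_skew=0.1)
    p = tmp_path / "field.yaml"
    f.save(p)
    f2 = DoseField.load(p)
    pts = np.array([[1.0, 2.0, -3.0], [0.5, 0.0, 4.0]])
    np.testing.assert_allclose(f2.evaluate(pts), f.evaluate(pts), atol=1e-12)
    assert f2.field_size_mm == f.field_size_mm
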