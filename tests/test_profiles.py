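import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from gkvol.profiles import (ErfSumModel, ProfileCurve, erf, evaluate_profile,
                            fit_profile)


class TestErf:
    def test_zero(self):
        assert erf(0.0) == 0.0

    def test_value_at_one_against_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the defining integral
        oracle, _ = integrate.quad(lambda t: np.exp(-t * t), 0.0, 1.0)
        oracle *= 2.0 / np.sqrt(np.pi)
        assert erf(1.0) == pytest.approx(oracle, abs=1e-12)
        assert erf(1.0) == pytest.approx(0.842700792949715, abs=1e-12)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(-5, 5))
    def test_odd_bounded_monotone(self, z):
        assert erf(-z) == -erf(z)
        assert -1.0 < erf(z) < 1.0 or z == 0
        assert erf(z + 0.1) > erf(z)


def penumbra_model(symmetric=True):
    """Flat-top-like model: 100 in the center falling to 0."""
    return ErfSumModel(A=[-50.0], a=[-4.0], b=[1.5], c0=50.0,
                       symmetric=symmetric)


class TestEvaluateProfile:
    def test_all_shifts_zero_gives_offset(self):
        m = ErfSumModel(A=[30.0, -20.0, 5.0], a=[0.0, 0.0, 0.0],
                        b=[1.0, 2.0, 3.0], c0=50.0, symmetric=False)
        assert evaluate_profile(m, 0.0) == pytest.approx(50.0, abs=1e-14)

    def test_two_term_closed_form(self):
        b = 1.7
        m = ErfSumModel(A=[50.0, -50.0], a=[b, -b], b=[b, b], c0=0.0,
                        symmetric=False)
        assert evaluate_profile(m, 0.0) == pytest.approx(100.0 * erf(1.0), abs=1e-12)

    def test_single_term_limits(self):
        m = ErfSumModel(A=[-50.0], a=[0.0], b=[2.0], c0=50.0, symmetric=False)
        assert evaluate_profile(m, 1e3) == pytest.approx(0.0, abs=1e-12)
        assert evaluate_profile(m, -1e3) == pytest.approx(100.0, abs=1e-12)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(-30, 30))
    def test_symmetric_model_is_exactly_even(self, k):
        m = penumbra_model(symmetric=True)
        assert evaluate_profile(m, k) == evaluate_profile(m, -k)

    def test_monotone_decreasing_in_abs_k_for_penumbra_shape(self):
        m = penumbra_model()
        k = np.linspace(0, 15, 400)
        d = evaluate_profile(m, k)
        assert np.all(np.diff(d) <= 0)

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            ErfSumModel(A=[1.0], a=[0.0], b=[0.0], c0=0.0)


class TestProfileCurve:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ProfileCurve("x", 16, [0, 1, 1], [10, 20, 30])
        with pytest.raises(ValueError):
            ProfileCurve("x", 16, [0, 1, 2], [10, 20, 150])
        with pytest.raises(ValueError):
            ProfileCurve("w", 16, [0, 1], [10, 20])

    def test_csv_round_trip(self, tmp_path):
        c = ProfileCurve("z", 8, np.linspace(-5, 5, 21),
                         np.linspace(0, 100, 21))
        p = tmp_path / "prof.csv"
        c.to_csv(p)
        c2 = ProfileCurve.from_csv(p, "z", 8)
        np.testing.assert_allclose(c2.positions, c.positions)
        np.testing.assert_allclose(c2.doses, c.doses)


class TestFitProfile:
    def test_noiseless_round_trip_recovers_predictions(self):
        truth = ErfSumModel(A=[-30.0, -20.0], a=[-3.5, -4.5], b=[1.0, 2.0],
                            c0=50.0, symmetric=True)
        k = np.linspace(0, 12, 50)
        curve = ProfileCurve("x", 8, k, evaluate_profile(truth, k))
        rep = fit_profile(curve, n=2, symmetric=True)
        assert rep.r_squared >= 0.999999
        assert rep.residual_max < 1e-4
        kk = np.linspace(0, 12, 137)
        np.testing.assert_allclose(evaluate_profile(rep.model, kk),
                                   evaluate_profile(truth, kk), atol=1e-4)

    def test_noisy_fit_reaches_published_quality_regime(self):
        truth = ErfSumModel(A=[-30.0, -20.0], a=[-3.5, -4.5], b=[1.0, 2.0],
                            c0=50.0, symmetric=True)
        rng = np.random.default_rng(7)
        k = np.linspace(0, 12, 120)
        d = np.clip(evaluate_profile(truth, k) + rng.normal(0, 0.2, k.size), 0, 110)
        rep = fit_profile(ProfileCurve("y", 8, k, d), n=2)
        assert rep.r_squared >= 0.999

    def test_constant_curve_is_degenerate(self):
        curve = ProfileCurve("x", 16, np.linspace(0, 10, 30),
                             np.full(30, 50.0))
        with pytest.raises(ValueError, match="constant"):
            fit_profile(curve, n=2)

    def test_too_few_points(self):
        curve = ProfileCurve("x", 16, np.linspace(0, 10, 6),
                             np.linspace(100, 0, 6))
        with pytest.raises(ValueError, match="points"):
            fit_profile(curve, n=4)

    def test_symmetric_fit_uses_only_nonnegative_positions(self):
        # corrupt the negative side: the symmetric fit must not see it
        truth = penumbra_model()
        k = np.linspace(-10, 10, 81)
        d = evaluate_profile(truth, k).copy()
        d[k < 0] = 10.0
        rep = fit_profile(ProfileCurve("x", 16, k, np.clip(d, 0, 110)),
                          n=1, symmetric=True)
        assert rep.residual_max < 1e-6
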