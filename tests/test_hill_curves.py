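"""Normalized Hill curves against independent brute-force evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emg2torque.exceptions import GeometryError, InvalidParameterError, ConfigurationError
from emg2torque.hill import (
    FV_ECCENTRIC_ASYMPTOTE,
    ModelConstants,
    MuscleParams,
    active_force_length,
    effective_optimal_length,
    fiber_velocity,
    force_velocity,
    invert_force_velocity,
    passive_force_length,
    pennation_angle,
    tendon_force,
    tendon_length,
    tendon_strain,
)


class TestActiveForceLength:
    def test_matches_pointwise_oracle(self, constants):
        l = np.linspace(0.0, 2.0, 201)
        got = active_force_length(l, constants)
        oracle = np.array(
            [
                (-2.06 + 6.16 * x - 3.13 * x * x) if 0.5 <= x <= 1.5 else 0.0
                for x in l
            ]
        )
        assert np.allclose(got, oracle, rtol=0, atol=1e-14)

    def test_outside_support_is_zero(self, constants):
        assert active_force_length(0.4, constants) == 0.0
        assert active_force_length(1.6, constants) == 0.0

    def test_at_optimal_length_sums_printed_coefficients(self, constants):
        assert active_force_length(1.0, constants) == pytest.approx(0.97, abs=1e-12)

    def test_support_endpoints_near_symmetric(self, constants):
        # vertex at l = 6.16 / (2 * 3.13) ~= 0.984, so endpoint values differ
        assert active_force_length(0.5, constants) == pytest.approx(0.2375, abs=1e-12)
        assert active_force_length(1.5, constants) == pytest.approx(0.1375, abs=1e-12)

    def test_negative_quadratic_on_support_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConstants(q0=-5.0)


class TestPassiveForceLength:
    def test_matches_pointwise_oracle(self):
        l = np.linspace(0.0, 2.0, 150)
        oracle = np.array([math.exp(10.0 * x - 15.0) for x in l])
        assert np.allclose(passive_force_length(l), oracle, rtol=1e-15)

    def test_exponent_cancellation_at_1p5(self):
        assert passive_force_length(1.5) == pytest.approx(1.0, abs=1e-15)
        assert passive_force_length(1.0) == pytest.approx(math.exp(-5.0), rel=1e-15)

    def test_strictly_increasing(self):
        l = np.linspace(0.5, 1.5, 100)
        assert np.all(np.diff(passive_force_length(l)) > 0)


class TestForceVelocity:
    def test_matches_pointwise_oracle(self):
        v = np.linspace(-1.0, 5.0, 241)
        oracle = np.array(
            [
                0.3 * (x + 1.0) / (0.3 - x)
                if x < 0
                else (2.34 * x + 0.039) / (1.3 * x + 0.039)
                for x in v
            ]
        )
        assert np.allclose(force_velocity(v), oracle, rtol=1e-14)

    def test_isometric_and_limits(self):
        assert force_velocity(0.0) == pytest.approx(1.0, abs=1e-15)
        assert force_velocity(-1.0) == pytest.approx(0.0, abs=1e-15)
        assert force_velocity(1e9) == pytest.approx(FV_ECCENTRIC_ASYMPTOTE, rel=1e-6)
        assert FV_ECCENTRIC_ASYMPTOTE == pytest.approx(1.8, abs=1e-12)

    def test_continuous_at_zero(self):
        assert force_velocity(-1e-12) == pytest.approx(force_velocity(1e-12), abs=1e-9)

    def test_bounded(self):
        v = np.linspace(-1, 50, 500)
        fv = force_velocity(v)
        assert fv.min() >= 0.0 and fv.max() < 1.8


class TestInvertForceVelocity:
    def test_fixed_points(self):
        assert invert_force_velocity(1.0) == pytest.approx(0.0, abs=1e-15)
        assert invert_force_velocity(0.0) == pytest.approx(-1.0, abs=1e-15)

    def test_round_trip_over_both_branches(self, rng):
        x = rng.uniform(-1.0, 5.0, 100)
        fv = force_velocity(x)
        back = invert_force_velocity(fv)
        assert np.allclose(back, x, atol=1e-10)

    @given(fv=st.floats(min_value=0.0, max_value=1.7))
    @settings(deadline=None, max_examples=50)
    def test_forward_of_inverse(self, fv):
        assert force_velocity(invert_force_velocity(fv)) == pytest.approx(fv, abs=1e-10)


class TestTendon:
    def test_slack_tendon_carries_no_load(self, ta):
        assert tendon_force(ta.lst, ta) == 0.0
        assert tendon_force(0.9 * ta.lst, ta) == 0.0

    def test_quadratic_toe_region_example(self, constants):
        mp = MuscleParams("x", F0m=1000.0, l0m=0.03, lst=0.3, phi0_deg=10.0)
        lt = mp.lst * 1.01  # eps = 0.01
        assert tendon_force(lt, mp, constants) == pytest.approx(
            1000.0 * 1480.3 * 1e-4, rel=1e-12
        )

    def test_branch_gap_at_knee_small(self, ta, constants):
        e = constants.eps_knee
        quad = constants.k_quad * e * e
        lin = constants.k_lin * e - constants.c_lin
        gap = abs(quad - lin)
        assert gap == pytest.approx(0.002507587, abs=1e-9)
        assert gap * ta.F0m < 0.005 * ta.F0m

    def test_nondecreasing_and_matches_oracle(self, ta, constants):
        lt = np.linspace(0.8 * ta.lst, 1.1 * ta.lst, 301)
        got = tendon_force(lt, ta, constants)

        def oracle(x):
            eps = (x - ta.lst) / ta.lst
            if eps <= 0:
                return 0.0
            if eps < 0.0127:
                return ta.F0m * 1480.3 * eps * eps
            return ta.F0m * (37.5 * eps - 0.24)

        assert np.allclose(got, [oracle(x) for x in lt], rtol=1e-12)
        assert np.all(np.diff(got) >= 0)
        assert got.min() >= 0.0

    def test_strain_sign_kept_for_diagnostics(self, ta):
        assert tendon_strain(0.95 * ta.lst, ta) < 0


class TestPennation:
    def test_identity_at_optimal_length(self, ta):
        assert pennation_angle(ta.l0m, ta) == pytest.approx(ta.phi0, rel=1e-12)

    def test_doubled_fiber_length_value(self, ta):
        # asin(sin(12 deg) / 2), evaluated independently
        assert pennation_angle(2 * ta.l0m, ta) == pytest.approx(0.10414400051050507, abs=1e-12)

    def test_monotone_decreasing(self, ta):
        assert pennation_angle(1.5 * ta.l0m, ta) < pennation_angle(ta.l0m, ta)

    def test_short_fiber_clamps_to_right_angle(self, ta):
        tiny = ta.l0m * math.sin(ta.phi0) * 0.5
        assert pennation_angle(tiny, ta) == pytest.approx(math.pi / 2)

    def test_nonpositive_fiber_rejected(self, ta):
        with pytest.raises(InvalidParameterError):
            pennation_angle(0.0, ta)


class TestTendonLength:
    def test_arithmetic(self):
        assert tendon_length(0.35, 0.04, 0.0) == pytest.approx(0.31, abs=1e-15)
        assert tendon_length(0.35, 0.04, math.pi / 2) == pytest.approx(0.35, abs=1e-12)

    def test_exactly_slack_composition(self, ta, constants):
        phi = 0.15
        lmt = ta.lst + 0.03 * math.cos(phi)
        lt = tendon_length(lmt, 0.03, phi)
        assert tendon_force(lt, ta, constants) == 0.0

    def test_negative_tendon_rejected(self):
        with pytest.raises(GeometryError):
            tendon_length(0.02, 0.05, 0.0)


class TestEffectiveOptimalLength:
    @pytest.mark.parametrize(
        "a,factor", [(1.0, 1.0), (0.0, 1.15), (0.5, 1.075)]
    )
    def test_printed_formula(self, ta, constants, a, factor):
        assert effective_optimal_length(a, ta, constants) == pytest.approx(
            factor * ta.l0m, rel=1e-12
        )


class TestFiberVelocity:
    def test_isometric_equilibrium_gives_zero_velocity(self, ta, constants):
        from conftest import isometric_setup

        lm, lmt = isometric_setup(ta, constants, a=0.5)
        vm, info = fiber_velocity(lm, 0.5, lmt, ta, constants, full_output=True)
        assert info["fv"] == pytest.approx(1.0, abs=1e-10)
        assert vm == pytest.approx(0.0, abs=1e-10 * ta.v0m)
        assert not info["clamped"]

    def test_tendon_below_passive_clamps_to_max_shortening(self, ta, constants):
        # slack tendon, long fiber: passive force alone exceeds tendon force
        lm = 1.4 * ta.l0m
        lmt = ta.lst * 0.9  # deeply slack
        vm, info = fiber_velocity(lm, 0.5, lmt, ta, constants, full_output=True)
        assert info["fv"] == 0.0
        assert info["clamped"]
        assert vm == pytest.approx(-ta.v0m, rel=1e-12)

    def test_round_trip_with_force_velocity_when_unclamped(self, ta, constants):
        from conftest import isometric_setup

        lm, lmt = isometric_setup(ta, constants, a=0.6, l_norm=1.1)
        for dl in (-0.002, -0.001, 0.0, 0.001):
            vm, info = fiber_velocity(lm + dl, 0.6, lmt, ta, constants, full_output=True)
            if not info["clamped"]:
                assert force_velocity(vm / ta.v0m) == pytest.approx(info["fv"], abs=1e-8)

    def test_kernel_agrees_with_reference_implementation(self, ta, constants, rng):
        from emg2torque._kernel import _fiber_velocity_scalar

        for _ in range(200):
            lm = rng.uniform(0.6, 1.6) * ta.l0m
            a = rng.uniform(0.0, 1.0)
            lmt = rng.uniform(0.98, 1.03) * (ta.lst + ta.l0m)
            vm_ref = fiber_velocity(lm, a, lmt, ta, constants)
            vm_ker = _fiber_velocity_scalar(
                lm, a, lmt, ta.F0m, ta.l0m, ta.lst, math.sin(ta.phi0), ta.v0m,
                constants.lambda_pct, constants.q0, constants.q1, constants.q2,
                constants.eps_knee, constants.k_quad, constants.k_lin,
                constants.c_lin, 0.01, 1,
            )[0]
            assert vm_ker == pytest.approx(vm_ref, rel=1e-12, abs=1e-15)
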