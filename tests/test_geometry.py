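"""Entrainment geometry: circle maps, dark-pulse shifts, variance laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clocktradeoff.dynamics import ClockGeometry
from clocktradeoff.geometry import (
    circle_map,
    dark_pulse_bound,
    dark_pulse_phase_shift,
    entrained_dusk_phase,
    external_variance_recursion,
    internal_variance_recursion,
    map_slope,
    optimal_ratio,
    point_attractor_variance,
    steady_state_variance_external,
    steady_state_variance_internal,
    tradeoff_product,
    variance_cycle_stages,
)


class TestCircleMap:
    def test_identity_when_undriven(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=0.0)
        cm = circle_map(g, "radial_projection")
        assert np.max(np.abs(cm.phi_values - cm.theta_grid)) < 1e-9

    def test_mirror_symmetry_points(self, cycle_geometry):
        cm = circle_map(cycle_geometry, "radial_projection")
        assert cm(0.0) == pytest.approx(0.0, abs=1e-12)
        assert abs(cm(np.pi)) == pytest.approx(np.pi, abs=1e-9)

    def test_projection_value_at_quarter_turn(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=0.1)
        cm = circle_map(g, "radial_projection")
        assert cm(np.pi / 2) == pytest.approx(np.arctan2(1.0, 0.1), abs=1e-6)

    def test_methods_agree(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=0.1, tau_relax=2.0)
        proj = circle_map(g, "radial_projection")
        relax = circle_map(g, "relaxation_integration", n_grid=41)
        diff = np.abs(proj(relax.theta_grid) - relax.phi_values)
        assert diff.max() < 1e-6
        s_p = map_slope(proj, 0.3)
        s_r = map_slope(relax, 0.3)
        assert s_r == pytest.approx(s_p, rel=0.02)

    def test_slope_at_origin_analytic(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=0.1)
        cm = circle_map(g, "radial_projection", n_grid=2001)
        assert map_slope(cm, 0.0) == pytest.approx(1.0 / 1.1, rel=1e-4)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(lr=st.floats(0.01, 0.8))
    def test_monotone_and_degree_one(self, lr):
        g = ClockGeometry.limit_cycle(R=1.0, L=lr)
        cm = circle_map(g, "radial_projection")
        assert cm.monotone
        assert np.all(np.diff(cm.phi_values) > 0)
        theta = np.linspace(-np.pi, np.pi, 11)
        assert np.allclose(cm(theta + 2 * np.pi), cm(theta) + 2 * np.pi,
                           atol=1e-9)

    def test_folded_map_flagged_when_overdriven(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=1.5)
        cm = circle_map(g, "radial_projection")
        assert not cm.monotone
        assert cm.warning is not None
        with pytest.raises(ValueError):
            map_slope(cm, np.pi)  # slope non-positive on the folded branch

    def test_point_attractor_rejected(self, point_geometry):
        with pytest.raises(ValueError):
            circle_map(point_geometry)


class TestEntrainedDuskPhase:
    def test_dusk_phase_sits_at_stable_fixed_point(self):
        # the one-day phase map theta -> theta - 2(L/R) sin(theta) attracts
        # to theta = 0 at dusk
        for lr in (0.05, 0.1, 0.2):
            g = ClockGeometry.limit_cycle(R=1.0, L=lr)
            assert abs(entrained_dusk_phase(g)) < 0.05


class TestVarianceRecursions:
    def test_external_fixed_point_matches_closed_form(self):
        for dphi2 in (0.01, 0.09, 1.0):
            for s2 in (1.05, 1.5, 2.0):
                sigma2 = 0.0
                for _ in range(800):
                    sigma2 = external_variance_recursion(sigma2, dphi2, s2)
                assert sigma2 == pytest.approx(
                    steady_state_variance_external(dphi2, s2), abs=1e-12)

    def test_internal_fixed_point_matches_closed_form(self):
        for eps2T in (0.001, 0.01, 0.5):
            for s2 in (1.05, 1.1, 2.0):
                sigma2 = 0.0
                for _ in range(800):
                    sigma2 = internal_variance_recursion(sigma2, eps2T, s2)
                assert sigma2 == pytest.approx(
                    steady_state_variance_internal(eps2T, 1.0, s2), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(s2=st.floats(1.0001, 10.0), eps2T=st.floats(1e-6, 1.0))
    def test_two_dusk_identity(self, s2, eps2T):
        # eps^2 T (1 + s^2)/(s^4 - 1) == eps^2 T/(s^2 - 1)
        lhs = eps2T * (1 + s2) / (s2**2 - 1)
        rhs = eps2T / (s2 - 1)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(s2=st.floats(1.01, 5.0), sigma0=st.floats(0.0, 100.0))
    def test_fixed_points_attract_from_anywhere(self, s2, sigma0):
        target = steady_state_variance_external(0.05, s2)
        sigma2 = sigma0
        for _ in range(2000):
            sigma2 = external_variance_recursion(sigma2, 0.05, s2)
        assert sigma2 == pytest.approx(target, rel=1e-6)

    def test_substitution_values(self):
        assert steady_state_variance_external(0.0, 2.0) == 0.0
        assert steady_state_variance_external(0.09, 2.0) == pytest.approx(0.03)
        assert steady_state_variance_internal(0.01, 1.0, 1.1) == pytest.approx(0.1)
        assert point_attractor_variance(0.01, 12.0) == pytest.approx(0.12)

    def test_no_steady_state_for_undriven(self):
        with pytest.raises(ValueError):
            steady_state_variance_external(0.1, 1.0)
        with pytest.raises(ValueError):
            steady_state_variance_internal(0.1, 12.0, 0.9)

    def test_stage_ledger_traces_one_cycle(self):
        stages = variance_cycle_stages(0.1, gain=0.02, s2=1.5)
        assert [s.stage for s in stages] == ["day", "dusk", "night", "dawn"]
        assert stages[0].sigma2 == pytest.approx(0.12)
        assert stages[-1].sigma2 == pytest.approx(((0.12 / 1.5) + 0.02) / 1.5)


class TestDarkPulse:
    def test_zero_duration_and_undriven_give_no_shift(self, cycle_geometry):
        assert dark_pulse_phase_shift(cycle_geometry, 2.4, 0.0) == 0.0
        g0 = ClockGeometry.limit_cycle(R=1.0, L=0.0)
        assert dark_pulse_phase_shift(g0, 2.4, 2.4) == 0.0

    def test_pulse_must_stay_inside_daytime(self, cycle_geometry):
        with pytest.raises(ValueError):
            dark_pulse_phase_shift(cycle_geometry, 10.8, 2.4)  # spills past dusk

    def test_point_attractor_shift_far_exceeds_limit_cycle(self):
        for lr in (0.05, 0.1, 0.2):
            cyc = ClockGeometry.limit_cycle(R=1.0, L=lr)
            pt = ClockGeometry.point_attractor(L=lr)
            assert dark_pulse_phase_shift(pt, 2.4, 2.4) > \
                5.0 * dark_pulse_phase_shift(cyc, 2.4, 2.4)

    def test_shift_bounded_by_attractor_geometry(self):
        # the circular attractor caps the lag for any pulse duration
        for lr in (0.1, 0.2):
            g = ClockGeometry.limit_cycle(R=1.0, L=lr)
            bound = dark_pulse_bound(g)
            shifts = [dark_pulse_phase_shift(g, 1.2, d)
                      for d in (0.6, 2.4, 4.8, 9.6)]
            assert max(shifts) <= bound


class TestTradeoffAlgebra:
    def test_optimal_ratio_is_noise_ratio(self):
        assert optimal_ratio(0.05, 0.05) == pytest.approx(1.0)
        assert optimal_ratio(0.0, 0.1) == 0.0
        with pytest.raises(ZeroDivisionError):
            optimal_ratio(0.1, 0.0)

    def test_product_invariant(self):
        assert tradeoff_product(0.1, 0.2) == pytest.approx(4e-4)
        assert tradeoff_product(0.0, 0.5) == 0.0
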