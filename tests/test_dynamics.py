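"""Minimal clock models: drift fields, integration, phase decoding."""

from dataclasses import replace

import numpy as np
import pytest

from clocktradeoff.dynamics import (
    ClockGeometry,
    NoiseSpec,
    copy_number_to_eps,
    decode_phase,
    drift_field,
    entrained_state,
    integrate_ensemble,
    reference_radius,
)
from clocktradeoff.signals import make_square_wave


def constant_light(t_end=100.0, dt=0.01):
    sig = make_square_wave(t_end=t_end, dt=dt)
    return replace(sig, rho=np.ones_like(sig.rho))


class TestDriftField:
    def test_on_cycle_radial_velocity_vanishes(self, cycle_geometry):
        # state on the day attractor circle: only tangential motion
        state = np.array([0.1 + 1.0, 0.0])
        v = drift_field(state, 1.0, cycle_geometry)
        u = state - np.array([0.1, 0.0])
        radial = np.dot(v, u) / np.linalg.norm(u)
        assert radial == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(v) == pytest.approx(cycle_geometry.omega, rel=1e-12)

    def test_point_attractor_fixed_point(self, point_geometry):
        center = np.array([-0.1, 0.0])  # day center for rho = 1
        v = drift_field(center, 1.0, point_geometry)
        assert np.allclose(v, 0.0, atol=1e-15)

    def test_cubic_radial_speed_value(self):
        g = ClockGeometry.limit_cycle(R=1.0, L=0.0, tau_relax=1.0)
        state = np.array([0.5, 0.0])  # r = 0.5 from the center (rho=0)
        v = drift_field(state, 0.0, g)
        # (r - r^3/R^2)/tau = 0.5 - 0.125 = 0.375
        assert v[0] == pytest.approx(0.375, rel=1e-12)

    def test_rho_out_of_range_rejected(self, cycle_geometry):
        with pytest.raises(ValueError):
            drift_field(np.array([1.0, 0.0]), 1.5, cycle_geometry)


class TestGeometryValidation:
    def test_point_attractor_requires_zero_R(self):
        with pytest.raises(ValueError):
            ClockGeometry(kind="point_attractor", R=1.0, L=0.1)
        with pytest.raises(ValueError):
            ClockGeometry(kind="limit_cycle", R=0.0, L=0.1)

    def test_copy_number_calibration(self):
        assert copy_number_to_eps(100, calibration=1.0) == pytest.approx(0.1)
        # quadrupling N halves eps
        assert copy_number_to_eps(400) == pytest.approx(copy_number_to_eps(100) / 2)
        with pytest.raises(ValueError):
            copy_number_to_eps(0)
        spec = NoiseSpec(copy_number=10_000)
        assert spec.eps_int == pytest.approx(0.01)


class TestDeterministicIntegration:
    def test_radius_pinned_to_attractor(self, cycle_geometry):
        sig = constant_light(100.0)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(), sig,
                                 n_members=1, init="entrained",
                                 record_every=100)
        u = ens.positions[:, 0, :] - np.array([0.1, 0.0])
        r = np.hypot(u[:, 0], u[:, 1])
        # skip the initial relaxation onto the constant-light attractor;
        # afterwards the Euler rotation bias pins r at ~ omega^2 dt tau / 2
        settled = ens.times > 40.0
        bound = cycle_geometry.omega**2 * sig.dt * cycle_geometry.tau_relax
        assert np.all(np.abs(r[settled] - 1.0) < bound)

    def test_uniform_rotation_rate(self, cycle_geometry):
        sig = constant_light(48.0)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(), sig,
                                 n_members=1, init="entrained",
                                 record_every=10)
        ph = np.unwrap(ens.phases[:, 0])
        drift = ph - ph[0] - cycle_geometry.omega * (ens.times - ens.times[0])
        assert np.max(np.abs(drift)) < 1e-3

    def test_radial_relaxation_matches_bernoulli_solution(self):
        # tau r' = r - r^3/R^2 from r0 has the closed form
        # r(t) = R / sqrt(1 + ((R/r0)^2 - 1) exp(-2 t / tau))
        g = ClockGeometry.limit_cycle(R=1.0, L=0.0, tau_relax=2.0)
        sig = constant_light(20.0, dt=0.001)
        r0 = 0.1
        init = np.array([[r0, 0.0]])
        ens = integrate_ensemble(g, NoiseSpec(), sig, n_members=1,
                                 init=init, record_every=100)
        r = np.hypot(ens.positions[:, 0, 0], ens.positions[:, 0, 1])
        t = ens.times
        expected = 1.0 / np.sqrt(1.0 + (1.0 / r0**2 - 1.0) * np.exp(-2 * t / 2.0))
        assert np.max(np.abs(r - expected)) < 1e-4

    def test_halving_dt_leaves_phase_unchanged(self, cycle_geometry):
        x0 = entrained_state(cycle_geometry)
        phases = []
        for dt in (0.01, 0.005):
            sig = make_square_wave(t_end=48.0 + dt, dt=dt)
            ens = integrate_ensemble(cycle_geometry, NoiseSpec(), sig,
                                     n_members=1, init=np.array([x0]),
                                     record_every=sig.rho.size - 1)
            phases.append(ens.phases[-1, 0])
        assert abs(phases[0] - phases[1]) < 1e-3

    def test_too_large_step_rejected(self, cycle_geometry):
        sig = make_square_wave(t_end=48.0, dt=0.2)
        with pytest.raises(ValueError):
            integrate_ensemble(cycle_geometry, NoiseSpec(), sig, n_members=1)


class TestDecodePhase:
    def test_cardinal_directions(self, cycle_geometry):
        c = np.array([0.1, 0.0])
        assert decode_phase(c + [1.0, 0.0], 1.0, cycle_geometry) == pytest.approx(0.0)
        assert decode_phase(c + [0.0, 1.0], 1.0, cycle_geometry) == pytest.approx(np.pi / 2)

    def test_rotation_equivariance(self, cycle_geometry, rng):
        c = np.array([0.1, 0.0])
        for _ in range(10):
            phi = rng.uniform(-np.pi, np.pi)
            alpha = rng.uniform(-np.pi, np.pi)
            p0 = c + [np.cos(phi), np.sin(phi)]
            rot = np.array([[np.cos(alpha), -np.sin(alpha)],
                            [np.sin(alpha), np.cos(alpha)]])
            p1 = c + rot @ (p0 - c)
            d = decode_phase(p1, 1.0, cycle_geometry) - decode_phase(p0, 1.0, cycle_geometry)
            assert np.angle(np.exp(1j * (d - alpha))) == pytest.approx(0.0, abs=1e-12)

    def test_center_state_rejected(self, cycle_geometry):
        with pytest.raises(ValueError):
            decode_phase(np.array([0.1, 0.0]), 1.0, cycle_geometry)


class TestEntrainedOrbit:
    def test_point_attractor_dawn_radius_closed_form(self):
        # complex one-period map z -> -e^{-T/tau}(z -+ L) has dawn radius
        # L / (1 - exp(-T_half/tau)) for T_half = tau = 12 h
        for L in (0.05, 0.1, 0.3):
            g = ClockGeometry.point_attractor(L=L)
            x = entrained_state(g)
            r_dawn = np.hypot(x[0] + L, x[1])  # day center at (-L, 0)
            assert r_dawn == pytest.approx(L / (1 - np.exp(-1.0)), rel=5e-3)

    def test_point_reference_radius_near_L(self):
        g = ClockGeometry.point_attractor(L=0.2)
        # mean orbital radius = L * (tau / T_half) for the square drive
        assert reference_radius(g) == pytest.approx(0.2, rel=0.01)

    def test_entrained_state_is_period_map_fixed_point(self, cycle_geometry):
        x0 = entrained_state(cycle_geometry)
        sig = make_square_wave(t_end=24.0 + 0.01, dt=0.01)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(), sig,
                                 n_members=1, init=np.array([x0]),
                                 record_every=sig.rho.size - 1)
        assert np.allclose(ens.positions[-1, 0], x0, atol=1e-6)


class TestStochasticIntegration:
    def test_flat_direction_diffusion_rate(self, cycle_geometry):
        # undriven limit cycle: phase variance grows as eps^2 per hour
        sig = constant_light(50.0, dt=0.01)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(eps_int=0.05, seed=1),
                                 sig, n_members=2000, init="entrained",
                                 record_every=50)
        var = np.unwrap(ens.phases, axis=0).var(axis=1)
        slope = np.polyfit(ens.times, var, 1)[0]
        assert slope == pytest.approx(0.05**2, rel=0.15)

    def test_fairness_equal_rates_across_geometries(self):
        # same eps_int => same undriven phase-diffusion rate, any R
        sig = constant_light(50.0, dt=0.01)
        slopes = []
        for R in (1.0, 2.0):
            g = ClockGeometry.limit_cycle(R=R, L=0.1 * R)
            ens = integrate_ensemble(g, NoiseSpec(eps_int=0.05, seed=2), sig,
                                     n_members=2000, init="entrained",
                                     record_every=50)
            var = np.unwrap(ens.phases, axis=0).var(axis=1)
            slopes.append(np.polyfit(ens.times, var, 1)[0])
        assert slopes[0] == pytest.approx(slopes[1], rel=0.10)

    def test_same_seed_reproducible(self, cycle_geometry):
        sig = make_square_wave(t_end=48.0, dt=0.05)
        a = integrate_ensemble(cycle_geometry, NoiseSpec(eps_int=0.1, seed=3),
                               sig, n_members=20, record_every=10)
        b = integrate_ensemble(cycle_geometry, NoiseSpec(eps_int=0.1, seed=3),
                               sig, n_members=20, record_every=10)
        assert np.array_equal(a.positions, b.positions)


class TestTrajectoryContainer:
    def test_phases_consistent_with_positions(self, cycle_geometry):
        sig = make_square_wave(t_end=48.0, dt=0.05)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(eps_int=0.05, seed=1),
                                 sig, n_members=10, record_every=10)
        ens.validate()

    def test_hdf5_round_trip(self, tmp_path, cycle_geometry):
        sig = make_square_wave(t_end=48.0, dt=0.05)
        ens = integrate_ensemble(cycle_geometry, NoiseSpec(eps_int=0.05, seed=1),
                                 sig, n_members=5, record_every=20)
        path = tmp_path / "ens.h5"
        ens.to_hdf5(path)
        from clocktradeoff.dynamics import EnsembleTrajectory

        back = EnsembleTrajectory.from_hdf5(path)
        assert np.array_equal(back.positions, ens.positions)
        assert back.geometry == ens.geometry
        back.validate()
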