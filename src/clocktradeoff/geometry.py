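"""Geometric theory of entrainment: circle maps, dark-pulse phase shifts,
and steady-state phase-variance laws.

The day and night attractors are circles of radius R whose centers are
separated by the drive displacement L.  Relaxation from one cycle to the
other at dusk/dawn defines a circle map ``phi = P(theta)`` whose slope
``s^{-1} = dP/dtheta`` sets the variance contraction ``sigma^2 ->
sigma^2 / s^2`` at each transition.  Balancing the daytime variance gains
against this contraction gives the steady-state phase variance laws:

* external (weather) noise:  sigma^2 = dPhi^2 / (s^4 - 1), where dPhi is
  the phase lag from a typical dark excursion of the light level;
* internal noise:  sigma^2 = eps_int^2 T / (s^2 - 1) for half-period T;
* point attractors: sigma^2 = eps_int^2 * tau_relax (constant curvature
  1/tau_relax at all times; proportionality constant fixed to 1 here --
  the underlying law is a proportionality).

Combining the two laws yields the optimal geometry
``(L/R)_opt = eps_int / eps_ext`` and the trade-off product
``Q = eps_int^2 * eps_ext^2`` with ``sigma_int^2 * sigma_ext^2 ~ Q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    ClockGeometry,
    decode_phase,
    entrained_state,
    _integrate_positions,
)
from .signals import insert_dark_pulse, make_square_wave

__all__ = [
    "CircleMap",
    "VarianceLedger",
    "circle_map",
    "map_slope",
    "entrained_dusk_phase",
    "dark_pulse_phase_shift",
    "dark_pulse_scan",
    "dark_pulse_bound",
    "external_variance_recursion",
    "internal_variance_recursion",
    "steady_state_variance_external",
    "steady_state_variance_internal",
    "point_attractor_variance",
    "optimal_ratio",
    "tradeoff_product",
]


@dataclass(frozen=True)
class CircleMap:
    """Day-cycle phase ``theta`` to night-cycle phase ``phi = P(theta)``.

    ``phi_values`` are unwrapped so the map is continuous and degree-1:
    P(theta + 2 pi) = P(theta) + 2 pi.  ``monotone`` is False (with a
    warning message) when L >= R makes the radial projection fold back.
    """

    theta_grid: np.ndarray
    phi_values: np.ndarray
    method: str
    monotone: bool = True
    warning: str | None = None

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        # exploit degree-1 periodicity for out-of-grid arguments
        k = np.floor((theta - self.theta_grid[0]) / (2 * np.pi))
        t = theta - 2 * np.pi * k
        return np.interp(t, self.theta_grid, self.phi_values) + 2 * np.pi * k

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.theta_grid, self.phi_values]),
            delimiter=",",
            header="theta,phi",
            comments="",
            fmt="%.17g",
        )


@dataclass(frozen=True)
class VarianceLedger:
    """Phase variance at one stage of the day/dusk/night/dawn cycle."""

    sigma2: float
    stage: str  # day | dusk | night | dawn
    gain: float = 0.0  # additive variance gained in this stage (rad^2)
    s2: float = 1.0  # contraction applied in this stage

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.stage not in ("day", "dusk", "night", "dawn"):
            raise ValueError(f"unknown stage {self.stage!r}")


def _projection_phi(theta: np.ndarray, R: float, L: float) -> np.ndarray:
    """Angle about the night center of the day-cycle point at phase theta."""
    return np.arctan2(R * np.sin(theta), L + R * np.cos(theta))


def circle_map(
    geometry: ClockGeometry,
    method: str = "relaxation_integration",
    n_grid: int = 361,
) -> CircleMap:
    """Map from day-cycle phases to night-cycle phases across dusk.

    ``radial_projection`` projects the day-cycle point radially onto the
    night cycle about the night center.  ``relaxation_integration``
    integrates the noise-free night dynamics from the day-cycle point until
    the radius converges to R (|r - R| < 1e-6 R) and subtracts the elapsed
    uniform rotation.  The two agree because the angular velocity about the
    center is exactly omega at any radius; they are kept as independent
    routes (analytic formula vs numerical integration).
    """
    if geometry.kind != "limit_cycle":
        raise ValueError("circle_map is defined for limit cycles")
    R, L = geometry.R, geometry.L
    theta = np.linspace(-np.pi, np.pi, n_grid)
    if method == "radial_projection":
        phi = np.unwrap(_projection_phi(theta, R, L))
        # anchor the branch: phi(-pi) = -pi exactly for L < R
        phi = phi - 2 * np.pi * np.round((phi[0] + np.pi) / (2 * np.pi))
    elif method == "relaxation_integration":
        phi = _relaxation_map(theta, geometry)
    else:
        raise ValueError(f"unknown circle map method {method!r}")
    warning = None
    monotone = bool(np.all(np.diff(phi) > 0))
    if L >= R:
        monotone = False
        warning = (
            f"L={L} >= R={R}: the day cycle encloses the night center and "
            "the circle map is not monotone"
        )
    return CircleMap(theta_grid=theta, phi_values=phi, method=method,
                     monotone=monotone, warning=warning)


def _relaxation_map(theta: np.ndarray, geometry: ClockGeometry) -> np.ndarray:
    from scipy.integrate import solve_ivp

    R, L = geometry.R, geometry.L

    def rhs(t, u):
        r2 = u[0] * u[0] + u[1] * u[1]
        g = (1.0 - r2 / R**2) / geometry.tau_relax
        return [g * u[0] - geometry.omega * u[1],
                g * u[1] + geometry.omega * u[0]]

    phi = np.empty_like(theta)
    t_max = 40.0 * geometry.tau_relax
    for i, th in enumerate(theta):
        u0 = [L + R * np.cos(th), R * np.sin(th)]
        r0 = np.hypot(*u0)
        if abs(r0 - R) <= 1e-6 * R:
            phi[i] = np.arctan2(u0[1], u0[0])
            continue
        ev = lambda t, u: abs(np.hypot(u[0], u[1]) - R) - 1e-6 * R
        ev.terminal = True
        sol = solve_ivp(rhs, (0.0, t_max), u0, events=ev,
                        rtol=1e-10, atol=1e-12, max_step=0.5)
        t_end = sol.t[-1]
        uf = sol.y[:, -1]
        phi[i] = np.arctan2(uf[1], uf[0]) - geometry.omega * t_end
    phi = np.unwrap(phi)
    phi -= 2 * np.pi * np.round((phi[0] + np.pi) / (2 * np.pi))
    return phi


def map_slope(cmap: CircleMap, theta: float) -> float:
    """Centered finite-difference slope dP/dtheta at ``theta`` (= 1/s).

    Raises for non-positive slopes (no contracting entrainment there).
    """
    if not (cmap.theta_grid[0] <= theta <= cmap.theta_grid[-1]):
        theta = np.angle(np.exp(1j * theta))  # wrap into the grid span
    # differentiate on the stored grid: a folded (non-monotone) map is not
    # degree-1, so the periodic extension cannot be used across the seam
    deriv = np.gradient(cmap.phi_values, cmap.theta_grid)
    slope = float(np.interp(theta, cmap.theta_grid, deriv))
    if slope <= 0:
        raise ValueError(f"circle map is not contracting at theta={theta}")
    return slope


def entrained_dusk_phase(geometry: ClockGeometry, period: float = 24.0,
                         day_fraction: float = 0.5) -> float:
    """Day-cycle phase of the noise-free entrained clock just before dusk.

    The decoded phase advances at exactly omega between the dawn/dusk
    decode jumps, so dusk phase = dawn phase + omega * T_day.
    """
    x0 = entrained_state(geometry, period=period, day_fraction=day_fraction)
    dawn = float(decode_phase(x0, 1.0, geometry))
    return float(np.angle(np.exp(1j * (dawn + geometry.omega * day_fraction * period))))


def dark_pulse_phase_shift(
    geometry: ClockGeometry,
    pulse_start: float = 2.4,
    duration: float = 2.4,
    period: float = 24.0,
    day_fraction: float = 0.5,
    dt: float = 0.01,
) -> float:
    """Phase lag |dPhi| caused by a single daytime dark pulse (rad).

    The noise-free entrained trajectory is integrated over one day with and
    without the pulse; dPhi is the absolute wrapped difference of the
    decoded phases (about the day center) at the dusk immediately following
    the pulse.  Deterministic.

    The default pulse (start 2.4 h, duration 2.4 h) is a representative
    morning pulse.  A pulse centered exactly at mid-day is a degenerate
    timing for this model: the square-wave-entrained orbit is symmetric
    about mid-day, the leading O(L/R) response coefficient
    ``sin(theta_end) - sin(theta_start)`` vanishes there, and dPhi falls
    off faster than the generic (L/R)^1 law.  Any off-node timing shows
    the generic scaling.
    """
    if duration == 0:
        return 0.0
    t_dusk = day_fraction * period
    if not (0.0 <= pulse_start and pulse_start + duration <= t_dusk):
        raise ValueError("dark pulse must lie strictly within the daytime")
    if geometry.L == 0:
        return 0.0
    x0 = entrained_state(geometry, period=period, day_fraction=day_fraction,
                         dt=dt)
    day = make_square_wave(period=period, day_fraction=day_fraction,
                           t_end=t_dusk + dt, dt=dt)
    pulsed = insert_dark_pulse(day, pulse_start, duration)
    record = day.rho.size - 1
    end_clean = _integrate_positions(np.array([x0]), day.rho, dt, geometry,
                                     0.0, None, record)[-1, 0]
    end_pulse = _integrate_positions(np.array([x0]), pulsed.rho, dt, geometry,
                                     0.0, None, record)[-1, 0]
    ph_c = decode_phase(end_clean, 1.0, geometry)
    ph_p = decode_phase(end_pulse, 1.0, geometry)
    return float(abs(np.angle(np.exp(1j * (ph_p - ph_c)))))


def dark_pulse_scan(ratios, pulse_start: float = 2.4, duration: float = 2.4,
                    R: float = 1.0, csv_path=None) -> np.ndarray:
    """|dPhi| of the representative dark pulse across a family of R/L
    ratios; returns an (n, 2) array of (R_over_L, delta_phi) and
    optionally writes it as CSV."""
    out = np.array([
        [r, dark_pulse_phase_shift(
            ClockGeometry.limit_cycle(R=R, L=R / r), pulse_start, duration)]
        for r in np.asarray(ratios, dtype=float)
    ])
    if csv_path is not None:
        np.savetxt(csv_path, out, delimiter=",",
                   header="R_over_L,delta_phi", comments="", fmt="%.17g")
    return out


def dark_pulse_bound(geometry: ClockGeometry) -> float:
    """Geometric upper bound on |dPhi| for limit cycles, any pulse duration.

    The pulsed trajectory leaves the day cycle only through the two decode
    transitions (day->night at pulse onset, night->day at pulse end), each
    of which re-centers the angle by at most arcsin(L/r) with r >= R - 2L.
    """
    if geometry.kind != "limit_cycle":
        raise ValueError("the bound applies to limit cycles")
    R, L = geometry.R, geometry.L
    if L == 0:
        return 0.0
    if R - 2 * L <= L:
        return np.pi  # strongly driven: no useful geometric bound
    return float(2.0 * np.arcsin(L / (R - 2 * L)))


# -- variance recursions and closed forms --------------------------------


def external_variance_recursion(sigma2: float, delta_phi2: float, s2: float) -> float:
    """One full day-night cycle under external noise:
    variance gains dPhi^2 during the day, then contracts by s^2 at dusk and
    again at dawn: sigma^2 -> (sigma^2 + dPhi^2) / s^4.
    """
    return (sigma2 + delta_phi2) / s2**2


def steady_state_variance_external(delta_phi2: float, s2: float) -> float:
    """Fixed point of the external-noise recursion: dPhi^2 / (s^4 - 1)."""
    if s2 <= 1.0:
        raise ValueError("no steady state: need s^2 > 1 (contracting dusk/dawn)")
    return delta_phi2 / (s2**2 - 1.0)


def internal_variance_recursion(sigma2: float, eps2T: float, s2: float) -> float:
    """One full cycle under internal noise (gain eps^2 T each half-cycle,
    contraction s^2 at each transition):
    sigma^2 -> ((sigma^2 + eps^2 T)/s^2 + eps^2 T)/s^2.
    """
    return ((sigma2 + eps2T) / s2 + eps2T) / s2


def steady_state_variance_internal(eps_int2: float, T: float, s2: float) -> float:
    """Fixed point of the internal-noise recursion: eps^2 T / (s^2 - 1).

    Invalid for undriven clocks (s = 1), whose variance grows without
    bound.
    """
    if s2 <= 1.0:
        raise ValueError("no steady state: need s^2 > 1 (undriven clocks dephase)")
    if T <= 0:
        raise ValueError("half-period T must be > 0")
    return eps_int2 * T / (s2 - 1.0)


def variance_cycle_stages(sigma2: float, gain: float, s2: float) -> list[VarianceLedger]:
    """Trace one day/dusk/night/dawn cycle of the variance recursion."""
    out = [VarianceLedger(sigma2 + gain, "day", gain=gain)]
    out.append(VarianceLedger(out[-1].sigma2 / s2, "dusk", s2=s2))
    out.append(VarianceLedger(out[-1].sigma2 + gain, "night", gain=gain))
    out.append(VarianceLedger(out[-1].sigma2 / s2, "dawn", s2=s2))
    return out


def point_attractor_variance(eps_int2: float, tau_relax: float) -> float:
    """Steady-state phase variance of a driven point-attractor clock.

    sigma^2 = eps_int^2 * tau_relax: the constant-curvature (1/tau_relax)
    dynamics confine diffusion at all times.  The underlying law is a
    proportionality; the constant is fixed to 1 here by convention.
    """
    if eps_int2 < 0 or tau_relax <= 0:
        raise ValueError("need eps_int2 >= 0 and tau_relax > 0")
    return eps_int2 * tau_relax


def optimal_ratio(eps_int: float, eps_ext: float) -> float:
    """Optimal drive-to-amplitude ratio (L/R)_opt = eps_int / eps_ext."""
    if eps_int < 0 or eps_ext < 0:
        raise ValueError("noise strengths must be >= 0")
    if eps_ext == 0:
        raise ZeroDivisionError(
            "pure-internal regime: the optimum is L/R -> infinity"
        )
    return eps_int / eps_ext


def tradeoff_product(eps_int: float, eps_ext: float) -> float:
    """Trade-off invariant Q = eps_int^2 * eps_ext^2.

    At fixed Q the product of the internal-only and external-only
    steady-state angular variances is geometry-independent in the scaling
    regime.
    """
    if eps_int < 0 or eps_ext < 0:
        raise ValueError("noise strengths must be >= 0")
    return eps_int**2 * eps_ext**2
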