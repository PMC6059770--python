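"""Clock-quality metrics: mutual information with time of day, circular
variance, and entrainment speed.

A clock is useful insofar as its state tells the cell what time it is.  The
headline precision metric is the mutual information (in bits) between the
time of day, discretized into uniform bins, and the decoded clock phase,
discretized into equal-count bins — estimated from the joint histogram of a
steady-state population, Miller–Madow bias corrected and clipped to the
channel bound ``log2(min(time_bins, phase_bins))``.

Circular variance ``1 - |<e^{i phi}>|`` measures population dispersion on
the circle (0 = coherent, 1 = uniform); for small dispersion it approaches
``sigma^2 / 2``.  Entrainment time measures how fast a phase-uniform
population reaches the steady-state dispersion under driving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .dynamics import (
    ClockGeometry,
    EnsembleTrajectory,
    NoiseSpec,
    integrate_ensemble,
)
from .signals import LightSignal

__all__ = [
    "PrecisionReport",
    "circular_variance",
    "mutual_information",
    "mi_from_samples",
    "circular_variance_by_hour",
    "entrainment_time",
    "precision_report",
]


def circular_variance(phases) -> float:
    """1 - mean resultant length of a set of angles (rad); in [0, 1]."""
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least 2 phases")
    return float(1.0 - np.abs(np.exp(1j * phases).mean()))


def _bin_phases(phases: np.ndarray, n_bins: int, scheme: str) -> np.ndarray:
    if scheme == "quantile":
        # exact equal-count bins by rank (stable under heavy ties, unlike
        # interpolated quantile edges)
        order = np.argsort(phases, kind="stable")
        bins = np.empty(phases.size, dtype=int)
        bins[order] = np.arange(phases.size) * n_bins // phases.size
        return bins
    if scheme == "uniform":
        width = 2.0 * np.pi / n_bins
        return np.clip(((phases + np.pi) / width).astype(int), 0, n_bins - 1)
    raise ValueError(f"unknown phase binning scheme {scheme!r}")


def mi_from_samples(
    time_of_day: np.ndarray,
    phases: np.ndarray,
    time_bins: int = 24,
    phase_bins: int = 24,
    period: float = 24.0,
    phase_binning: str = "quantile",
    bias_correction: bool = True,
    min_per_time_bin: int = 10,
) -> float:
    """Plug-in mutual information (bits) between binned time of day and
    binned phase.

    Time of day is discretized uniformly over one period; phases by
    equal-count (default) or uniform bins.  The Miller–Madow correction
    ``(m_t + m_p - m_joint - 1) / (2 N ln 2)`` (m = occupied bins) offsets
    the plug-in estimator's downward bias; the result is clipped to
    ``[0, log2(min(time_bins, phase_bins))]``, the exact channel bound.
    """
    if time_bins < 2 or phase_bins < 2:
        raise ValueError("need at least 2 bins on each axis")
    t = np.asarray(time_of_day, dtype=float).ravel()
    p = np.asarray(phases, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError("time and phase samples must align")
    ti = np.clip((np.mod(t, period) / period * time_bins).astype(int),
                 0, time_bins - 1)
    t_counts = np.bincount(ti, minlength=time_bins)
    if t_counts.min() < min_per_time_bin:
        raise ValueError(
            f"insufficient sampling: a time bin has {t_counts.min()} "
            f"samples (< {min_per_time_bin})"
        )
    pi_ = _bin_phases(p, phase_bins, phase_binning)
    joint = np.bincount(ti * phase_bins + pi_, minlength=time_bins * phase_bins)
    joint = joint.reshape(time_bins, phase_bins).astype(float)
    n = joint.sum()
    pj = joint / n
    pt = pj.sum(axis=1, keepdims=True)
    pp = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    mi = float(np.sum(pj[nz] * np.log2(pj[nz] / (pt @ pp)[nz])))
    if bias_correction:
        m_joint = int(np.count_nonzero(joint))
        m_t = int(np.count_nonzero(pt))
        m_p = int(np.count_nonzero(pp))
        mi += (m_t + m_p - m_joint - 1) / (2.0 * n * np.log(2.0))
    return float(np.clip(mi, 0.0, np.log2(min(time_bins, phase_bins))))


def mutual_information(
    ensemble: EnsembleTrajectory,
    time_bins: int = 24,
    phase_bins: int = 24,
    discard_hours: float = 240.0,
    **kwargs,
) -> float:
    """Mutual information (bits) between time of day and decoded phase for
    a steady-state population.

    The first ``discard_hours`` of the trajectory are dropped as
    entrainment transient; the remainder must cover at least 5 full
    periods.  See :func:`mi_from_samples` for estimator details.
    """
    period = ensemble.period
    times = ensemble.times
    t0 = times[0] + discard_hours
    span = times[-1] - t0
    if span < 5 * period - 1e-9:
        raise ValueError("need >= 5 full periods at steady state for MI")
    # whole periods only: a partial trailing day would unbalance the
    # time-of-day sample counts (and with them the equal-count phase bins)
    n_periods = int(np.floor(span / period + 1e-9))
    sel = (times >= t0) & (times < t0 + n_periods * period - 1e-9)
    t = np.broadcast_to(times[sel, None], ensemble.phases[sel].shape).ravel()
    return mi_from_samples(
        t, ensemble.phases[sel].ravel(), time_bins=time_bins,
        phase_bins=phase_bins, period=period, **kwargs,
    )


def circular_variance_by_hour(
    ensemble: EnsembleTrajectory,
    time_bins: int = 24,
    discard_hours: float = 240.0,
) -> np.ndarray:
    """Population circular variance per time-of-day bin (steady state)."""
    period = ensemble.period
    sel = ensemble.times >= ensemble.times[0] + discard_hours
    t = np.mod(ensemble.times[sel], period)
    ti = np.clip((t / period * time_bins).astype(int), 0, time_bins - 1)
    out = np.empty(time_bins)
    out.fill(np.nan)
    for k in range(time_bins):
        ph = ensemble.phases[sel][ti == k]
        if ph.size >= 2:
            out[k] = circular_variance(ph)
    return out


@dataclass
class PrecisionReport:
    """Summary of a clock's timekeeping quality."""

    mutual_information: float
    circular_variance_by_hour: np.ndarray
    entrainment_time: float  # hours; inf = not attained
    n_members: int
    n_days: float
    bin_counts: tuple[int, int] = (24, 24)
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        d = {
            "mutual_information_bits": self.mutual_information,
            "circular_variance_by_hour": list(map(float, self.circular_variance_by_hour)),
            "entrainment_time_h": None if np.isinf(self.entrainment_time)
            else self.entrainment_time,
            "n_members": self.n_members,
            "n_days": self.n_days,
            "bin_counts": list(self.bin_counts),
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    def variance_table_csv(self, path) -> None:
        tb = self.circular_variance_by_hour.size
        arr = np.column_stack([np.arange(tb), self.circular_variance_by_hour])
        np.savetxt(path, arr, delimiter=",", header="hour_bin,circular_variance",
                   comments="", fmt="%.17g")


def _dawn_indices(times: np.ndarray, period: float) -> np.ndarray:
    """Indices of the first sample of each period (the dawns)."""
    day = np.floor((times - times[0]) / period + 1e-9).astype(int)
    return np.searchsorted(day, np.arange(day[-1] + 1), side="left")


def entrainment_time(
    geometry: ClockGeometry,
    noise: NoiseSpec,
    signal: LightSignal,
    tolerance: float = 0.1,
    n_members: int = 300,
    max_days: int = 200,
    consecutive: int = 3,
    atol: float = 1e-4,
    record_every: int = 20,
    init="uniform_phase",
    rho_matrix: np.ndarray | None = None,
) -> float:
    """Hours for a phase-uniform population to reach steady-state dispersion.

    Two ensembles run on the *same* drive (``signal``, optionally a
    per-member ``rho_matrix`` of weather realizations): a reference started
    from the entrained state (its dawn-by-dawn circular variance is the
    steady state, tracking any slow weather variation) and a test ensemble
    started from ``init`` (default: phases uniform on the attractor).
    Entrainment is attained at the first dawn where the test circular
    variance is within ``tolerance`` (relative, plus ``atol``) of the
    reference and stays so for ``consecutive`` dawns.  Returns ``inf`` when
    not attained within the signal span or ``max_days``.
    """
    ref = integrate_ensemble(geometry, noise, signal, n_members=n_members,
                             init="entrained", record_every=record_every,
                             rho_matrix=rho_matrix)
    test_noise = NoiseSpec(eps_int=noise.eps_int,
                           seed=noise.seed + 7_654_321)
    test = integrate_ensemble(geometry, test_noise, signal,
                              n_members=n_members, init=init,
                              record_every=record_every,
                              rho_matrix=rho_matrix)
    period = signal.period
    dawns = _dawn_indices(ref.times, period)
    dawns = dawns[ref.times[dawns] <= max_days * period + 1e-9]
    cv_ref = np.array([circular_variance(ref.phases[i]) for i in dawns])
    cv_test = np.array([circular_variance(test.phases[i]) for i in dawns])
    ok = cv_test <= cv_ref * (1.0 + tolerance) + atol
    run = 0
    for k, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= consecutive:
            first = k - consecutive + 1
            return float(ref.times[dawns[first]] - ref.times[dawns[0]])
    return float("inf")


def precision_report(
    ensemble: EnsembleTrajectory,
    time_bins: int = 24,
    phase_bins: int = 24,
    discard_hours: float = 240.0,
    entrainment_time_h: float = float("nan"),
) -> PrecisionReport:
    """Bundle MI, per-hour dispersion and bookkeeping for one ensemble."""
    mi = mutual_information(ensemble, time_bins, phase_bins,
                            discard_hours=discard_hours)
    cv = circular_variance_by_hour(ensemble, time_bins, discard_hours)
    span_days = (ensemble.times[-1] - ensemble.times[0]) / ensemble.period
    return PrecisionReport(
        mutual_information=mi,
        circular_variance_by_hour=cv,
        entrainment_time=entrainment_time_h,
        n_members=ensemble.n_members,
        n_days=float(span_days),
        bin_counts=(time_bins, phase_bins),
    )
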