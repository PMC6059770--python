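"""Synthetic day-night light signals.

The external drive is a normalized light intensity rho(t) in [0, 1] on a
uniform time grid: a clean square wave of period 24 h (dawn at t = 0, dusk
at ``day_fraction * period``), optionally degraded by weather-style daytime
amplitude fluctuations and by discrete dark pulses (clouds blotting out the
sun for a few hours).

The weather model has two ingredients:

* a stationary, mean-one lognormal amplitude-modulating process with
  standard deviation ``eps_ext`` and an Ornstein-Uhlenbeck exponent of
  correlation time ``correlation_time`` (broad-band fluctuations), applied
  multiplicatively to daytime samples and clipped to [0, 1];
* Poisson-arrival dark pulses of exponentially distributed duration during
  which rho is forced to 0.

``eps_ext`` is the dimensionless fractional strength of the amplitude
fluctuations; it is the external-noise knob used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LightSignal",
    "WeatherModel",
    "make_square_wave",
    "add_weather_noise",
    "weather_realizations",
    "insert_dark_pulse",
    "signal_spectrum",
    "weather_modulator",
]

_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class LightSignal:
    """A normalized light signal rho(t) on a strictly uniform time grid.

    Attributes
    ----------
    times : ndarray
        Time points in hours, strictly increasing, uniformly spaced.
    rho : ndarray
        Normalized light intensity in [0, 1], one value per time point.
    period : float
        Drive period in hours (default 24).
    day_fraction : float
        Fraction of the period that is day (default 0.5).
    seed : int or None
        RNG seed of the noise realization; None for deterministic signals.
    """

    times: np.ndarray
    rho: np.ndarray
    period: float = 24.0
    day_fraction: float = 0.5
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-d grid with at least 2 points")
        if rho.shape != times.shape:
            raise ValueError("rho and times must have the same shape")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > _GRID_RTOL * max(abs(dt), 1.0)):
            raise ValueError("times must be uniformly spaced")
        if rho.min() < 0.0 or rho.max() > 1.0:
            raise ValueError("rho values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rho", rho)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def is_clean(self) -> bool:
        """True when rho takes only the values {0, 1} and no noise was added."""
        if self.meta.get("noisy", False):
            return False
        vals = np.unique(self.rho)
        return bool(np.all((vals == 0.0) | (vals == 1.0)))

    def rho_at(self, t: float | np.ndarray) -> np.ndarray:
        """rho at arbitrary times, previous-grid-point (zero-order) hold."""
        idx = np.clip(
            np.floor((np.asarray(t) - self.times[0]) / self.dt + 1e-12).astype(int),
            0,
            self.times.size - 1,
        )
        return self.rho[idx]

    # -- serialization ---------------------------------------------------

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.rho])
        header = "time_h,rho"
        np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def from_csv(cls, path, period: float = 24.0, day_fraction: float = 0.5) -> "LightSignal":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(times=arr[:, 0], rho=arr[:, 1], period=period, day_fraction=day_fraction)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            rho=self.rho,
            period=self.period,
            day_fraction=self.day_fraction,
            seed=-1 if self.seed is None else self.seed,
            noisy=bool(self.meta.get("noisy", False)),
        )

    @classmethod
    def from_npz(cls, path) -> "LightSignal":
        with np.load(path) as data:
            seed = int(data["seed"])
            return cls(
                times=data["times"],
                rho=data["rho"],
                period=float(data["period"]),
                day_fraction=float(data["day_fraction"]),
                seed=None if seed < 0 else seed,
                meta={"noisy": bool(data["noisy"])},
            )


@dataclass(frozen=True)
class WeatherModel:
    """Statistical model of daytime weather degradation of the light signal.

    Parameters
    ----------
    eps_ext : float
        Standard deviation of the fractional daytime amplitude fluctuations
        (dimensionless). 0 disables amplitude noise.
    correlation_time : float
        Correlation time of the amplitude-modulating process, hours.
    pulse_rate : float
        Expected number of dark pulses per day (Poisson arrivals).
    pulse_duration_mean : float
        Mean dark-pulse duration, hours (exponential distribution).
    """

    eps_ext: float = 0.3
    correlation_time: float = 2.0
    pulse_rate: float = 1.0
    pulse_duration_mean: float = 2.4

    def __post_init__(self):
        if self.eps_ext < 0:
            raise ValueError("eps_ext must be >= 0")
        if self.correlation_time <= 0:
            raise ValueError("correlation_time must be > 0")
        if self.pulse_rate < 0 or self.pulse_duration_mean < 0:
            raise ValueError("pulse_rate and pulse_duration_mean must be >= 0")


def make_square_wave(
    period: float = 24.0,
    day_fraction: float = 0.5,
    t_end: float = 240.0,
    dt: float = 0.01,
) -> LightSignal:
    """Clean square-wave drive: rho = 1 during the day, 0 at night.

    Dawn is at t = 0 (mod period); dusk at ``day_fraction * period``.
    The grid spans [0, t_end) with spacing dt.
    """
    if period <= 0 or dt <= 0:
        raise ValueError("period and dt must be positive")
    if not 0 < day_fraction < 1:
        raise ValueError("day_fraction must be in (0, 1)")
    if dt >= period / 10:
        raise ValueError("dt must resolve the period (dt < period/10)")
    n = int(round(t_end / dt))
    times = np.arange(n) * dt
    phase = np.mod(times, period)
    # half-open [dawn, dusk) day interval; tolerance guards grid round-off
    rho = (phase < day_fraction * period - 1e-12).astype(float)
    return LightSignal(times=times, rho=rho, period=period, day_fraction=day_fraction)


def weather_modulator(n: int, dt: float, weather: WeatherModel, seed: int) -> np.ndarray:
    """Stationary mean-1 lognormal amplitude modulation, sd ``eps_ext``.

    The log-amplitude follows an exact discretized Ornstein-Uhlenbeck process
    with correlation time ``weather.correlation_time``, so the modulation is
    broad-band below 1/correlation_time.  Returned before any clipping, for
    direct inspection of the configured moments.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    if weather.eps_ext == 0:
        return np.ones(n)
    # lognormal with mean 1 and sd eps_ext: sigma_ln^2 = ln(1 + eps^2)
    sigma_ln = np.sqrt(np.log1p(weather.eps_ext**2))
    a = np.exp(-dt / weather.correlation_time)
    b = sigma_ln * np.sqrt(1.0 - a * a)
    x0 = sigma_ln * rng.standard_normal()  # stationary start
    z = rng.standard_normal(n)
    # exact AR(1) recursion x[i] = a x[i-1] + b z[i], x[-1] = x0
    x, _ = lfilter([b], [1.0, -a], z, zi=np.array([a * x0]))
    return np.exp(x - 0.5 * sigma_ln**2)


def _apply_weather(rho_clean: np.ndarray, times: np.ndarray, dt: float,
                   weather: WeatherModel, seed) -> np.ndarray:
    """One weather realization applied to a clean rho series."""
    rho = rho_clean.copy()
    day = rho > 0
    mod = weather_modulator(times.size, dt, weather, seed)
    rho[day] = np.clip(rho[day] * mod[day], 0.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD42C]))
    if weather.pulse_rate > 0 and weather.pulse_duration_mean > 0:
        span_days = (times[-1] - times[0]) / 24.0
        n_pulses = rng.poisson(weather.pulse_rate * span_days)
        starts = np.sort(rng.uniform(times[0], times[-1], n_pulses))
        durations = rng.exponential(weather.pulse_duration_mean, n_pulses)
        for s, d in zip(starts, durations):
            rho[(times >= s) & (times < s + d)] = 0.0
    return rho


def weather_realizations(signal: LightSignal, weather: WeatherModel,
                         n_members: int, seed: int) -> np.ndarray:
    """Independent weather realizations per population member.

    Returns an array of shape (n_times, n_members): column j is the clean
    signal degraded by an independent draw of the weather process.  This is
    the drive used for external-noise ensembles — each clock in the
    population experiences its own weather history, while the underlying
    square-wave skeleton (dawn/dusk times) is shared.
    """
    if not signal.is_clean:
        raise ValueError("weather noise can only be applied to a clean signal")
    ss = np.random.SeedSequence(seed)
    out = np.empty((signal.times.size, n_members))
    for j, child in enumerate(ss.spawn(n_members)):
        member_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        out[:, j] = _apply_weather(signal.rho, signal.times, signal.dt,
                                   weather, member_seed)
    return out


def add_weather_noise(signal: LightSignal, weather: WeatherModel, seed: int) -> LightSignal:
    """Apply daytime amplitude fluctuations and dark pulses to a clean signal.

    Daytime samples are multiplied by the mean-1 modulating process and
    clipped to [0, 1]; nighttime samples stay 0.  Dark pulses arrive as a
    Poisson process (``pulse_rate`` per day) with exponential durations and
    force rho to 0.  Identical (signal, weather, seed) gives bit-identical
    output.  Applying weather twice is an error.
    """
    if not signal.is_clean:
        raise ValueError("weather noise can only be applied to a clean signal")
    if seed is None:
        raise ValueError("a seed is required for weather noise")
    rho = _apply_weather(signal.rho, signal.times, signal.dt, weather, seed)
    meta = dict(signal.meta)
    meta["noisy"] = True
    meta["weather"] = weather
    return replace(signal, rho=rho, seed=seed, meta=meta)


def insert_dark_pulse(signal: LightSignal, start: float, duration: float) -> LightSignal:
    """Force rho = 0 on [start, start + duration); unchanged elsewhere."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return signal
    if start < signal.times[0] or start + duration > signal.t_end + signal.dt:
        raise ValueError("dark pulse must lie within the signal span")
    rho = signal.rho.copy()
    mask = (signal.times >= start - 1e-12) & (signal.times < start + duration - 1e-12)
    rho[mask] = 0.0
    meta = dict(signal.meta)
    meta.setdefault("dark_pulses", []).append((float(start), float(duration)))
    return replace(signal, rho=rho, meta=meta)


def signal_spectrum(signal: LightSignal) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of rho; returns (frequencies in 1/h, power)."""
    from scipy.signal import periodogram

    freqs, power = periodogram(signal.rho, fs=1.0 / signal.dt, detrend=False)
    return freqs, power
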