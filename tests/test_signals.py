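"""Synthetic light-signal generation: square waves, weather, dark pulses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clocktradeoff.signals import (
    LightSignal,
    WeatherModel,
    add_weather_noise,
    insert_dark_pulse,
    make_square_wave,
    signal_spectrum,
    weather_modulator,
    weather_realizations,
)


class TestSquareWave:
    def test_day_and_night_values(self):
        sig = make_square_wave(period=24, day_fraction=0.5, t_end=48, dt=0.01)
        assert sig.rho_at(6.0) == 1.0   # mid-day
        assert sig.rho_at(18.0) == 0.0  # mid-night
        assert set(np.unique(sig.rho)) == {0.0, 1.0}

    def test_exact_periodicity(self):
        sig = make_square_wave(period=24, day_fraction=0.5, t_end=96, dt=0.02)
        n_period = int(round(24 / 0.02))
        assert np.array_equal(sig.rho[:-n_period], sig.rho[n_period:])

    @pytest.mark.parametrize("kwargs", [
        dict(period=-24), dict(dt=-0.01), dict(day_fraction=0.0),
        dict(day_fraction=1.0), dict(dt=3.0),
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_square_wave(**{**dict(period=24.0, day_fraction=0.5,
                                       t_end=48.0, dt=0.01), **kwargs})

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(ValueError):
            LightSignal(times=t, rho=np.zeros(4))


class TestDarkPulse:
    def test_zero_duration_is_identity(self, clean_signal_short):
        out = insert_dark_pulse(clean_signal_short, 4.8, 0.0)
        assert np.array_equal(out.rho, clean_signal_short.rho)

    def test_pulse_zeroes_midday_and_nothing_else(self, clean_signal_short):
        out = insert_dark_pulse(clean_signal_short, 4.8, 2.4)
        assert out.rho_at(6.0) == 0.0       # inside the pulse
        assert out.rho_at(7.3) == 1.0       # just after pulse end (7.2)
        assert out.rho_at(4.7) == 1.0       # just before pulse start
        # unchanged outside [4.8, 7.2)
        mask = (clean_signal_short.times < 4.8) | (clean_signal_short.times >= 7.2)
        assert np.array_equal(out.rho[mask], clean_signal_short.rho[mask])

    def test_pulse_outside_span_rejected(self, clean_signal_short):
        with pytest.raises(ValueError):
            insert_dark_pulse(clean_signal_short, 118.0, 5.0)


class TestWeather:
    def test_zero_noise_is_bit_exact_identity(self, clean_signal_short):
        w = WeatherModel(eps_ext=0.0, pulse_rate=0.0)
        out = add_weather_noise(clean_signal_short, w, seed=1)
        assert np.array_equal(out.rho, clean_signal_short.rho)

    def test_modulator_matches_configured_moments(self):
        w = WeatherModel(eps_ext=0.3)
        mod = weather_modulator(200_000, 0.05, w, seed=7)
        assert mod.std() == pytest.approx(0.3, abs=0.02)
        assert mod.mean() == pytest.approx(1.0, abs=0.02)
        assert np.all(mod > 0)

    def test_noisy_rho_stays_in_unit_interval_and_night_dark(self, clean_signal_short):
        w = WeatherModel(eps_ext=0.5, pulse_rate=1.0)
        out = add_weather_noise(clean_signal_short, w, seed=3)
        assert out.rho.min() >= 0.0 and out.rho.max() <= 1.0
        night = clean_signal_short.rho == 0.0
        assert np.all(out.rho[night] == 0.0)

    def test_mean_daytime_intensity_biased_down_but_bounded(self, clean_signal_short):
        # clipping at 1 only removes light: mean in [1 - 2 eps, 1]
        for eps in (0.1, 0.2, 0.3):
            w = WeatherModel(eps_ext=eps, pulse_rate=0.0)
            out = add_weather_noise(clean_signal_short, w, seed=11)
            day = clean_signal_short.rho == 1.0
            m = out.rho[day].mean()
            assert 1.0 - 2.0 * eps <= m <= 1.0

    def test_same_seed_bit_identical(self, clean_signal_short):
        w = WeatherModel(eps_ext=0.3, pulse_rate=1.0)
        a = add_weather_noise(clean_signal_short, w, seed=5)
        b = add_weather_noise(clean_signal_short, w, seed=5)
        assert np.array_equal(a.rho, b.rho)
        c = add_weather_noise(clean_signal_short, w, seed=6)
        assert not np.array_equal(a.rho, c.rho)

    def test_double_application_forbidden(self, clean_signal_short):
        w = WeatherModel(eps_ext=0.3)
        noisy = add_weather_noise(clean_signal_short, w, seed=1)
        with pytest.raises(ValueError):
            add_weather_noise(noisy, w, seed=2)

    def test_per_member_realizations_are_independent(self, clean_signal_short):
        w = WeatherModel(eps_ext=0.3, pulse_rate=0.0)
        mat = weather_realizations(clean_signal_short, w, 4, seed=9)
        assert mat.shape == (clean_signal_short.times.size, 4)
        day = clean_signal_short.rho == 1.0
        for i in range(3):
            assert not np.array_equal(mat[day, i], mat[day, i + 1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(eps=st.floats(0.0, 0.6), seed=st.integers(0, 10_000))
    def test_output_always_valid_signal(self, eps, seed):
        sig = make_square_wave(t_end=48.0, dt=0.05)
        w = WeatherModel(eps_ext=eps)
        out = add_weather_noise(sig, w, seed=seed)
        assert out.rho.min() >= 0.0 and out.rho.max() <= 1.0
        assert np.allclose(np.diff(out.times), 0.05)


class TestSpectrum:
    def test_constant_signal_power_is_dc_only(self):
        sig = make_square_wave(t_end=96.0, dt=0.05)
        const = LightSignal(times=sig.times, rho=np.ones_like(sig.rho))
        freqs, power = signal_spectrum(const)
        assert power.size == sig.rho.size // 2 + 1
        assert np.argmax(power) == 0
        assert power[1:].max() < 1e-20 * power[0]

    def test_square_wave_fundamental_at_one_over_24(self):
        sig = make_square_wave(t_end=30 * 24.0, dt=0.05)
        freqs, power = signal_spectrum(sig)
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(1.0 / 24.0, rel=0.01)

    def test_weather_adds_broadband_power(self):
        sig = make_square_wave(t_end=30 * 24.0, dt=0.05)
        noisy = add_weather_noise(
            sig, WeatherModel(eps_ext=0.3, correlation_time=2.0,
                              pulse_rate=0.0), seed=2)
        f_c, p_c = signal_spectrum(sig)
        f_n, p_n = signal_spectrum(noisy)
        # continuum power between the square wave's harmonic lines,
        # over periods 1-10 h
        off_harmonic = np.abs(f_c * 24.0 - np.round(f_c * 24.0)) > 0.25
        band = (f_c >= 0.1) & (f_c <= 1.0) & off_harmonic
        assert p_n[band].sum() > 10.0 * p_c[band].sum()


class TestSerialization:
    def test_csv_round_trip_lossless(self, tmp_path, clean_signal_short):
        w = WeatherModel(eps_ext=0.3)
        noisy = add_weather_noise(clean_signal_short, w, seed=1)
        path = tmp_path / "sig.csv"
        noisy.to_csv(path)
        back = LightSignal.from_csv(path)
        assert np.allclose(back.rho, noisy.rho, atol=1e-12)
        assert np.allclose(back.times, noisy.times, atol=1e-12)

    def test_npz_round_trip_lossless(self, tmp_path, clean_signal_short):
        path = tmp_path / "sig.npz"
        clean_signal_short.to_npz(path)
        back = LightSignal.from_npz(path)
        assert np.array_equal(back.rho, clean_signal_short.rho)
        assert back.period == clean_signal_short.period
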