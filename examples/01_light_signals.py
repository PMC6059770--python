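"""Build the external drive: a clean day-night square wave, weather
degradation, and a single dark pulse.

The drive rho(t) in [0, 1] is what every clock in this package sees.
Weather multiplies daytime light by a broad-band mean-1 process of
standard deviation eps_ext and blots out stretches with Poisson dark
pulses; both only ever remove light.
"""

import numpy as np

from clocktradeoff import (
    WeatherModel,
    add_weather_noise,
    insert_dark_pulse,
    make_square_wave,
    signal_spectrum,
)

signal = make_square_wave(period=24.0, day_fraction=0.5, t_end=10 * 24.0,
                          dt=0.05)
print(f"clean signal: {signal.times.size} samples, "
      f"rho(6 h) = {signal.rho_at(6.0):.0f} (day), "
      f"rho(18 h) = {signal.rho_at(18.0):.0f} (night)")

weather = WeatherModel(eps_ext=0.3, correlation_time=2.0,
                       pulse_rate=1.0, pulse_duration_mean=2.4)
noisy = add_weather_noise(signal, weather, seed=1)
day = signal.rho == 1.0
print(f"weather (eps_ext = {weather.eps_ext}): mean daytime intensity "
      f"{noisy.rho[day].mean():.3f} (clipping only removes light), "
      f"{(noisy.rho[day] == 0).mean():.1%} of daytime fully dark (pulses)")

pulsed = insert_dark_pulse(signal, start=4.8, duration=2.4)
print(f"dark pulse 4.8-7.2 h: rho(6 h) = {pulsed.rho_at(6.0):.0f}, "
      f"rho(7.3 h) = {pulsed.rho_at(7.3):.0f}")

freqs, power = signal_spectrum(noisy)
f_c, p_c = signal_spectrum(signal)
# continuum between the square wave's harmonic lines, periods 1-10 h
band = ((freqs >= 0.1) & (freqs <= 1.0)
        & (np.abs(freqs * 24 - np.round(freqs * 24)) > 0.25))
print("spectral continuum at 1-10 h periods: "
      f"{p_c[band].sum():.2e} (clean: pure harmonic lines) vs "
      f"{power[band].sum():.2f} with weather (broad-band fluctuations)")
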