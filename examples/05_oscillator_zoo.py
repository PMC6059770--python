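"""Generality beyond the minimal model: drive classic biochemical
oscillators (Goodwin cascade here; Brusselator and repressilator are in
the library too) through their Hopf bifurcation and measure precision in
three regimes.

`damped` sits below the Hopf point (an hourglass), `small_cycle` and
`large_cycle` above it with free-running amplitudes ~0.5x and several
times the drive-induced displacement.
"""

from clocktradeoff.signals import WeatherModel, make_square_wave, weather_realizations
from clocktradeoff.zoo import hopf_locate, model_library, precision_vs_internal_noise

lib = model_library()
print("Hopf points:",
      {name: round(hopf_locate(m), 4) for name, m in lib.items()})
print("(Brusselator: analytic b_c = 1 + a^2 = 2)\n")

signal = make_square_wave(t_end=20 * 24.0 + 0.05, dt=0.05)
weather = WeatherModel(eps_ext=0.3, correlation_time=2.0,
                       pulse_rate=1.0, pulse_duration_mean=2.4)
rho = weather_realizations(signal, weather, n_members=150, seed=11)

df = precision_vs_internal_noise(lib["goodwin"], [0.01, 0.1, 0.4], signal,
                                 n_members=150, seed=1, rho_matrix=rho)
print("Goodwin oscillator, MI (bits) vs internal noise:")
print(df.pivot(index="eps_int", columns="regime", values="MI_bits").round(3))
print("\nlarge_cycle wins at low internal noise (external-noise filtering),")
print("damped wins at high internal noise — the same trade-off as the")
print("minimal geometric model.")
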