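"""The central trade-off: sweep internal noise at fixed weather and watch
the free-running clock and the hourglass clock swap places.

Every population member experiences its own weather realization; the
precision is the mutual information (bits) between the decoded clock
phase and the time of day.
"""

import numpy as np

from clocktradeoff import (
    ClockGeometry,
    NoiseSpec,
    WeatherModel,
    integrate_ensemble,
    make_square_wave,
    mutual_information,
    weather_realizations,
)

signal = make_square_wave(t_end=30 * 24.0 + 0.05, dt=0.05)
weather = WeatherModel(eps_ext=0.3, correlation_time=2.0,
                       pulse_rate=1.0, pulse_duration_mean=2.4)
rho = weather_realizations(signal, weather, n_members=200, seed=5)

cycle = ClockGeometry.limit_cycle(R=1.0, L=0.05)   # weakly driven cycle
point = ClockGeometry.point_attractor(L=0.1)       # hourglass

print("eps_int   MI(limit cycle)   MI(point attractor)")
for eps in (0.01, 0.03, 0.1, 0.3):
    mis = {}
    for name, g in (("cycle", cycle), ("point", point)):
        ens = integrate_ensemble(g, NoiseSpec(eps_int=eps, seed=3), signal,
                                 n_members=200, record_every=10,
                                 rho_matrix=rho)
        mis[name] = mutual_information(ens, discard_hours=240.0)
    tag = "cycle wins" if mis["cycle"] > mis["point"] else "point wins"
    print(f"{eps:7.2f}   {mis['cycle']:15.3f}   {mis['point']:19.3f}   {tag}")

print("\nLow internal noise: the limit cycle's flat direction filters the")
print("weather.  High internal noise: the same flat direction accumulates")
print("diffusion, and the hourglass clock keeps better time.")
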