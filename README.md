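# clocktradeoff

Why do some organisms keep time with self-sustained ("free-running")
circadian oscillators while others make do with damped "hourglass"
clocks that simply relax between a day state and a night state?
`clocktradeoff` implements a dynamical-systems answer: the two
architectures sit at opposite ends of a trade-off between **external
noise** (weather-driven fluctuations of the light input) and **internal
noise** (stochasticity of the clock's own biochemistry, e.g. low protein
copy number). It is a library for researchers in systems biology and
nonlinear dynamics who want to simulate, measure and extend that
trade-off.

## The models and the theory

A minimal driven clock lives in a plane and rotates at ω = 2π/24 rad/h
about an attractor whose position follows the normalized light level
ρ(t) ∈ [0, 1]:

* **limit cycle** — τ_relax·ṙ = r − r³/R², θ̇ = ω, about a center at
  (ρ(t)·L, 0): a free-running rhythm of amplitude R, shifted a distance
  L between day and night;
* **point attractor** — ṙ = −r/τ_relax, θ̇ = ω, about (−ρ(t)·L, 0): an
  hourglass whose amplitude is set entirely by the drive
  (τ_relax = 12 h ≈ half the period).

Internal noise is isotropic Langevin forcing of angular strength ε_int
(phase variance grows as ε_int²·t on a flat direction; ε_int² ∝ 1/N for
copy number N). External noise is a weather model: broad-band mean-1
amplitude fluctuations of strength ε_ext plus Poisson dark pulses.

The entrainment theory is geometric. Dusk relaxation defines a circle
map φ = P(θ) between the day and night cycles whose slope s⁻¹ = dP/dθ
contracts phase variance (σ² → σ²/s², with s² − 1 ≈ 2L/R), while a dark
pulse of fixed duration produces a phase lag ΔΦ ∝ L/R (free fall, order
one, for the point attractor). Balancing gains and contractions over
the day/dusk/night/dawn cycle gives

    σ²_ext = ΔΦ² / (s⁴ − 1),      σ²_int = ε_int²·T / (s² − 1),

so weak driving (small L/R) filters external noise but accumulates
internal noise, strong driving the reverse, with the optimum at
(L/R)* ∝ ε_int/ε_ext and the trade-off product Q = ε_int²·ε_ext².
Clock precision is measured as the mutual information (bits) between
the decoded clock phase and the time of day across a population.
The same trade-off is demonstrated in driven literature oscillators
(Brusselator, Goodwin, repressilator) carried through their Hopf
bifurcations.

## Worked example

`examples/03_precision_tradeoff.py` sweeps internal noise at fixed
weather (ε_ext = 0.3 plus one ~2.4-h dark pulse per day, each of 200
population members drawing its own weather realization) and prints:

```
eps_int   MI(limit cycle)   MI(point attractor)
   0.01             3.276                 2.710   cycle wins
   0.03             2.030                 2.527   point wins
   0.10             0.242                 1.757   point wins
   0.30             0.003                 0.555   point wins
```

At low internal noise the weakly driven limit cycle (L/R = 0.05) tells
time better — its circular attractor absorbs the weather, and a 2.4-h
dark pulse costs it only ~8 minutes of phase against ~2.2 hours for the
hourglass (`examples/02_geometry_theory.py`). As internal noise grows,
diffusion along the cycle's flat phase direction erodes its precision
while the point attractor's uniformly contracting dynamics confine it,
and the ordering flips — the trade-off in one table. The other example
scripts build the light signals, evaluate the geometric theory
(including the (R/L)⁻² dark-pulse scaling), run configured sweep
experiments, and reproduce the trade-off in the Goodwin oscillator.

Sweep experiments are also exposed through a small CLI:

```bash
clocktradeoff list-experiments
clocktradeoff run --config sweep.yaml --out results/ --seed 1
```

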