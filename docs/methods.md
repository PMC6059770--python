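# Methods

`clocktradeoff` studies a single question with a family of minimal models:
when is a self-sustained (limit-cycle) circadian clock a better timekeeper
than a damped "hourglass" clock, given that real clocks face both
**external noise** (weather-driven fluctuations of the light input) and
**internal noise** (stochasticity of the clock's own biochemistry, e.g.
finite protein copy number)?

## The minimal driven-clock models

Both architectures live in a plane and rotate at angular speed
ω = 2π/24 rad/h about an attractor whose position tracks the normalized
light level ρ(t) ∈ [0, 1]:

* **Limit cycle** (free-running clock): radial dynamics
  τ_relax ṙ = r − r³/R² about a center at (ρ(t)·L, 0). The attracting
  orbit has fixed amplitude R; the tangential ("flat") direction neither
  grows nor shrinks perturbations. R is the free-running amplitude, L the
  day–night displacement of the cycle, so L/R measures drive strength
  relative to the clock's own rhythm.
* **Point attractor** (damped clock): ṙ = −r/τ_relax, θ̇ = ω about a
  center at (−ρ(t)·L, 0). Every direction contracts at rate 1/τ_relax;
  the oscillation amplitude is set entirely by the drive. The default
  τ_relax = 12 h makes relaxation comparable to half the 24-h period — a
  damped clock that relaxed much faster could not distinguish times
  within a day.

The drive ρ(t) is a square wave of period 24 h (dawn at t = 0, dusk at
12 h by default), optionally degraded by the weather model below.

**Integrator.** Euler–Maruyama on the signal's grid (default dt = 0.01 h
for geometric analyses, 0.05 h for population sweeps; both well under the
τ_relax/100 guard). A deterministic run is the same stepper with zero
noise. The plain Euler rotation inflates the limit-cycle radius by a
known bias ≈ ω²·dt·τ_relax/2 (≤ 0.2 % at dt = 0.05 h), which cancels in
all phase-difference measurements.

**Entrained start.** Population runs start from the attracting fixed
point of the one-period return map, found by iterating the map and
polishing with a root solver *on the same time grid as the run*. For
weakly driven cycles the return map contracts phase at only ~2 L/R per
day, so the naive "integrate a few periods and clone" recipe starts the
ensemble measurably off the entrained orbit; solving the fixed point
removes the transient exactly. The entrained orbit of the clean drive
puts the decoded dusk phase at ≈ 0 (the attracting fixed point of the
one-day phase map θ → θ − 2(L/R)·sin θ) and the dawn phase at ≈ π.

**Internal noise.** ε_int is an *angular* diffusion amplitude in
rad/√h: along a flat direction the ensemble phase variance grows as
ε_int²·t. The Cartesian Langevin amplitude is ε_int·R_ref per
coordinate, with R_ref = R for limit cycles and the entrained mean
orbital radius for point attractors (computed once, noise-free; for the
default square drive it equals L·τ_relax/T_half = L). This is the
fairness normalization: clocks of either architecture lose phase
information at the same rate when undriven. Derived from copy number,
ε_int² = c/N with c = 1 rad²·h⁻¹ (only the proportionality is
physical). Noise is isotropic — internal fluctuations cannot be confined
to directions perpendicular to the attractor.

A consequence worth stating explicitly: with this normalization the
driven point attractor's stationary angular variance is
ε²·R_ref²·τ_relax/2 · ⟨1/r(t)²⟩ ≈ 0.62·ε²·τ_relax (the transverse
spatial deviation is an Ornstein–Uhlenbeck process of variance
ε²R_ref²τ/2; dividing by the squared orbital radius and averaging over
the cycle gives the factor ≈ 1.28). The package's closed-form helper
`point_attractor_variance` keeps the conventional unit constant
(σ² = ε²τ_relax) because the underlying law is a proportionality; the
simulation sits a factor ≈ 0.62 below it, which is a diffusion-constant
convention (variance = 2Dt vs Dt), not a failure of the τ_relax scaling.

## Geometric theory

* **Circle map.** Dusk relaxation maps day-cycle phases θ to night-cycle
  phases φ = P(θ). Two routes are implemented: the analytic radial
  projection φ = atan2(R sin θ, L + R cos θ), and direct integration of
  the night dynamics until radial convergence. In this model the angular
  velocity about the instantaneous center is exactly ω at any radius, so
  the two coincide to integrator tolerance for every τ_relax; they are
  kept as mutually checking routes. The slope s⁻¹ = dP/dθ sets the
  variance contraction σ² → σ²·s⁻² at each transition; at the entrained
  dusk phase s² − 1 ≈ 2 L/R.
* **Dark-pulse phase shift ΔΦ.** A transient dark pulse lets the clock
  fall toward the night attractor; ΔΦ is the wrapped phase difference
  between pulsed and unpulsed noise-free entrained trajectories at the
  following dusk (after the pulse the difference is frozen until dusk).
  For limit cycles ΔΦ ≈ (L/R)·|sin θ_end − sin θ_start| + O((L/R)²),
  bounded by the circular attractor; for point attractors the state is in
  free fall and ΔΦ is order one. The package's representative pulse is
  start 2.4 h, duration 2.4 h. A pulse centered *exactly* at mid-day is
  the one degenerate timing: the square-wave-entrained orbit is mirror
  symmetric about mid-day, cos(θ_midday) = 0, and the leading term
  vanishes, so the generic (R/L)⁻² law of ΔΦ² only appears off the node
  (measured exponent −1.96…−2.00 at every off-node timing tested).
* **Variance recursions.** Phase variance gains additively during day and
  night and contracts by s² at dusk and dawn. The fixed points give
  σ²_ext = ΔΦ²/(s⁴ − 1) for external noise and
  σ²_int = ε²T/(s² − 1) for internal noise (half-period T); both
  recursions are exposed and tested against their closed forms.
  Combining the two laws in the small-L/R scaling regime yields the
  optimal geometry (L/R)* ∝ ε_int/ε_ext and the trade-off product
  Q = ε_int²·ε_ext².

## Synthetic weather

The weather model degrades the daytime signal two ways:

* a stationary mean-1 **lognormal amplitude modulation** with standard
  deviation ε_ext and an Ornstein–Uhlenbeck exponent of correlation time
  2 h by default (broad-band below 1/τ_c), multiplied into daytime
  samples and clipped to [0, 1] (clipping only removes light; mean
  daytime intensity stays within [1 − 2ε_ext, 1] for ε_ext ≤ 0.3);
* **Poisson dark pulses** (default 1/day, exponential duration of mean
  2.4 h) that force ρ = 0.

External-noise ensembles give every member an *independent* weather
realization on a shared square-wave skeleton
(`weather_realizations`) — the population variance of the theory is a
variance across weather histories, not the day-to-day wander of one
history.

What the generator does not emulate: the empirical shape of measured
sunlight spectra, seasonal photoperiod changes, latitude effects, or
correlated weather across "locations". Passing tests therefore show the
architecture-dependent response to broad-band amplitude noise and
discrete dark events, not fidelity to any particular climate record.

## Precision metrics

* **Mutual information** between time of day (uniform bins) and decoded
  phase (equal-count bins by rank over the pooled steady-state samples),
  Miller–Madow corrected and clipped to the channel bound
  log2(min(time_bins, phase_bins)). Equal-count phase bins make the
  noise-free entrained clock an exact hour→bin bijection (uniform bins
  would straddle the O(L/R) distortions that the dusk/dawn maps imprint
  on the hourly phase cells); the clip enforces the information
  inequality that the bias correction can otherwise violate on
  deterministic data. MI collection drops the first 10 days as transient
  and uses whole periods only (a partial trailing day would unbalance
  the equal-count bins). Default 24×24 bins; the optimal-geometry
  experiment uses 96×96 bins at 0.25-h sampling because near the optimum
  the phase spread falls below an hour bin's width, where a 24-bin MI
  saturates at its bound and the argmax dissolves.
* **Circular variance** 1 − |⟨e^{iφ}⟩| (≈ σ²/2 for small dispersion).
* **Entrainment time**: first dawn at which a phase-uniform population's
  circular variance falls within 10 % (plus a 10⁻⁴ absolute floor) of a
  reference population started entrained *on the same drive realization*,
  sustained for 3 consecutive dawns; ∞ if never within 200 days. Using a
  per-day reference makes the criterion robust to day-to-day weather
  variation.

## Sweep experiments (study conditions)

All sweeps fix R = 1 and vary L; the degenerate geometry L/R = 0 routes
to the point attractor with τ_relax = 12 h and L = 0.1. Default desk
scales: 300 members, 30 simulated days (10 discarded), dt = 0.05 h,
3 replicates for stochastic cells; the crossover experiment uses 500
members × 40 days.

* **Crossover** (internal-noise sweep at fixed weather): full default
  weather (amplitude ε_ext = 0.3 **and** dark pulses — pulses are what
  punish the free-falling point attractor hardest), geometries
  L/R = 0.05 vs point attractor, ε_int ∈ [0.01, 0.3].
* **Optimal geometry**: amplitude-only weather (pulse_rate 0, so the
  external strength is carried entirely by ε_ext), correlation time 12 h,
  ε_ext = 0.8 with ε_int spanning ×16. The long correlation time and the
  fine MI binning place all three optima inside the small-L/R scaling
  regime where the (L/R)* ∝ ε_int/ε_ext law holds; the argmax is
  refined by a parabola through the peak in log L/R. The measured
  proportionality constant is ≈ 16 under these conditions — the law is a
  scaling statement, and only the log–log slope is compared.
* **Speed–precision**: amplitude-only weather (ε_ext = 0.8, τ_c = 12 h)
  or internal-only ε_int = 0.1, over L/R ∈ {0.05…0.8}.

## Oscillator zoo

Three parameter-complete literature models — Brusselator, Goodwin
(3-stage cascade, Hill n = 12, equal degradation rates; the secant
condition requires n > 8 for any instability), and a protein-only
repressilator (n = 3, leak α₀) — are driven through a Hopf bifurcation.
Per-model documented light couplings (uniform couplings proved
unworkable; each choice is forced by the model's structure):

* Brusselator: light multiplies the production rate a (κ = 0.1).
* Goodwin: light multiplies the shared degradation rate b (κ = 0.1);
  with n = 12 the fixed point is nearly insensitive to production, so a
  production drive would barely displace the attractor.
* Repressilator: light multiplies **one** gene's promoter strength
  (α₁, κ = 0.1); a symmetric all-promoter drive displaces the fixed
  point along the (1,1,1) diagonal, orthogonal to the oscillation plane,
  and cannot entrain phase.

Regimes: `damped` (below the Hopf point, |Re λ|/Im λ = 1/π so the
relaxation time is 12 h once the linear period is scaled to 24 h),
`small_cycle` (amplitude 0.5× the drive-induced fixed-point
displacement) and `large_cycle` (amplitude 2.5× for Brusselator and
repressilator, 5× for Goodwin — the largest ratios at which the driven
system retains a stably phase-locked orbit; beyond them the leading
Floquet multiplier of the return-map fixed point crosses 1 and the
clock is quasiperiodic rather than entrained). The per-regime time scale
starts from the duty-cycle-averaged day/night rotation rate and is then
refined by scanning for the smallest leading Floquet multiplier — the
center of the 1:1 locking tongue. Internal noise is additive per species
with amplitude ε_int scaled by that species' entrained-orbit standard
deviation; negative concentrations reflect at 0 (counted; > 1 % flags a
warning). Phases are decoded as the angle in the two leading principal
components of the noise-free entrained orbit.

**Known limitation.** Goodwin and the repressilator reproduce the full
trade-off ordering (large cycle best under external noise at low
internal noise; damped best at high internal noise). The Brusselator
reproduces the high-internal-noise reversal but not the
low-internal-noise ordering: under any rate-parameter coupling tried,
modulating its kinetics shifts the free-running frequency at first
order, and frequency noise is integrated by the cycle's flat direction
rather than filtered by its geometry, so its damped regime stays
slightly more weather-robust than its best stably-locked large cycle.
The geometric filtering argument assumes the input displaces the
attractor without detuning the rotation; couplings with that property
for these models live in the original publications and are outside this
package's scope.

## Numerical choices and degenerate inputs

* Seeds: every stochastic component takes an explicit seed;
  per-member weather seeds are spawned from a `SeedSequence`. Identical
  configuration ⇒ bit-identical output (CSV byte equality is tested).
* Circle maps are tabulated on 361-point grids, unwrapped to a
  continuous degree-1 branch; maps with L ≥ R are flagged non-monotone
  and their non-contracting slopes raise.
* `optimal_ratio` with ε_ext = 0 raises (the optimum runs to L/R → ∞);
  variance closed forms with s² ≤ 1 raise (undriven clocks dephase
  without bound).
* A state exactly at the instantaneous center has no phase and raises.
* MI requires ≥ 10 samples in every time bin and ≥ 5 steady-state
  periods.
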