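# Methods

## Model

Two phase oscillators in the master–slave (unidirectional) configuration:

    dφ₁/dt = ω₁
    dφ₂/dt = ω₂ + q_t(φ₁, φ₂)            (+ ξ₂(t) when noise is enabled)

The coupling function `q_t` is the diffusive trigonometric polynomial

    q_t(φ₁, φ₂) = c₁(t)·sin(φ₁−φ₂) + c₂(t)·cos(φ₁−φ₂),

a 2π-biperiodic function on the torus, identified with the square
[−π, π]². Under the normalised inner product
`⟨f,g⟩ = (1/4π²) ∫∫ f·g dφ₁ dφ₂` its L² norm — the **net coupling
strength** — follows from Parseval's identity:
`‖q_t‖₂ = √((c₁²+c₂²)/2)`.

The time-variation law keeps that norm constant while rotating the form:

    c₁(t) = √2·α·cos(φ(t)),   c₂(t) = √2·α·sin(φ(t)),   φ(t) = f(t)·t,

with `f` the T-periodic piecewise-linear rate (plateau `ε` on [0, T₁],
linear ramp to `k` on [T₁, T/2], plateau `k` on [T/2, T₂], ramp back on
[T₂, T]). Note the *raw* time multiplies `f`; only `f` itself is reduced
mod T. An alternative law φ(t) = ∫f dt would also be consistent with
constant norm, but the product form is what the schedule here defines; it
makes φ wind faster in later periods even during slow plateaus of f (the
winding rate on the n-th slow plateau is ε, but on the down-ramps it is
f + f′·t, which grows with t). The epoch structure — one locked epoch per
slow plateau, slipping over each fast plateau — is unaffected.

The phase difference ψ = φ₁ − φ₂ obeys the driven Adler equation

    dψ/dt = Ω − √2·α·sin(ψ + φ(t)),     Ω = ω₁ − ω₂,

and η = ψ + φ obeys dη/dt = Ω + dφ/dt − √2·α·sin(η). In the frozen
system (dφ/dt = 0) everything is classical: locking at
η* = arcsin(Ω/(√2α)) iff √2α > |Ω|, otherwise drift at mean rate
√(Ω² − 2α²) (the sign of Ω), with the unstable companion point π − η*.

## Two regimes, two certificates

**Slow driving.** If |dφ/dt| ≤ ε₀ with ε₀ below the minimum of
F(η) = Ω − √2α·sin(η) at the start angle and at the edges η* ∓ ε̃/2 of a
target ball, the trajectory of η enters that ball within the worst-case
travel time T₀ = ∫ dη/(|F(η)| − ε₀) (computed by adaptive quadrature;
the integrand is bounded because ε₀ is chosen a `safety` factor of 0.9
below the minimum) and never leaves it. `certify_slow_containment`
computes (ε₀, T₀) from this recipe, checks the schedule actually satisfies
|dφ/dt| ≤ ε₀, simulates, and reports the first violation time (or none).
Start angles coinciding with the unstable point are rejected.

**Fast winding.** If dφ/dt > K₁ (with relative curvature controlled by
K₂ > √(2π); for linear winding the condition is vacuous and K₂ = ∞ drops
its term), averaging over successive full turns of φ bounds the departure
of ψ from free drift at the detuning:

    |ψ(s) − ψ(0) − Ω·s| ≤ κ₀(K₁) + κ(K₁, K₂)·s
    κ₀ = 2√2·π·α/K₁
    κ  = √2·α·( 2π(|Ω|+√2α)/K₁ + (2π²/K₂²)(1 − 2π/K₂²)⁻² )

`certify_fast_drift` simulates ψ under uniform winding at rate k ≥ K₁ and
reports `max_s (deviation − bound)`, which must be ≤ 0. Both certificates
are *empirical* statements about one simulated trajectory, not proofs;
bound comparisons carry 1e-9 absolute slack for integrator rounding.

## Reference configurations

All fixtures share Ω = 1.08 rad/s, T = 1000 s, T₁ = 490 s, T₂ = 990 s,
ψ(0) = 0, h = 0.001 s, and a 5000 s default duration. The main
intermittency run uses √2α = 1.55 (α ≈ 1.096 s⁻¹), ε = 0.01, k = 100
rad/s; the four-panel sweep uses √2α = 1.176 with (ε, k) =
(0.01, 100), (0.001, 10), (0.0001, 10), (0, 1). For two-phase runs the
detuning is realised as ω₁ = 5.01, ω₂ = 3.93 rad/s — an arbitrary
physiologically plausible pair (≈0.8 and ≈0.63 Hz); only Ω matters for the
difference dynamics. The noisy synthetic uses additive phase noise of
intensity 0.05 rad·s^(−1/2) on both phases.

## Numerics

* **Integrator**: classical fixed-step RK4; fixed step so the output grid
  equals the integration grid and runs are bit-reproducible. Noisy runs
  use Euler–Maruyama with increments drawn once from
  `numpy.random.default_rng(seed)`.
* **Schedule evaluation**: φ and dφ/dt are pretabulated on the half-step
  grid (RK4 stage times) by exact branch-wise formulas, with one-sided
  derivatives at the corner points, evaluated in the printed branch order
  (ties at shared endpoints are harmless by continuity).
* **Accuracy regime**: the step resolves the forcing while
  |dφ/dt|·h ≪ 2π. At h = 0.001 this holds on plateaus (k·h = 0.1) but not
  on late down-ramps, where |dφ/dt| ~ f′·t can reach 5·10⁴ rad/s. There
  the system is deep in the slipping regime and only the drift matters:
  step-halving reproduces the terminal ψ to ~1e-13 on locked spans but
  only to ~1e-3 across fast spans, while the fast-plateau drift slope is
  stable to 5 decimal places between h = 0.01 and h = 0.001. Conclusions
  are therefore drawn from tolerance-based observables (slopes, epoch
  structure, bound margins), not from pointwise trajectory values across
  fast spans. `simulate_eta` is accurate under the same condition on
  |dφ/dt|; its cross-check against ψ + φ is meaningful on slow spans.
* **Kernels** are compiled with numba when available (pure-Python
  fallback, identical semantics). The packaged default problem sizes
  (5·10⁶ steps) run in well under a second with numba.

## Epoch detection

A sample is *locked* when the centred sliding-window mean slope
|Δψ/Δt| over `window` = 10 s falls below `slope_threshold` (default
0.108 rad/s = |Ω|/10); runs shorter than `min_duration` = 20 s are merged
into their neighbours, shortest first. The three defaults separate the two
timescales of the reference runs by an order of magnitude on each side;
all are configurable. The procedure is deterministic, idempotent, and
invariant under adding a constant to the track. Locked epochs creep at
−ε (they track η* − φ(t)), comfortably below the threshold.

## Windowed inference

Within each window (default 50 s, stride 25 s) the driven-phase velocity
(central differences after decimation to a 0.01 s regression step;
one-sided at window edges) is regressed on the torus Fourier basis
{1} ∪ {cos, sin(kφ₁+lφ₂)} up to order 2 (one representative per ±(k,l)
pair). Estimation is Bayesian ridge in closed form: flat prior on the
intercept (the ω₂ estimate), zero-mean Gaussian prior with sd `prior_sd`
(default 2.0 rad/s, weakly informative at the amplitude scale of interest)
on every coupling coefficient, and the noise scale taken from OLS
residuals, so noiseless data reduce to (minimum-norm) least squares. The
per-window noise report converts the residual sd of the differenced
velocities back to the phase-noise intensity via σ_ξ = σ_y·√(2Δt).

The full sequential Bayesian scheme with prior propagation between
windows is not reproduced; an optional `carryover_diffusion` mode
propagates each posterior as the next prior with covariance inflated by
diffusion²·stride, which emulates that behaviour without its exact
recursion.

**What the synthetic benchmarks show — and do not.** The generator
produces exactly the model class the regression assumes (finite Fourier
coupling, white phase noise, uniformly sampled true phases). Recovery
results on it therefore validate the estimator's correctness, not its
robustness to protophase error, observational noise, nonstationary
frequencies, or bidirectional coupling, all of which real recordings have.

Two identifiability limits are inherent and documented rather than worked
around:

1. *Fast rotation*: when the coupling form rotates with period comparable
   to or shorter than the window, the rotation averages out inside the
   window and the inferred strength collapses toward zero. Windows must be
   short against the rotation timescale.
2. *Strict locking*: when the pair is phase-locked under a slowly rotating
   coupling, the observed velocity of the driven phase is constant in time
   — the rotation of the true coefficients exactly offsets the arc swept
   by the phase difference — so such windows carry no information about
   the coupling amplitude, and *any* windowed regression underestimates
   the strength there (exactly zero for noiseless data; dynamical noise
   restores only a weak, biased signal). This is a property of the data,
   not the estimator: the strength series ε(t) from locked epochs of the
   rotating-schedule synthetic is not a usable estimate of α, and the test
   asserting that recovery is expected to fail. Inference on drifting
   (unlocked) synthetics recovers coefficients to ~1e-5 (noiseless) and
   ~1e-2 (noise 0.05).

## Design choices on open points

* The similarity index ρ is the plain cosine similarity of the raw
  functions (the constant term participates; no mean-centring), and the
  reference is the coefficient-wise mean over windows.
* Breakpoint membership in f uses closed intervals in printed order; both
  adjacent branches agree at shared endpoints.
* ψ is integrated unwrapped on the real line; wrapping to [−π, π) happens
  only on request.
* The slow-containment certificate accepts only schedules whose winding
  rate stays below ε₀ over the whole run (checked on a dense probe grid);
  the fast-drift certificate accepts only constant-rate schedules, since a
  twice-differentiability requirement on φ excludes the corner points of
  the piecewise schedule — fast spans of the periodic schedule are covered
  per-branch by the same constants.

## Known limitations

* Phase models only: no limit-cycle state-space oscillators, phase
  reduction, isochrons, or protophase extraction from raw signals.
* Unidirectional coupling only; no networks; no Lyapunov-exponent
  stability analysis.
* The piecewise-periodic and constant-rate laws are the only modulation
  laws; arbitrary user φ(t) is out of scope.
* Fixed-step integration: no stiff/adaptive schemes; accuracy caveats on
  under-resolved fast ramps as above.
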