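# Methods

## Model and assumptions

The package simulates batch (closed-reactor) cultivation of a micro-organism
population under substrate limitation with two mortality channels:

    s′(t) = −(1/γ) · μ(s(t)) · x(t)
    x′(t) =  μ(s(t)) · x(t) − k1·x(t) − k2·x(t − τ)

`s` and `x` are substrate and biomass concentrations (g/L); μ(s) is the
intrinsic specific growth rate (1/h); γ (g/g) is the yield; `k1` (1/h) is an
instantaneous specific decay and `k2` (1/h) a decay proportional to the
population one average lifetime τ (h) earlier.  The initial data are a
substrate charge `s0 > 0` and a biomass history φ on `[−τ, 0]` that must be
nonnegative, nondecreasing, continuous and bounded with φ(0) > 0; these
history conditions are enforced at validation (named analytic forms satisfy
them by construction; tabular histories are monotonicity-checked and
interpolated with shape-preserving PCHIP; arbitrary callables are screened
on a 257-point grid).  The reactor is assumed spatially uniform; `k2 ≥ k1`
(most deaths at lifetime expiry) is biologically plausible but deliberately
not enforced.  With τ = 0 the delayed term acts instantaneously and the
decays lump to `k1 + k2`.

Growth families, in their standard literature forms (all with μ(0) = 0):

| family  | μ(s)                                        | shape |
|---------|---------------------------------------------|-------|
| monod   | μmax·s/(ks+s)                               | strictly increasing → μmax |
| haldane | μmax·s/(ks+s+s²/ki)                         | unimodal, argmax √(ks·ki) |
| andrews | μmax·s/((ks+s)(1+s/ki))                     | unimodal, argmax √(ks·ki) |
| webb    | μmax·s(1+βs/ki)/(ks+s+s²/ki)                | unimodal iff β < 1, else monotone → μmax·β |

Webb's regime is *detected numerically* (sign of μ′ far out on the s axis)
rather than hard-coding the β threshold, so a corrected functional form
would be picked up automatically.  Webb with β = 0 reduces to Haldane
exactly; this is property-tested.

## Operational calculators

* `minimal_growth_substrate` returns `{s : μ(s) > k1+k2}` as an interval.
  Monotone families give `(s_min, ∞)`; unimodal families give
  `(s_low, s_high)`, with `s_high = ∞` when the tail limit of μ (Webb's
  μmax·β) still exceeds the mortality.  An empty window is the no-growth
  classification.
* `critical_substrate` is the ascending-branch root of μ(s) = k1+k2 —
  ascending because the substrate decreases monotonically and therefore
  crosses that branch from above on its way down.  Monod inverts in closed
  form `ks·r/(μmax−r)`; Haldane/Andrews solve their quadratics (numerically
  stable form, small root computed as c/(a·root_large)); Webb uses brentq
  on the requested monotone branch (xtol 1e−12).  Rates within a relative
  guard of 1e−12 of the supremum are classified unattainable.
* `find_stationary_onset` locates the biomass peak: grid argmax refined to
  the zero of the model's own x′(t) reconstructed on the dense output
  (brentq; golden-section fallback on flat tops).  It reports both the
  simple criterion's residual |μ(s(t*)) − (k1+k2)| and the delayed ratio
  x(t*−τ)/x(t*) entering the exact identity
  μ(s(t*)) = k1 + k2·x(t*−τ)/x(t*), so the quality of the practical
  prescription is explicit instead of silently chosen.  `onset_time` is when
  the falling substrate first crosses the critical level — the measurement
  rule a practitioner would apply.

## Integrator

Method of steps with classical fixed-step RK4.  The step h divides τ exactly
(default τ/64; a requested h is rounded to the nearest divisor and the
adjustment logged in the trajectory meta), so the delayed biomass needed at
RK4 stage times falls either on an already-computed node or on a step
midpoint of the previous delay interval, evaluated with the cubic-Hermite
midpoint formula `x(t+h/2) = (x_a+x_b)/2 + h(f_a−f_b)/8`.  On the first
interval the exact history φ is used.  With τ = 0 the default step is
horizon/10⁴ and the delayed term is applied to the stage state itself.

Dense output is cubic Hermite on node values and model derivatives,
matching the scheme's local accuracy; on `[−τ, 0)` the convention
`(s, x) = (s0, φ(t))` holds (the model constrains only the biomass history).
The substrate is non-increasing *by construction*: every stage slope of s is
non-positive (stage biomass is floored at zero in the consumption term, as
stage values can dip negative near an extinction crossing).

**Events.**  If a step drives s (or x) through zero, that step is
re-integrated with 64 fine sub-steps whose delayed lookups use general cubic
Hermite interpolation on the computed grid, and the state is clamped at zero
from the crossing on; the event time is recorded.  After substrate depletion
μ(0) = 0 keeps s at zero exactly and the biomass follows pure decay.  After
biomass extinction the state is frozen (x ≡ 0 cannot regrow; s is no longer
consumed).  Without the sub-step refinement the kink costs O(h) locally —
measured as a ~0.6% final-state error on a near-zeroth-order depletion
scenario, reduced to ~1e−4 by the refinement.

A genuinely independent cross-check, `euler_oracle`, integrates the same
system with explicit first-order Euler and a plain ring-buffer delayed
lookup (τ/h must be integral).  It shares no stepping code with the
production integrator, is first-order convergent (property-tested), and —
with k1 = k2 = 0 — conserves γ·s + x to roundoff because both updates reuse
the same μ(s_i)·x_i product.

**Biomass can genuinely reach zero in finite time.**  Once growth stops, the
decay x′ = −k1·x − k2·x(t−τ) is oscillatory whenever k2·τ > 1/e, so the
solution crosses zero while s > 0; positivity of the solution is therefore
guaranteed only up to the first such extinction event, and the positivity
check covers exactly the span before the first clamp.

## Qualitative checks (`verify_theorems`)

Deterministic functions of one trajectory plus recorded tolerances:

* positivity — s, x > 0 on the grid before the first clamp event;
* substrate monotonicity — Δs ≤ 1e−9 everywhere;
* depletion implies decay — after an s-clamp with k1+k2 > 0, x strictly
  decreases while positive (no live growth without nutrient);
* extinction — with k1+k2 > 0, x(horizon)/max x < 1e−3.  After depletion
  x(t−τ) ≥ x(t), so x decays at least like e^{−(k1+k2)t}; the test is
  therefore decidable once the horizon clears the clamp by
  ln(10³)/(k1+k2), and shorter horizons return a flagged vacuous pass
  (noted in the report) rather than a spurious failure.

`estimate_extinction_horizon` sizes runs for the extinction study:
peak-time estimate + 1.5·ln(10³)/(k1+k2) + 5τ.

## Fixtures

No external data exists for this model; all test inputs are generated.
`sample_parameters` draws log-uniformly μmax ∈ [0.1, 2] /h, ks ∈ [0.1, 10]
g/L, ki ∈ [1, 100] g/L, γ ∈ [0.2, 1], τ ∈ [0.5, 10] h, and uniformly
β ∈ [0, 0.9], k1, k2 ∈ [0, 0.3·μmax] — wide enough to span monotone and
inhibited kinetics and both growth/no-growth classifications.  These ranges
are invented bench-scale values, not measurements of any organism.
`sample_scenario` additionally places s0 strictly inside the growth window
(cultures that actually grow) and supports a mortality floor
(k1+k2 ≥ 0.05·μmax in the extinction studies, because the decay tail lasts
~1/(k1+k2) and must fit an observable horizon).  Eight named reference
scenarios with hand-fixed constants cover: the conservative classical
reduction, instant-only and delay-only mortality, combined mortality (Webb
and Andrews), an inhibited start on the descending branch of a Haldane μ, a
no-growth regime, and a near-zeroth-order fast-depletion case that exercises
the finite-time depletion clamp non-vacuously.

What the generator does **not** emulate: measurement noise, temperature/pH
dependence of μ, spatial gradients, substrate inflow (fed-batch/chemostat),
lag-phase physiology, or parameter uncertainty.  Passing tests demonstrate
the numerics and the model's internal consistency, not agreement with any
particular experimental culture.

## Numerical conventions and problem sizes

* Root finding: brentq after bracketing (bracket doubling from
  max(ks, ki)), xtol 1e−12 on s.
* Unattainable-rate guard: relative 1e−12 against the supremum.
* Trajectory CSV and config TOML are written at 17 significant digits, so
  repeated runs are byte-identical.
* Cross-scheme and cross-integrator comparisons use mixed tolerances with
  the absolute floor set by the problem's mass scale γ·s0 + x0 (i.e.
  atol = rtol·scale): a state that has decayed many orders of magnitude
  below that scale is compared absolutely, avoiding ill-posed relative
  comparisons of near-zero concentrations.
* Study sizes: the oracle cross-check runs the eight reference scenarios at
  Euler h = 1e−4; root identities use 100 seeded draws per family; the peak
  criteria 20 seeded fixtures each; the qualitative suite 50 seeded
  fixtures run to their extinction horizons.  The full test suite runs in
  under a minute on one CPU.

## Known limitations

* Fixed-step integration only; no adaptive error control (refinement is
  available by raising `steps_per_delay`).  Stiff parameter corners
  (extreme μmax·τ) would need smaller steps.
* Single discrete delay; no distributed delays or multiple lifetimes.
* Batch mode only — no inflow/outflow terms.
* No parameter estimation from data; the package simulates and analyses a
  given parameter set.
* The delayed-peak identity is verified on the numerical interpolant; its
  1e−6 agreement is a property of the dense output, inherited from the
  integrator's accuracy.
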