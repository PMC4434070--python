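# monodde

Batch (periodic) cultivation of micro-organisms — bacteria, yeasts — with
**instantaneous and delayed mortality**: a tested delay-differential-equation
simulator plus the two operational calculators a cultivation practitioner
needs (the minimal nutrient concentration that sustains net reproduction, and
the critical concentration at which the biomass peaks).

## The model

A closed reactor holds an initial nutrient-substrate charge `s0` (g/L) and a
small inoculum of biomass `x` (g/L).  The biomass grows at a
substrate-dependent specific rate μ(s) and dies through two channels: in
proportion to the current population (rate `k1`, unfavourable conditions
acting now) and in proportion to the population one average lifetime `τ` ago
(rate `k2` — the cohort born at `t − τ` reaching the end of its lifespan):

    s′(t) = −(1/γ) · μ(s(t)) · x(t)
    x′(t) =  μ(s(t)) · x(t) − k1 · x(t) − k2 · x(t − τ)

with `s(0) = s0` and a biomass history `x(t) = φ(t)` on `[−τ, 0]` that is
nonnegative, nondecreasing, continuous and bounded.  `γ` is the economic
(yield) coefficient, g biomass per g substrate.  Four μ(s) families are
supported — Monod (saturating), Haldane, Andrews and Webb (substrate
inhibition, unimodal in the usual parameter regime).

Two quantities answer the practical questions of batch cultivation:

* **growth window** — the set `{s : μ(s) > k1 + k2}`; its lower endpoint is
  the minimal substrate concentration at which reproduction outruns total
  mortality (for at least one lifetime τ);
* **critical substrate `s*`** — the ascending-branch root of
  `μ(s) = k1 + k2`.  The substrate falls monotonically during cultivation,
  so when periodic measurements show `s` reaching `s*`, the biomass is at
  (or very near) its maximum: the culture has entered the stationary phase.
  At `τ = 0` this criterion is exact; at `τ > 0` the exact interior-maximum
  condition is `μ(s(t*)) = k1 + k2 · x(t*−τ)/x(t*)`, and the reported
  `residual` quantifies the difference.

The delay system is integrated by the **method of steps**: fixed-step
classical RK4 whose step divides τ exactly, so every delayed lookup lands on
an already-computed grid node or step midpoint (cubic-Hermite midpoint
formula).  Steps that cross a depletion (`s → 0`) or extinction (`x → 0`)
event are re-integrated with fine sub-steps so the clamp is resolved sharply.

## Worked example

`culture.toml`:

```toml
[model]
family = "monod"
mu_max = 0.8     # 1/h
k_s = 2.0        # g/L
gamma = 0.5      # g biomass / g substrate
k1 = 0.1         # 1/h  instantaneous decay
k2 = 0.15        # 1/h  delayed decay
tau = 2.0        # h    average lifetime

[initial]
s0 = 12.0        # g/L
history = "constant"
x0 = 0.1         # g/L

[solver]
horizon = 60.0   # h
```

```text
$ monodde critical-substrate --config culture.toml
0.90909090909090906

$ monodde growth-window --config culture.toml
(0.90909090909090906, inf)

$ monodde simulate --config culture.toml --out-dir out
trajectory: out/run.csv
report: out/run.report.json
biomass peak x=4.0381134695606207 at t=8.2029808743691142 (s=0.59383261206512816, critical s*=0.90909090909090906)
```

Reading: with total mortality `k1 + k2 = 0.25` /h, the culture needs more
than 0.909 g/L of substrate to sustain net growth (closed form
`k_s·r/(μ_max − r)` for Monod kinetics).  Starting from 12 g/L the biomass
climbs to 4.04 g/L at t ≈ 8.2 h.  At the true peak the substrate is already
0.594 g/L — slightly below `s* = 0.909` because with `τ = 2` the delayed
mortality term still references the smaller population of two hours earlier;
the report's `residual` and `delayed_ratio` fields make that gap explicit.
`monodde verify` re-checks positivity, substrate monotonicity,
post-depletion decay and extinction on the simulated trajectory and exits
nonzero if any fails.

```text
$ monodde scenarios --export configs/   # named reference scenarios as TOML
```

## Library use

```python
from monodde import (GrowthModelSpec, ModelParameters, InitialData,
                     make_history, simulate, find_stationary_onset)

g = GrowthModelSpec("monod", mu_max=0.8, k_s=2.0)
p = ModelParameters(growth=g, gamma=0.5, k1=0.1, k2=0.15, tau=2.0)
init = InitialData(s0=12.0, history=make_history("constant", 0.1, tau=2.0))
traj = simulate(p, init, horizon=60.0)
report = find_stationary_onset(traj, p)
print(report.t_star, report.x_peak, report.s_critical)
```

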