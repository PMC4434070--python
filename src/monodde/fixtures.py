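"""Seeded generators for valid model inputs and named reference scenarios.

Every test and example runs on inputs produced here; there is no external
data.  The random ranges are deliberately wide enough to span monotone and
substrate-inhibited kinetics and both growth and no-growth classifications;
they emulate bench-scale batch cultivations (rates of order 0.1–2 per hour,
half-saturation constants of order 0.1–10 g/L, lifetimes of 0.5–10 h) and do
not represent any measured organism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .analysis import estimate_peak_horizon
from .dde import History, InitialData, ModelParameters
from .growth import Family, GrowthModelSpec, evaluate_mu, growth_window

__all__ = [
    "Scenario",
    "sample_parameters",
    "make_history",
    "sample_initial_data",
    "sample_scenario",
    "reference_scenarios",
]

_FAMILY_TAG = {Family.MONOD: 0, Family.HALDANE: 1, Family.ANDREWS: 2, Family.WEBB: 3}


@dataclass(frozen=True)
class Scenario:
    """A named, fully-specified simulation: parameters, initial data, horizon."""

    name: str
    params: ModelParameters
    init: InitialData
    horizon: float
    seed: int = 0
    tags: tuple = ()


def _log_uniform(rng, lo, hi):
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def sample_parameters(seed: int, family) -> ModelParameters:
    """Draw a valid, seeded parameter set for the given growth family.

    Log-uniform draws: mu_max in [0.1, 2] 1/h, k_s in [0.1, 10] g/L,
    k_i in [1, 100] g/L (inhibited families), gamma in [0.2, 1],
    tau in [0.5, 10] h; uniform draws: beta in [0, 0.9] (webb),
    k1, k2 in [0, 0.3 * mu_max].  Deterministic for a given (seed, family).
    """
    family = Family(family)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _FAMILY_TAG[family]]))
    mu_max = _log_uniform(rng, 0.1, 2.0)
    k_s = _log_uniform(rng, 0.1, 10.0)
    k_i = _log_uniform(rng, 1.0, 100.0) if family is not Family.MONOD else None
    beta = float(rng.uniform(0.0, 0.9)) if family is Family.WEBB else None
    spec = GrowthModelSpec(family=family, mu_max=mu_max, k_s=k_s, k_i=k_i, beta=beta)
    return ModelParameters(
        growth=spec,
        gamma=_log_uniform(rng, 0.2, 1.0),
        k1=float(rng.uniform(0.0, 0.3 * mu_max)),
        k2=float(rng.uniform(0.0, 0.3 * mu_max)),
        tau=_log_uniform(rng, 0.5, 10.0),
    )


def make_history(kind: str, x0: float, tau: float, growth_fraction: float = 0.0) -> History:
    """Build a named history reaching x0 at t = 0.

    Ramps rise from ``x0 * (1 - growth_fraction)`` at -tau to ``x0`` at 0;
    ``constant`` ignores ``growth_fraction``.  The result always satisfies
    the history conditions (nonnegative, nondecreasing, continuous, bounded).
    """
    return History(kind=kind, x0=x0, tau=tau, growth_fraction=growth_fraction)


def sample_initial_data(
    seed: int, params: ModelParameters, require_growth: bool = False
) -> InitialData:
    """Draw a seeded initial state consistent with the parameter set.

    With ``require_growth`` the initial substrate is placed strictly inside
    the growth window (so the culture starts with net reproduction); without
    it, s0 is a free log-uniform draw in [0.5, 50] g/L.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 104729]))
    window = growth_window(params.growth, params.mortality_rate)
    if require_growth:
        if window.empty:
            raise ValueError("no-growth parameter set: the growth window is empty")
        lo = window.lower
        if math.isinf(window.upper):
            hi = max(10.0 * lo, lo + 20.0) if lo > 0 else 20.0
        else:
            hi = window.upper
        u = rng.uniform(0.15, 0.85)  # stay strictly inside the window
        s0 = lo + u * (hi - lo) if lo > 0 else _log_uniform(rng, 0.5, hi)
    else:
        s0 = _log_uniform(rng, 0.5, 50.0)
    x0 = params.gamma * s0 * _log_uniform(rng, 0.005, 0.1)
    kind = ("constant", "linear_ramp", "exponential_ramp")[int(rng.integers(3))]
    gf = float(rng.uniform(0.0, 0.5)) if kind != "constant" else 0.0
    return InitialData(s0=s0, history=make_history(kind, x0, params.tau, gf))


def sample_scenario(
    seed: int,
    family=None,
    require_growth: bool = True,
    tau: Optional[float] = None,
    min_mortality_frac: float = 1e-3,
    max_redraws: int = 50,
) -> Scenario:
    """Draw a full seeded scenario, redrawing until the regime is met.

    ``require_growth=True`` yields cultures that start growing (so a biomass
    peak exists when mortality is positive); ``tau`` overrides the drawn
    delay (``tau=0`` gives the ODE reduction); ``min_mortality_frac`` sets a
    floor k1 + k2 >= frac * mu_max (extinction studies need a mortality that
    acts on an observable time scale, since the decay tail lasts about
    1/(k1 + k2)).  Redraw seeds are derived deterministically from ``seed``.
    """
    families = list(Family) if family is None else [Family(family)]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 15485863]))
    for attempt in range(max_redraws):
        sub = int(seed) + 1_000_003 * attempt
        fam = families[int(rng.integers(len(families)))]
        params = sample_parameters(sub, fam)
        if tau is not None:
            params = replace(params, tau=tau)
        window = growth_window(params.growth, params.mortality_rate)
        if require_growth and (
            window.empty
            or params.mortality_rate <= min_mortality_frac * params.growth.mu_max
        ):
            continue
        try:
            init = sample_initial_data(sub, params, require_growth=require_growth)
        except ValueError:
            continue
        horizon = estimate_peak_horizon(params, init)
        tags = ["sampled", fam.value]
        if window.empty:
            tags.append("no-growth")
        return Scenario(
            name=f"sampled-{fam.value}-{seed}",
            params=params,
            init=init,
            horizon=horizon,
            seed=int(seed),
            tags=tuple(tags),
        )
    raise RuntimeError(f"could not draw a scenario meeting the regime in {max_redraws} tries")


def reference_scenarios():
    """The fixed, named scenarios used throughout the tests and docs.

    Covers the classical conservative reduction (no mortality), instant-only
    and delay-only mortality, the combined model, an inhibited start on the
    descending branch of a unimodal mu, a no-growth regime, and all four
    growth families.  Constants are fixed by hand (not drawn) so the set is
    stable across releases.
    """
    monod = lambda mm, ks: GrowthModelSpec(Family.MONOD, mu_max=mm, k_s=ks)
    scenarios = [
        Scenario(
            name="classical",
            params=ModelParameters(growth=monod(0.6, 1.5), gamma=0.5, k1=0.0, k2=0.0, tau=0.0),
            init=InitialData(s0=10.0, history=make_history("constant", 0.1, 0.0)),
            horizon=30.0,
            tags=("classical", "monotone", "conservation", "monod"),
        ),
        Scenario(
            name="instant-only",
            params=ModelParameters(growth=monod(0.8, 2.0), gamma=0.5, k1=0.1, k2=0.0, tau=2.0),
            init=InitialData(s0=12.0, history=make_history("constant", 0.15, 2.0)),
            horizon=40.0,
            tags=("monotone", "instant-mortality", "monod"),
        ),
        Scenario(
            name="delay-only",
            params=ModelParameters(growth=monod(0.7, 1.2), gamma=0.45, k1=0.0, k2=0.15, tau=2.0),
            init=InitialData(
                s0=10.0, history=make_history("linear_ramp", 0.1, 2.0, growth_fraction=0.4)
            ),
            horizon=40.0,
            tags=("monotone", "delayed-mortality", "monod"),
        ),
        Scenario(
            name="combined-webb",
            params=ModelParameters(
                growth=GrowthModelSpec(Family.WEBB, mu_max=0.9, k_s=1.0, k_i=30.0, beta=0.4),
                gamma=0.5, k1=0.05, k2=0.1, tau=3.0,
            ),
            init=InitialData(
                s0=8.0, history=make_history("exponential_ramp", 0.1, 3.0, growth_fraction=0.3)
            ),
            horizon=40.0,
            tags=("combined", "webb"),
        ),
        Scenario(
            name="inhibited-start",
            params=ModelParameters(
                growth=GrowthModelSpec(Family.HALDANE, mu_max=1.0, k_s=0.8, k_i=5.0),
                gamma=0.5, k1=0.04, k2=0.06, tau=1.5,
            ),
            init=InitialData(s0=15.0, history=make_history("constant", 0.1, 1.5)),
            horizon=40.0,
            tags=("inhibited", "combined", "haldane"),
        ),
        Scenario(
            name="no-growth",
            params=ModelParameters(
                growth=GrowthModelSpec(Family.HALDANE, mu_max=0.5, k_s=1.0, k_i=4.0),
                gamma=0.5, k1=0.15, k2=0.15, tau=1.0,
            ),
            init=InitialData(s0=2.0, history=make_history("constant", 0.2, 1.0)),
            horizon=30.0,
            tags=("no-growth", "haldane"),
        ),
        Scenario(
            name="fast-depletion",
            # k_s << s: nearly zeroth-order consumption, so the substrate
            # genuinely hits zero in finite time and the post-depletion pure
            # decay regime is exercised (not just approached asymptotically).
            params=ModelParameters(growth=monod(1.0, 1e-3), gamma=0.5, k1=0.1, k2=0.12, tau=1.0),
            init=InitialData(s0=4.0, history=make_history("constant", 1.0, 1.0)),
            horizon=60.0,
            tags=("depletion", "combined", "monod"),
        ),
        Scenario(
            name="combined-andrews",
            params=ModelParameters(
                growth=GrowthModelSpec(Family.ANDREWS, mu_max=0.75, k_s=1.5, k_i=40.0),
                gamma=0.55, k1=0.06, k2=0.08, tau=2.5,
            ),
            init=InitialData(
                s0=9.0, history=make_history("linear_ramp", 0.12, 2.5, growth_fraction=0.25)
            ),
            horizon=45.0,
            tags=("combined", "andrews"),
        ),
    ]
    # sanity: the no-growth scenario really is one
    ng = scenarios[5]
    assert growth_window(ng.params.growth, ng.params.mortality_rate).empty
    assert evaluate_mu(ng.params.growth, ng.init.s0) < ng.params.mortality_rate
    return scenarios
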