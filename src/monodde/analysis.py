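"""Operational calculators and trajectory diagnostics.

Two practical questions of batch cultivation are answered in closed form /
by root finding on mu:

1. *Minimal substrate for increasing reproduction* — the set
   ``{s : mu(s) > k1 + k2}``; its lower endpoint is the smallest nutrient
   concentration at which the population can reproduce faster than its total
   specific mortality (for at least one lifetime tau).
2. *Critical substrate at the biomass peak* — the ascending-branch root of
   ``mu(s) = k1 + k2``.  The substrate falls monotonically during
   cultivation, so when it reaches this level the biomass is at (or near)
   its maximum and the culture enters the stationary phase.  At tau = 0 the
   peak condition is exact; at tau > 0 the exact interior-maximum condition
   is ``mu(s(t*)) = k1 + k2 * x(t* - tau) / x(t*)`` and the report's
   ``residual`` quantifies the gap to the simpler criterion.

The theorem verifier checks, on a computed trajectory, the qualitative
claims the model provably satisfies: positivity, substrate monotonicity,
strict biomass decay after substrate depletion, and long-horizon extinction
when total mortality is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dde import InitialData, ModelParameters, SolverOptions, Trajectory, simulate
from .errors import UnattainableRateError, UsageError
from .growth import GrowthWindow, evaluate_mu, growth_window, invert_mu

__all__ = [
    "PeakReport",
    "TheoremReport",
    "minimal_growth_substrate",
    "critical_substrate",
    "find_stationary_onset",
    "verify_theorems",
    "simulate_to_peak",
    "estimate_peak_horizon",
    "estimate_extinction_horizon",
]


def minimal_growth_substrate(params: ModelParameters) -> GrowthWindow:
    """Substrate interval sustaining net growth against mortality k1 + k2.

    The window's lower endpoint is the minimal nutrient concentration needed
    to start an increasing reproduction for at least one lifetime tau.  An
    empty window means no substrate level can offset the mortality ("no
    growth possible at this mortality").
    """
    return growth_window(params.growth, params.mortality_rate)


def critical_substrate(params: ModelParameters) -> float:
    """Ascending-branch root of mu(s) = k1 + k2.

    This is the concentration the falling substrate is heading toward when
    the biomass peaks; measuring s against this level detects the onset of
    the stationary phase.  With zero mortality the peak occurs only at
    substrate exhaustion, so 0 is returned.
    """
    r = params.mortality_rate
    if r == 0.0:
        return 0.0  # biomass peaks only when the substrate is exhausted
    return invert_mu(params.growth, r, branch="ascending")


@dataclass(frozen=True)
class PeakReport:
    """Where and how the biomass peaks on a trajectory.

    ``residual`` = |mu(s_at_peak) - (k1 + k2)| measures how closely the
    simple stationary-phase criterion holds at the true maximum;
    ``delayed_ratio`` = x(t* - tau) / x(t*) enters the exact peak identity
    mu(s(t*)) = k1 + k2 * delayed_ratio.  ``onset_time`` is when the falling
    substrate first crosses the critical level (the practical detection
    rule); nan when not applicable.
    """

    found: bool
    t_star: float = math.nan
    x_peak: float = math.nan
    s_at_peak: float = math.nan
    s_critical: float = math.nan
    residual: float = math.nan
    delayed_ratio: float = math.nan
    onset_time: float = math.nan
    message: str = ""


def _net_growth(traj: Trajectory, params: ModelParameters, t: float) -> float:
    """x'(t) reconstructed from the model on the trajectory's dense output."""
    s, x = traj.evaluate_at(t)
    td = t - params.tau
    if td < -params.tau:
        td = -params.tau
    _, xd = traj.evaluate_at(td)
    return evaluate_mu(params.growth, s) * x - params.k1 * x - params.k2 * xd


def find_stationary_onset(traj: Trajectory, params: ModelParameters) -> PeakReport:
    """Locate the biomass maximum and report the stationary-phase criteria.

    The grid argmax of x is refined to the zero of the model's own x'(t)
    evaluated on the dense output (falling back to a golden-section polish
    of x itself when no sign change brackets the node).  A trajectory whose
    biomass is monotone over the whole horizon has no interior peak and is
    flagged rather than raising.
    """
    t = traj._t
    x = traj._x
    j = int(np.argmax(x))
    try:
        s_crit = critical_substrate(params)
    except UnattainableRateError:
        s_crit = math.nan

    if j == len(x) - 1 and x[-1] > x[0]:
        return PeakReport(
            found=False,
            s_critical=s_crit,
            message="biomass still increasing at the horizon; extend the horizon",
        )
    if j == 0:
        return PeakReport(
            found=False,
            s_critical=s_crit,
            message="biomass decreasing from t=0: no interior peak (no-growth regime)",
        )

    lo, hi = t[j - 1], t[j + 1]
    g_lo, g_hi = _net_growth(traj, params, lo), _net_growth(traj, params, hi)
    if g_lo > 0.0 > g_hi:
        t_star = brentq(
            lambda tt: _net_growth(traj, params, tt), lo, hi, xtol=1e-12, rtol=8.9e-16
        )
    else:  # flat top or clamped biomass: polish the maximum of x directly
        res = minimize_scalar(
            lambda tt: -traj.evaluate_at(tt)[1], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        t_star = float(res.x)

    s_star, x_peak = traj.evaluate_at(t_star)
    td = max(t_star - params.tau, -params.tau)
    _, x_del = traj.evaluate_at(td)
    ratio = x_del / x_peak if x_peak > 0 else math.nan
    residual = abs(evaluate_mu(params.growth, s_star) - params.mortality_rate)

    onset = math.nan
    if math.isfinite(s_crit) and traj._s[0] > s_crit:
        k = int(np.searchsorted(-traj._s, -s_crit))  # s is non-increasing
        if k < len(t):
            a = t[max(k - 1, 0)]
            b = t[k]
            f = lambda tt: traj.evaluate_at(tt)[0] - s_crit
            if f(a) > 0.0 >= f(b):
                onset = brentq(f, a, b, xtol=1e-12, rtol=8.9e-16)
            else:
                onset = float(t[k])

    return PeakReport(
        found=True,
        t_star=t_star,
        x_peak=x_peak,
        s_at_peak=s_star,
        s_critical=s_crit,
        residual=residual,
        delayed_ratio=ratio,
        onset_time=onset,
    )


_DEFAULT_TOLERANCES = {
    "substrate_monotone": 1e-9,   # absolute slack on s increments
    "positivity": 0.0,            # strict positivity pre-depletion
    "extinction_ratio": 1e-3,     # x(horizon) / max x threshold
    "decay_slack": 0.0,           # strictness of post-depletion decay
}


@dataclass(frozen=True)
class TheoremReport:
    """Qualitative-claim flags evaluated on one trajectory.

    Deterministic functions of the trajectory and the recorded tolerances;
    purely diagnostic.  ``s_limit_estimate`` is the empirical limit of the
    substrate (its value at the horizon); ``extinction_ok`` is only
    meaningful when the horizon extends well past the biomass peak.
    """

    positivity_ok: bool
    substrate_monotone_ok: bool
    depletion_implies_decay_ok: bool
    extinction_ok: bool
    s_limit_estimate: float
    x_end_over_x_peak: float
    notes: tuple = ()
    tolerances: dict = field(default_factory=dict)

    @property
    def all_ok(self) -> bool:
        return (
            self.positivity_ok
            and self.substrate_monotone_ok
            and self.depletion_implies_decay_ok
            and self.extinction_ok
        )


def verify_theorems(
    traj: Trajectory, params: ModelParameters, tolerances: Optional[dict] = None
) -> TheoremReport:
    """Check positivity, substrate monotonicity, depletion decay, extinction.

    * positivity — s and x stay strictly positive on the grid before any
      substrate clamp (the regime in which the model provably has a positive
      solution);
    * substrate monotonicity — s is non-increasing throughout;
    * depletion implies decay — once s is clamped at 0, x is strictly
      decreasing (while positive) whenever k1 + k2 > 0: no live growth
      after the nutrient is gone;
    * extinction — with positive total mortality and a horizon well past
      the peak, the final biomass is a negligible fraction of the peak.
    """
    tol = dict(_DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    notes = []
    t = traj._t
    s = traj._s
    x = traj._x
    r = params.mortality_rate

    clamp = traj.meta.get("s_clamp_time")
    x_clamp = traj.meta.get("x_clamp_time")
    if clamp is not None:
        notes.append(f"substrate clamped at t={clamp:.6g}")
    if x_clamp is not None:
        # With strong delayed mortality (k2*tau > 1/e) the pure-decay phase is
        # oscillatory and the biomass genuinely reaches zero in finite time;
        # positivity is guaranteed only up to that first extinction event.
        notes.append(f"biomass reached zero at t={x_clamp:.6g}")
    first_event = min(
        clamp if clamp is not None else math.inf,
        x_clamp if x_clamp is not None else math.inf,
    )
    pre = t < first_event
    positivity_ok = bool(np.all(s[pre] > tol["positivity"]) and np.all(x[pre] > tol["positivity"]))

    substrate_monotone_ok = bool(np.all(np.diff(s) <= tol["substrate_monotone"]))

    if clamp is None or r == 0.0:
        depletion_implies_decay_ok = True
        if clamp is None:
            notes.append("substrate never depleted within the horizon (vacuous decay check)")
        else:
            notes.append("zero total mortality: post-depletion biomass is constant")
    else:
        post = (t > clamp) & (x > 0.0)
        idx = np.flatnonzero(post)
        if idx.size >= 2:
            dx = np.diff(x[idx])
            depletion_implies_decay_ok = bool(np.all(dx < tol["decay_slack"]))
        else:
            depletion_implies_decay_ok = True
            notes.append("biomass already extinct at depletion (vacuous decay check)")

    x_peak = float(np.max(x))
    x_end_ratio = float(x[-1] / x_peak) if x_peak > 0 else math.nan
    # After depletion x(t - tau) >= x(t), so x decays at least like exp(-r t):
    # the ratio test is decidable once the horizon clears the clamp by
    # ln(1/tol)/r.  Shorter horizons cannot refute extinction.
    if r == 0.0:
        extinction_ok = True
        notes.append("zero total mortality: extinction not expected (vacuous)")
    elif x_end_ratio < tol["extinction_ratio"]:
        extinction_ok = True
    elif clamp is not None and t[-1] >= clamp + math.log(1.0 / tol["extinction_ratio"]) / r:
        extinction_ok = False
    else:
        extinction_ok = True
        notes.append("horizon too short past depletion to assess extinction (vacuous)")

    return TheoremReport(
        positivity_ok=positivity_ok,
        substrate_monotone_ok=substrate_monotone_ok,
        depletion_implies_decay_ok=depletion_implies_decay_ok,
        extinction_ok=extinction_ok,
        s_limit_estimate=float(s[-1]),
        x_end_over_x_peak=x_end_ratio,
        notes=tuple(notes),
        tolerances=tol,
    )


def simulate_to_peak(
    params: ModelParameters,
    init: InitialData,
    options: Optional[SolverOptions] = None,
    horizon: Optional[float] = None,
    max_doublings: int = 8,
):
    """Simulate long enough that the biomass peak (if any) lies inside.

    Starts from a growth-time heuristic and doubles the horizon while the
    biomass is still rising at the end.  Returns ``(trajectory, report)``;
    the report is flagged not-found if no interior peak exists (no-growth
    regimes) or the cap is reached.
    """
    if horizon is None:
        horizon = estimate_peak_horizon(params, init)
    traj = simulate(params, init, horizon, options)
    report = find_stationary_onset(traj, params)
    for _ in range(max_doublings):
        if report.found or "decreasing" in report.message:
            break
        horizon *= 2.0
        traj = simulate(params, init, horizon, options)
        report = find_stationary_onset(traj, params)
    return traj, report


def estimate_peak_horizon(params: ModelParameters, init: InitialData) -> float:
    """Heuristic horizon comfortably past the expected biomass peak.

    Time to convert the substrate charge into biomass at the initial net
    growth rate, plus a few delay intervals of margin.  Used as the starting
    guess by :func:`simulate_to_peak` and the CLI default.
    """
    r = params.mortality_rate
    net0 = evaluate_mu(params.growth, init.s0) - r
    x0 = init.x0
    cap = params.gamma * init.s0 + x0
    if net0 > 1e-6:
        t_grow = math.log(cap / x0 + 1.0) / net0
    else:
        t_grow = 1.0 / max(r, 1e-3)
    horizon = 3.0 * t_grow + 5.0 * params.tau + 1.0
    return min(horizon, 1e4)


def estimate_extinction_horizon(
    params: ModelParameters, init: InitialData, ratio: float = 1e-3
) -> float:
    """Horizon long enough for the biomass to decay below ``ratio`` of its peak.

    Past the peak the substrate crashes and the net specific rate approaches
    -(k1 + k2), so the decay tail needs about ln(1/ratio)/(k1 + k2); a 50%
    margin plus a few lifetimes covers the slower transient just after the
    peak.  Requires positive total mortality.
    """
    r = params.mortality_rate
    if r <= 0:
        raise UsageError("extinction requires positive total mortality k1 + k2")
    tail = 1.5 * math.log(1.0 / ratio) / r
    return estimate_peak_horizon(params, init) + tail + 5.0 * params.tau
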