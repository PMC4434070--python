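"""Batch-cultivation dynamics with instantaneous and delayed mortality.

The state is the pair (s, x): nutrient substrate and biomass concentration in
a closed (batch) reactor.  The model is

    s'(t) = -(1/gamma) * mu(s(t)) * x(t)
    x'(t) =  mu(s(t)) * x(t) - k1 * x(t) - k2 * x(t - tau)

with an initial substrate charge ``s(0) = s0`` and a biomass history
``x(t) = phi(t)`` on ``[-tau, 0]`` that is nonnegative, nondecreasing,
continuous and bounded.  ``k1`` removes biomass in proportion to the current
population (unfavourable conditions acting now); ``k2`` removes it in
proportion to the population one average lifetime ``tau`` ago (individuals
born then dying now).

The integrator advances interval-by-interval of length ``tau`` (method of
steps) with a classical fixed-step 4th-order Runge–Kutta scheme whose step
divides ``tau`` exactly, so every delayed lookup lands either on an
already-computed grid node or on the midpoint of an already-computed step
(evaluated by the cubic-Hermite midpoint formula).  A first-order explicit
Euler scheme with a ring buffer (:func:`euler_oracle`) provides an
independent low-tech cross-check for the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from .errors import DomainError, UsageError, ValidationError
from .growth import Family, GrowthModelSpec, evaluate_mu

__all__ = [
    "ModelParameters",
    "History",
    "InitialData",
    "SolverOptions",
    "Trajectory",
    "rhs",
    "simulate",
    "euler_oracle",
    "evaluate_at",
]

HISTORY_KINDS = ("constant", "linear_ramp", "exponential_ramp", "tabular")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the delayed-mortality batch model.

    gamma is the economic (yield) coefficient, g biomass per g substrate;
    k1 and k2 are the instantaneous and delayed specific decay rates (1/h);
    tau is the average lifetime / delay (h).  k2 >= k1 is *not* required.
    With tau = 0 the delayed term acts instantaneously and k1 + k2 lump.
    """

    growth: GrowthModelSpec
    gamma: float
    k1: float = 0.0
    k2: float = 0.0
    tau: float = 0.0

    def __post_init__(self):
        problems = []
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            problems.append(f"gamma must be a positive finite yield, got {self.gamma}")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                problems.append(f"{name} must be a finite rate >= 0, got {v}")
        if not (self.tau >= 0 and math.isfinite(self.tau)):
            problems.append(f"tau must be a finite time >= 0, got {self.tau}")
        if problems:
            raise ValidationError(problems)

    @property
    def mortality_rate(self) -> float:
        """Total specific mortality k1 + k2."""
        return self.k1 + self.k2


class History:
    """Biomass history phi on [-tau, 0]: nonnegative, nondecreasing, continuous.

    Named analytic forms (value x0 at t = 0):

    * ``constant`` — phi(t) = x0;
    * ``linear_ramp`` — affine from x0*(1 - growth_fraction) at -tau to x0;
    * ``exponential_ramp`` — geometric from x0*(1 - growth_fraction) to x0;
    * ``tabular`` — monotone (PCHIP) interpolation of nondecreasing knots.
    """

    def __init__(self, kind, x0=None, tau=0.0, growth_fraction=0.0, knots=None):
        problems = []
        if kind not in HISTORY_KINDS:
            problems.append(f"history kind must be one of {HISTORY_KINDS}, got {kind!r}")
            raise ValidationError(problems)
        if not (tau >= 0 and math.isfinite(tau)):
            problems.append(f"tau must be a finite time >= 0, got {tau}")
        if kind == "tabular":
            if not knots:
                problems.append("tabular history requires knots")
            else:
                knots = tuple((float(t), float(x)) for t, x in knots)
                ts = [t for t, _ in knots]
                xs = [x for _, x in knots]
                if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
                    problems.append("tabular knot times must be strictly increasing")
                if abs(ts[0] + tau) > 1e-12 * max(tau, 1.0) or abs(ts[-1]) > 1e-12:
                    problems.append("tabular knots must span exactly [-tau, 0]")
                if any(x2 < x1 for x1, x2 in zip(xs, xs[1:])):
                    problems.append("tabular history must be nondecreasing (condition on phi)")
                if any(x < 0 for x in xs):
                    problems.append("history values must be >= 0")
                if xs and not xs[-1] > 0:
                    problems.append("history must end positive: phi(0) > 0")
                if x0 is None:
                    x0 = xs[-1] if xs else None
                elif xs and abs(x0 - xs[-1]) > 1e-12 * max(abs(x0), 1.0):
                    problems.append("x0 inconsistent with the last tabular knot")
        else:
            if knots is not None:
                problems.append(f"knots are only valid for tabular histories, not {kind!r}")
            if x0 is None or not (x0 > 0 and math.isfinite(x0)):
                problems.append(f"x0 must be a positive finite biomass, got {x0}")
            g = growth_fraction
            if not (0.0 <= g <= 1.0) or (kind == "exponential_ramp" and g >= 1.0):
                problems.append(
                    "growth_fraction must lie in [0, 1] (strictly below 1 for "
                    f"exponential_ramp), got {g}"
                )
        if problems:
            raise ValidationError(problems)
        self.kind = kind
        self.x0 = float(x0)
        self.tau = float(tau)
        self.growth_fraction = float(growth_fraction)
        self.knots = knots if kind == "tabular" else None
        self._pchip = None
        if kind == "tabular" and len(self.knots) >= 2:
            self._pchip = PchipInterpolator(
                [t for t, _ in self.knots], [x for _, x in self.knots]
            )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tol = 1e-9 * max(self.tau, 1.0)
        if np.any(t < -self.tau - tol) or np.any(t > tol):
            raise DomainError(f"history is defined on [-{self.tau}, 0] only")
        t = np.clip(t, -self.tau, 0.0)
        if self.kind == "constant" or self.tau == 0.0:
            out = np.full_like(t, self.x0)
        elif self.kind == "linear_ramp":
            out = self.x0 * (1.0 + self.growth_fraction * t / self.tau)
        elif self.kind == "exponential_ramp":
            out = self.x0 * (1.0 - self.growth_fraction) ** (-t / self.tau)
        else:
            out = self._pchip(t) if self._pchip is not None else np.full_like(t, self.x0)
        return float(out) if out.ndim == 0 else out

    def __repr__(self):
        return (
            f"History(kind={self.kind!r}, x0={self.x0}, tau={self.tau}, "
            f"growth_fraction={self.growth_fraction})"
        )


@dataclass(frozen=True)
class InitialData:
    """Initial substrate charge s0 plus the biomass history on [-tau, 0]."""

    s0: float
    history: Callable[[float], float]

    def __post_init__(self):
        problems = []
        if not (self.s0 > 0 and math.isfinite(self.s0)):
            problems.append(f"s0 must be a positive finite concentration, got {self.s0}")
        try:
            x_at_zero = float(self.history(0.0))
        except Exception as exc:  # noqa: BLE001 - reported as a validation problem
            problems.append(f"history is not evaluable at t=0: {exc}")
        else:
            if not x_at_zero > 0:
                problems.append(f"history(0) must be > 0, got {x_at_zero}")
        if problems:
            raise ValidationError(problems)

    @property
    def x0(self) -> float:
        return float(self.history(0.0))


@dataclass(frozen=True)
class SolverOptions:
    """Fixed-step solver settings.

    ``h`` — requested step; rounded to the nearest divisor of tau when
    tau > 0 (a note is recorded in the trajectory meta when adjusted).
    ``steps_per_delay`` — default step count per delay interval when ``h``
    is not given.  ``interpolation`` — dense-output order ('cubic' Hermite,
    matching the scheme's local accuracy, or 'linear').
    """

    h: Optional[float] = None
    steps_per_delay: int = 64
    interpolation: str = "cubic"

    def __post_init__(self):
        problems = []
        if self.h is not None and not (self.h > 0 and math.isfinite(self.h)):
            problems.append(f"step h must be > 0, got {self.h}")
        if self.steps_per_delay < 1:
            problems.append(f"steps_per_delay must be >= 1, got {self.steps_per_delay}")
        if self.interpolation not in ("cubic", "linear"):
            problems.append(f"interpolation must be 'cubic' or 'linear', got {self.interpolation!r}")
        if problems:
            raise ValidationError(problems)


@dataclass
class Trajectory:
    """Numerical solution (t, s(t), x(t)) including the history segment.

    ``times``/``s_values``/``x_values`` cover the grid from -tau to the
    horizon; on t < 0 the convention s = s0 holds (the model constrains only
    the biomass history).  ``evaluate_at`` provides continuous dense output
    that matches grid values exactly at the nodes.
    """

    times: np.ndarray
    s_values: np.ndarray
    x_values: np.ndarray
    params: ModelParameters
    s0: float
    history: Callable[[float], float]
    meta: dict
    # node data on [0, horizon] backing the dense output
    _t: np.ndarray = field(repr=False, default=None)
    _s: np.ndarray = field(repr=False, default=None)
    _x: np.ndarray = field(repr=False, default=None)
    _fs: np.ndarray = field(repr=False, default=None)
    _fx: np.ndarray = field(repr=False, default=None)
    _splines: tuple = field(repr=False, default=None)

    @property
    def tau(self) -> float:
        return self.params.tau

    @property
    def horizon(self) -> float:
        return float(self._t[-1])

    def _build_splines(self):
        if self._splines is None:
            if self.meta.get("interpolation") == "linear":
                s_sp = lambda t: np.interp(t, self._t, self._s)
                x_sp = lambda t: np.interp(t, self._t, self._x)
            else:
                s_sp = CubicHermiteSpline(self._t, self._s, self._fs)
                x_sp = CubicHermiteSpline(self._t, self._x, self._fx)
            self._splines = (s_sp, x_sp)
        return self._splines

    def evaluate_at(self, t: float):
        """Dense output: (s, x) at any t in [-tau, horizon]."""
        tau, hor = self.tau, self.horizon
        tol = 1e-9 * max(hor, 1.0)
        if t < -tau - tol or t > hor + tol:
            raise DomainError(f"t={t} outside the trajectory range [-{tau}, {hor}]")
        t = min(max(t, -tau), hor)
        if t < 0.0:
            return self.s0, float(self.history(t))
        s_sp, x_sp = self._build_splines()
        return max(float(s_sp(t)), 0.0), max(float(x_sp(t)), 0.0)

    def to_csv(self, path):
        """Write the grid (history rows included) as ``t,s,x`` at 17 digits."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("t,s,x\n")
            for t, s, x in zip(self.times, self.s_values, self.x_values):
                fh.write(f"{t:.17g},{s:.17g},{x:.17g}\n")

    @property
    def s_clamp_time(self):
        return self.meta.get("s_clamp_time")


def evaluate_at(traj: Trajectory, t: float):
    """Module-level alias for :meth:`Trajectory.evaluate_at`."""
    return traj.evaluate_at(t)


def rhs(params: ModelParameters, s: float, x: float, x_delayed: float):
    """Right-hand side of the model at a single state.

    Returns ``(ds_dt, dx_dt)`` = ``(-(1/gamma) mu(s) x,
    mu(s) x - k1 x - k2 x_delayed)``.
    """
    if s < 0 or x < 0 or x_delayed < 0:
        raise DomainError("s, x and x_delayed must all be >= 0")
    m = evaluate_mu(params.growth, s)
    return (-m * x / params.gamma, m * x - params.k1 * x - params.k2 * x_delayed)


def _mu_scalar(spec: GrowthModelSpec):
    """Fast scalar closure for mu(s) used inside the integration loops."""
    mu_max, k_s = spec.mu_max, spec.k_s
    fam = spec.family
    if fam is Family.MONOD:
        return lambda s: mu_max * s / (k_s + s)
    k_i = spec.k_i
    if fam is Family.HALDANE:
        return lambda s: mu_max * s / (k_s + s + s * s / k_i)
    if fam is Family.ANDREWS:
        return lambda s: mu_max * s / ((k_s + s) * (1.0 + s / k_i))
    beta = spec.beta
    return lambda s: mu_max * s * (1.0 + beta * s / k_i) / (k_s + s + s * s / k_i)


def _validate_history(history, tau: float):
    """Enforce the history conditions (nonnegative, nondecreasing, bounded)."""
    h_tau = getattr(history, "tau", None)
    if h_tau is not None and abs(h_tau - tau) > 1e-9 * max(tau, 1.0):
        raise ValidationError(
            [f"history is defined on [-{h_tau}, 0] but the model delay is tau={tau}"]
        )
    if isinstance(history, History) or tau == 0.0:
        return
    ts = np.linspace(-tau, 0.0, 257)
    vals = np.array([float(history(t)) for t in ts])
    problems = []
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        problems.append("history must be finite and >= 0 on [-tau, 0]")
    if np.any(np.diff(vals) < -1e-12 * max(vals.max(initial=1.0), 1.0)):
        problems.append("history must be nondecreasing on [-tau, 0]")
    if problems:
        raise ValidationError(problems)


def _grid_counts(tau, horizon, options):
    """Resolve (h, steps per delay n, total steps N, adjusted?) for the grid."""
    adjusted = False
    if tau > 0:
        if options.h is not None:
            n = max(1, round(tau / options.h))
            adjusted = abs(n * options.h - tau) > 1e-12 * tau
        else:
            n = options.steps_per_delay
        h = tau / n
    else:
        n = 0
        h = options.h if options.h is not None else horizon / 1e4
    N = max(1, math.ceil(horizon / h - 1e-9))
    return h, n, N, adjusted


def simulate(
    params: ModelParameters,
    init: InitialData,
    horizon: float,
    options: Optional[SolverOptions] = None,
) -> Trajectory:
    """Integrate the model by the method of steps (fixed-step RK4).

    The step divides tau exactly, so the delayed biomass x(t - tau) needed by
    the Runge–Kutta stages is read off already-computed nodes (or the exact
    history on the first delay interval); stage midpoints use the cubic
    Hermite midpoint formula on the previous interval.  If the substrate
    reaches zero it is clamped there (mu(0) = 0 keeps it at zero exactly) and
    the event time is recorded; the biomass then follows pure decay.
    """
    if options is None:
        options = SolverOptions()
    if not (horizon > 0 and math.isfinite(horizon)):
        raise ValidationError([f"horizon must be a positive finite time, got {horizon}"])
    tau = params.tau
    _validate_history(init.history, tau)
    if tau > 0 and horizon <= tau:
        raise ValidationError([f"horizon ({horizon}) must exceed the delay tau ({tau})"])

    h, n, N, adjusted = _grid_counts(tau, horizon, options)
    mu = _mu_scalar(params.growth)
    phi = init.history
    inv_g = 1.0 / params.gamma
    a1, a2 = params.k1, params.k2
    lumped = a1 + a2  # tau = 0: delayed term applied instantaneously

    s = np.empty(N + 1)
    x = np.empty(N + 1)
    fs = np.empty(N + 1)
    fx = np.empty(N + 1)
    s[0] = init.s0
    x[0] = float(phi(0.0))
    s_clamp_time = None
    x_clamp_time = None

    def node_derivs(i, si, xi):
        m = mu(si)
        if n:
            j = i - n
            d = float(phi(j * h)) if j < 0 else x[j]
            dx = m * xi - a1 * xi - a2 * d
        else:
            dx = m * xi - lumped * xi
        if xi == 0.0 and dx < 0.0:
            dx = 0.0  # biomass is held at zero: no regrowth from extinction
        return -inv_g * m * xi, dx

    fs[0], fx[0] = node_derivs(0, s[0], x[0])

    def lookup_x(tq):
        """Biomass at an arbitrary past time: history or cubic Hermite on nodes."""
        if tq <= 0.0:
            return float(phi(tq if tq >= -tau else -tau))
        j = int(tq / h)
        th = tq / h - j
        if th == 0.0:
            return x[j]
        h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
        h10 = th * (1.0 - th) ** 2
        h01 = th * th * (3.0 - 2.0 * th)
        h11 = th * th * (th - 1.0)
        return h00 * x[j] + h * h10 * fx[j] + h01 * x[j + 1] + h * h11 * fx[j + 1]

    def refine_crossing(i, si, xi, nsub=64):
        """Redo step i with fine sub-steps to resolve a clamp event sharply.

        The depletion/extinction clamps kink the right-hand side; integrating
        through the kink at the full step costs O(h) locally, so the crossing
        step alone is re-integrated at h/nsub with interpolated delayed
        lookups.  Returns (s_end, x_end, s_clamp_t, x_clamp_t).
        """
        hq = h / nsub
        halfq, sixthq = 0.5 * hq, hq / 6.0
        sq, xq = si, xi
        sct = xct = None
        for k in range(nsub):
            tq = (i + k / nsub) * h
            if xq == 0.0:
                continue  # frozen: extinct biomass, constant substrate
            if n:
                d0 = lookup_x(tq - tau)
                dm = lookup_x(tq + halfq - tau)
                d1 = lookup_x(tq + hq - tau)
            m1 = mu(sq if sq > 0.0 else 0.0)
            k1s = -inv_g * m1 * xq
            k1x = m1 * xq - a1 * xq - a2 * (d0 if n else xq)
            s2 = sq + halfq * k1s
            x2 = xq + halfq * k1x
            m2 = mu(s2 if s2 > 0.0 else 0.0)
            k2s = -inv_g * m2 * (x2 if x2 > 0.0 else 0.0)
            k2x = m2 * x2 - a1 * x2 - a2 * (dm if n else x2)
            s3 = sq + halfq * k2s
            x3 = xq + halfq * k2x
            m3 = mu(s3 if s3 > 0.0 else 0.0)
            k3s = -inv_g * m3 * (x3 if x3 > 0.0 else 0.0)
            k3x = m3 * x3 - a1 * x3 - a2 * (dm if n else x3)
            s4 = sq + hq * k3s
            x4 = xq + hq * k3x
            m4 = mu(s4 if s4 > 0.0 else 0.0)
            k4s = -inv_g * m4 * (x4 if x4 > 0.0 else 0.0)
            k4x = m4 * x4 - a1 * x4 - a2 * (d1 if n else x4)
            s_nw = sq + sixthq * (k1s + 2.0 * (k2s + k3s) + k4s)
            x_nw = xq + sixthq * (k1x + 2.0 * (k2x + k3x) + k4x)
            if s_nw <= 0.0:
                if sct is None:
                    frac = sq / (sq - s_nw) if s_nw < sq else 1.0
                    sct = tq + frac * hq
                s_nw = 0.0
            if x_nw < 0.0:
                if xct is None:
                    xct = tq + hq
                x_nw = 0.0
            sq, xq = s_nw, x_nw
        return sq, xq, sct, xct

    sixth = h / 6.0
    half = 0.5 * h
    for i in range(N):
        si = s[i]
        xi = x[i]
        if xi == 0.0:
            # extinct biomass cannot regrow (dx = -k2*x_delayed <= 0, held at
            # zero) and consumes nothing: the state is frozen exactly
            s[i + 1] = si
            x[i + 1] = 0.0
            fs[i + 1] = 0.0
            fx[i + 1] = 0.0
            continue
        if n:
            j = i - n
            if j < 0:
                d0 = float(phi(j * h))
                dm = float(phi((j + 0.5) * h))
            else:
                d0 = x[j]
                dm = 0.5 * (x[j] + x[j + 1]) + 0.125 * h * (fx[j] - fx[j + 1])
            jj = j + 1
            d1 = float(phi(jj * h)) if jj < 0 else x[jj]
        else:
            d0 = dm = d1 = None  # instantaneous: stage x itself is used

        m1 = mu(si if si > 0.0 else 0.0)
        k1s = -inv_g * m1 * xi
        k1x = m1 * xi - a1 * xi - a2 * (d0 if n else xi)

        s2 = si + half * k1s
        x2 = xi + half * k1x
        m2 = mu(s2 if s2 > 0.0 else 0.0)
        # stage biomass can dip below zero near the extinction crossing; the
        # substrate-consumption term must not change sign there
        k2s = -inv_g * m2 * (x2 if x2 > 0.0 else 0.0)
        k2x = m2 * x2 - a1 * x2 - a2 * (dm if n else x2)

        s3 = si + half * k2s
        x3 = xi + half * k2x
        m3 = mu(s3 if s3 > 0.0 else 0.0)
        k3s = -inv_g * m3 * (x3 if x3 > 0.0 else 0.0)
        k3x = m3 * x3 - a1 * x3 - a2 * (dm if n else x3)

        s4 = si + h * k3s
        x4 = xi + h * k3x
        m4 = mu(s4 if s4 > 0.0 else 0.0)
        k4s = -inv_g * m4 * (x4 if x4 > 0.0 else 0.0)
        k4x = m4 * x4 - a1 * x4 - a2 * (d1 if n else x4)

        s_new = si + sixth * (k1s + 2.0 * (k2s + k3s) + k4s)
        x_new = xi + sixth * (k1x + 2.0 * (k2x + k3x) + k4x)

        if s_new <= 0.0 or x_new < 0.0:
            s_new, x_new, sct, xct = refine_crossing(i, si, xi)
            if sct is not None and s_clamp_time is None:
                s_clamp_time = sct
            if xct is not None and x_clamp_time is None:
                x_clamp_time = xct
        s[i + 1] = s_new
        x[i + 1] = x_new
        fs[i + 1], fx[i + 1] = node_derivs(i + 1, s_new, x_new)

    return _assemble(
        params, init, h, n, N, s, x, fs, fx,
        meta={
            "scheme": "rk4-method-of-steps",
            "h": h,
            "steps_per_delay": n,
            "n_steps": N,
            "requested_horizon": horizon,
            "h_adjusted_to_divide_tau": adjusted,
            "interpolation": options.interpolation,
            "s_clamp_time": s_clamp_time,
            "x_clamp_time": x_clamp_time,
        },
    )


def euler_oracle(
    params: ModelParameters, init: InitialData, horizon: float, h: float
) -> Trajectory:
    """Explicit fixed-step first-order integrator with a delayed ring buffer.

    Deliberately low-tech: a single-line Euler update whose delayed lookup is
    a plain buffer index, sharing no code with the production stepper.  Used
    as the independent oracle in tests; ``tau / h`` must be integral.
    """
    tau = params.tau
    if not (h > 0 and math.isfinite(h)):
        raise UsageError(f"step h must be > 0, got {h}")
    m = 0
    if tau > 0:
        m = round(tau / h)
        if m < 1 or abs(m * h - tau) > 1e-9 * tau:
            raise UsageError(f"tau/h must be integral for the Euler oracle (tau={tau}, h={h})")
    _validate_history(init.history, tau)

    mu = _mu_scalar(params.growth)
    phi = init.history
    inv_g = 1.0 / params.gamma
    a1, a2 = params.k1, params.k2
    N = max(1, math.ceil(horizon / h - 1e-9))

    s = np.empty(N + 1)
    x = np.empty(N + 1)
    s[0] = init.s0
    xi = float(phi(0.0))
    x[0] = xi
    si = s[0]
    s_clamp_time = None
    x_clamp_time = None
    for i in range(N):
        if m:
            j = i - m
            d = float(phi(j * h)) if j < 0 else x[j]
        else:
            d = xi
        g = mu(si) if si > 0.0 else 0.0
        gx = g * xi
        s_new = si - h * inv_g * gx
        x_new = xi + h * (gx - a1 * xi - a2 * d)
        if s_new <= 0.0:
            if s_clamp_time is None:
                s_clamp_time = (i + 1) * h
            s_new = 0.0
        if x_new < 0.0:
            if x_clamp_time is None:
                x_clamp_time = (i + 1) * h
            x_new = 0.0
        si = s_new
        xi = x_new
        s[i + 1] = si
        x[i + 1] = xi

    # node derivatives for the dense-output contract, vectorized post-pass
    mu_nodes = evaluate_mu(params.growth, s)
    prod = mu_nodes * x
    if m:
        xdel = np.empty(N + 1)
        k = min(m, N + 1)
        xdel[:k] = [float(phi(max(i * h - tau, -tau))) for i in range(k)]
        if k <= N:
            xdel[k:] = x[: N + 1 - m]
    else:
        xdel = x
    fs = -inv_g * prod
    fx = prod - a1 * x - a2 * xdel
    fx[(x == 0.0) & (fx < 0.0)] = 0.0
    return _assemble(
        params, init, h, m, N, s, x, fs, fx,
        meta={
            "scheme": "euler-oracle",
            "h": h,
            "steps_per_delay": m,
            "n_steps": N,
            "requested_horizon": horizon,
            "h_adjusted_to_divide_tau": False,
            "interpolation": "cubic",
            "s_clamp_time": s_clamp_time,
            "x_clamp_time": x_clamp_time,
        },
    )


def _assemble(params, init, h, n, N, s, x, fs, fx, meta) -> Trajectory:
    """Attach the history segment and build the Trajectory record."""
    t_main = np.arange(N + 1) * h
    if n:
        t_hist = (np.arange(n) - n) * h  # [-tau, 0), t = 0 belongs to the main grid
        x_hist = np.array([float(init.history(t)) for t in t_hist])
        times = np.concatenate([t_hist, t_main])
        s_vals = np.concatenate([np.full(n, init.s0), s])
        x_vals = np.concatenate([x_hist, x])
    else:
        times, s_vals, x_vals = t_main, s, x
    return Trajectory(
        times=times,
        s_values=s_vals,
        x_values=x_vals,
        params=params,
        s0=init.s0,
        history=init.history,
        meta=meta,
        _t=t_main,
        _s=s,
        _x=x,
        _fs=fs,
        _fx=fx,
    )
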