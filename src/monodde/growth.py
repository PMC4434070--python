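"""Specific growth-rate functions mu(s) for substrate-limited microbial growth.

Four classical families are supported:

* **Monod** — ``mu(s) = mu_max * s / (k_s + s)``: saturating, strictly
  increasing, approaches ``mu_max`` asymptotically.
* **Haldane** — ``mu(s) = mu_max * s / (k_s + s + s**2 / k_i)``: substrate
  inhibition; unimodal with maximizer ``sqrt(k_s * k_i)``.
* **Andrews** — ``mu(s) = mu_max * s / ((k_s + s) * (1 + s / k_i))``:
  substrate inhibition; unimodal with the same maximizer ``sqrt(k_s * k_i)``.
* **Webb** — ``mu(s) = mu_max * s * (1 + beta * s / k_i) /
  (k_s + s + s**2 / k_i)``: interpolates between Haldane (``beta = 0``) and a
  monotone saturating shape; unimodal exactly when the derivative is
  ultimately negative, which for this form means ``beta < 1``.

``s`` is a substrate concentration (g/L), rates are per hour.  All families
satisfy ``mu(0) = 0`` and ``mu(s) > 0`` for ``s > 0``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, UnattainableRateError, UsageError, ValidationError

__all__ = [
    "Family",
    "GrowthModelSpec",
    "GrowthWindow",
    "evaluate_mu",
    "mu_prime",
    "mu_limit_at_infinity",
    "is_unimodal",
    "growth_supremum",
    "invert_mu",
    "growth_window",
]

# Relative guard used to classify a rate as unattainable deterministically.
_SUP_GUARD = 1e-12
# Absolute tolerance on s for bracketed root finding.
_ROOT_XTOL = 1e-12


class Family(str, enum.Enum):
    MONOD = "monod"
    HALDANE = "haldane"
    ANDREWS = "andrews"
    WEBB = "webb"


_INHIBITED = (Family.HALDANE, Family.ANDREWS, Family.WEBB)


@dataclass(frozen=True)
class GrowthModelSpec:
    """A mu(s) family together with its kinetic constants.

    Parameters
    ----------
    family
        One of :class:`Family` (or its string value).
    mu_max
        Maximal specifically possible producing rate (1/h), > 0.
    k_s
        Half-saturation constant (g/L), > 0.
    k_i
        Inhibition constant (g/L); required for haldane/andrews/webb and
        must be absent for monod.
    beta
        Dimensionless shape parameter, webb only, >= 0.
    """

    family: Family
    mu_max: float
    k_s: float
    k_i: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "family", Family(self.family))
        problems = []
        if not (self.mu_max > 0 and math.isfinite(self.mu_max)):
            problems.append(f"mu_max must be a positive finite rate, got {self.mu_max}")
        if not (self.k_s > 0 and math.isfinite(self.k_s)):
            problems.append(f"k_s must be a positive finite concentration, got {self.k_s}")
        if self.family in _INHIBITED:
            if self.k_i is None or not (self.k_i > 0 and math.isfinite(self.k_i)):
                problems.append(
                    f"k_i must be a positive finite concentration for {self.family.value}, got {self.k_i}"
                )
        elif self.k_i is not None:
            problems.append("k_i is not a monod parameter")
        if self.family is Family.WEBB:
            if self.beta is None or not (self.beta >= 0 and math.isfinite(self.beta)):
                problems.append(f"beta must be >= 0 for webb, got {self.beta}")
        elif self.beta is not None:
            problems.append(f"beta is only a webb parameter, not valid for {self.family.value}")
        if problems:
            raise ValidationError(problems)


def evaluate_mu(spec: GrowthModelSpec, s):
    """Evaluate mu(s); accepts a scalar or an ndarray of concentrations >= 0."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DomainError("substrate concentration s must be >= 0")
    mu_max, k_s = spec.mu_max, spec.k_s
    fam = spec.family
    if fam is Family.MONOD:
        out = mu_max * s / (k_s + s)
    elif fam is Family.HALDANE:
        out = mu_max * s / (k_s + s + s * s / spec.k_i)
    elif fam is Family.ANDREWS:
        out = mu_max * s / ((k_s + s) * (1.0 + s / spec.k_i))
    else:  # webb
        k_i = spec.k_i
        out = mu_max * s * (1.0 + spec.beta * s / k_i) / (k_s + s + s * s / k_i)
    return float(out) if out.ndim == 0 else out


def mu_prime(spec: GrowthModelSpec, s):
    """Closed-form derivative d mu/d s (same broadcasting as evaluate_mu)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise DomainError("substrate concentration s must be >= 0")
    mu_max, k_s = spec.mu_max, spec.k_s
    fam = spec.family
    if fam is Family.MONOD:
        out = mu_max * k_s / (k_s + s) ** 2
    elif fam is Family.HALDANE:
        den = k_s + s + s * s / spec.k_i
        out = mu_max * (k_s - s * s / spec.k_i) / den**2
    elif fam is Family.ANDREWS:
        k_i = spec.k_i
        out = mu_max * k_i * (k_s * k_i - s * s) / ((k_s + s) ** 2 * (k_i + s) ** 2)
    else:  # webb
        k_i, beta = spec.k_i, spec.beta
        num = s + beta * s * s / k_i
        dnum = 1.0 + 2.0 * beta * s / k_i
        den = k_s + s + s * s / k_i
        dden = 1.0 + 2.0 * s / k_i
        out = mu_max * (dnum * den - num * dden) / den**2
    return float(out) if out.ndim == 0 else out


def mu_limit_at_infinity(spec: GrowthModelSpec) -> float:
    """lim_{s->inf} mu(s): mu_max (monod), 0 (haldane/andrews), mu_max*beta (webb)."""
    if spec.family is Family.MONOD:
        return spec.mu_max
    if spec.family is Family.WEBB:
        return spec.mu_max * spec.beta
    return 0.0


def is_unimodal(spec: GrowthModelSpec) -> bool:
    """Whether mu has a single interior maximizer (vs being monotone).

    Detected numerically from the sign of mu'(s) far out on the s axis, so a
    change in the webb regime condition is picked up automatically rather
    than relying on a hard-coded beta threshold.
    """
    if spec.family is Family.MONOD:
        return False
    if spec.family in (Family.HALDANE, Family.ANDREWS):
        return True
    s_far = 1e9 * max(spec.k_s, spec.k_i)
    return mu_prime(spec, s_far) < 0.0


def growth_supremum(spec: GrowthModelSpec):
    """Return ``(s_at_max, mu_sup)``.

    Monotone families return ``(inf, asymptotic supremum)`` — the supremum is
    not attained.  Unimodal families return the interior maximizer and the
    attained maximum.
    """
    fam = spec.family
    if fam is Family.MONOD:
        return math.inf, spec.mu_max
    if fam in (Family.HALDANE, Family.ANDREWS):
        s_star = math.sqrt(spec.k_s * spec.k_i)
        return s_star, evaluate_mu(spec, s_star)
    # webb
    if not is_unimodal(spec):
        return math.inf, mu_limit_at_infinity(spec)
    # bracket the zero of mu' : positive at 0+, negative far out
    lo = 1e-12 * spec.k_s
    hi = max(spec.k_s, spec.k_i)
    while mu_prime(spec, hi) > 0:
        hi *= 2.0
        if hi > 1e15 * max(spec.k_s, spec.k_i):  # pragma: no cover - guarded by is_unimodal
            return math.inf, mu_limit_at_infinity(spec)
    s_star = brentq(lambda s: mu_prime(spec, s), lo, hi, xtol=_ROOT_XTOL, rtol=8.9e-16)
    return s_star, evaluate_mu(spec, s_star)


def _quadratic_roots(a: float, b: float, c: float):
    """Roots of a*s^2 + b*s + c = 0, numerically stable, ascending order."""
    disc = b * b - 4.0 * a * c
    if disc < 0:
        if disc > -1e-12 * max(b * b, abs(4.0 * a * c)):
            disc = 0.0
        else:
            raise UnattainableRateError("rate exceeds the maximum of mu on this family")
    sq = math.sqrt(disc)
    # b < 0 for attainable rates here; avoid cancellation in the small root
    q = -0.5 * (b - sq) if b < 0 else -0.5 * (b + sq)
    r1, r2 = q / a, c / q
    return (r2, r1) if r2 <= r1 else (r1, r2)


def _inversion_quadratic(spec: GrowthModelSpec, r: float):
    """Coefficients (a, b, c) of the quadratic mu(s) = r for haldane/andrews."""
    if spec.family is Family.HALDANE:
        return r / spec.k_i, r - spec.mu_max, r * spec.k_s
    # andrews: r*(k_s+s)*(1+s/k_i) = mu_max*s
    return r / spec.k_i, r * (1.0 + spec.k_s / spec.k_i) - spec.mu_max, r * spec.k_s


def invert_mu(spec: GrowthModelSpec, r: float, branch: str = "ascending") -> float:
    """Solve mu(s) = r for s on the requested monotone branch.

    ``branch="descending"`` is only meaningful for unimodal families, and
    only for rates above the s -> inf limit of mu (below it the descending
    branch never comes back down to r).
    """
    if branch not in ("ascending", "descending"):
        raise UsageError(f"branch must be 'ascending' or 'descending', got {branch!r}")
    if not r > 0:
        raise DomainError(f"rate r must be > 0, got {r}")
    unimodal = is_unimodal(spec)
    if branch == "descending" and not unimodal:
        raise UsageError(f"{spec.family.value} is monotone here: no descending branch")
    s_star, mu_sup = growth_supremum(spec)
    if r >= mu_sup * (1.0 - _SUP_GUARD):
        raise UnattainableRateError(
            f"rate {r} is at or above the supremum {mu_sup} of mu; unattainable"
        )

    fam = spec.family
    if fam is Family.MONOD:
        return spec.k_s * r / (spec.mu_max - r)
    if fam in (Family.HALDANE, Family.ANDREWS):
        lo, hi = _quadratic_roots(*_inversion_quadratic(spec, r))
        return lo if branch == "ascending" else hi

    # webb: bracketed root finding on the requested monotone branch
    f = lambda s: evaluate_mu(spec, s) - r
    if branch == "ascending":
        hi = s_star if unimodal else max(spec.k_s, spec.k_i)
        if not unimodal:
            while f(hi) < 0:
                hi *= 2.0
        return brentq(f, 0.0, hi, xtol=_ROOT_XTOL, rtol=8.9e-16)
    if r <= mu_limit_at_infinity(spec) * (1.0 + _SUP_GUARD):
        raise UnattainableRateError(
            f"rate {r} is not attained on the descending branch (mu tends to "
            f"{mu_limit_at_infinity(spec)} at large s)"
        )
    hi = 2.0 * s_star
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, s_star, hi, xtol=_ROOT_XTOL, rtol=8.9e-16)


@dataclass(frozen=True)
class GrowthWindow:
    """The substrate interval on which mu(s) strictly exceeds a mortality rate.

    ``lower`` is the minimal substrate concentration sustaining increasing
    reproduction; ``upper`` is ``inf`` for monotone families (and for
    unimodal families whose tail stays above the rate).  ``empty`` flags the
    no-growth classification: the rate is at or above the supremum of mu.
    """

    lower: Optional[float]
    upper: Optional[float]
    empty: bool
    mortality_rate: float

    def contains(self, s: float) -> bool:
        if self.empty:
            return False
        return self.lower < s < self.upper


def growth_window(spec: GrowthModelSpec, r: float) -> GrowthWindow:
    """Return ``{s : mu(s) > r}`` as an interval (possibly empty)."""
    if r < 0:
        raise DomainError(f"rate r must be >= 0, got {r}")
    if r == 0.0:
        return GrowthWindow(lower=0.0, upper=math.inf, empty=False, mortality_rate=0.0)
    _, mu_sup = growth_supremum(spec)
    if r >= mu_sup * (1.0 - _SUP_GUARD):
        return GrowthWindow(lower=None, upper=None, empty=True, mortality_rate=r)
    lower = invert_mu(spec, r, "ascending")
    if not is_unimodal(spec) or r <= mu_limit_at_infinity(spec) * (1.0 + _SUP_GUARD):
        upper = math.inf
    else:
        upper = invert_mu(spec, r, "descending")
    return GrowthWindow(lower=lower, upper=upper, empty=False, mortality_rate=r)
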