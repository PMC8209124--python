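"""Deterministic demographic math for the five-parameter Siler mortality model.

The Siler hazard combines a declining infant/juvenile hazard, a constant
age-independent hazard, and an exponentially increasing senescent hazard:

    mu(x) = exp(a0 - a1*x) + c + exp(b0 + b1*x),   x >= 0

with a0, b0 real and a1, c, b1 >= 0.  From the hazard we derive the
cumulative hazard U, survival S = exp(-U), the density of ages at death
f = mu*S, life expectancy at birth e = int_0^inf S dx, lifespan inequality
H (Keyfitz entropy) and lifespan equality eps = -log(H).

All ages are in years and all hazards per year.  Improper integrals are
truncated at an upper age where survival is numerically negligible; the
truncation point is either supplied explicitly or found adaptively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import integrate

__all__ = [
    "SilerParams",
    "QuadratureConfig",
    "PaceShapeSummary",
    "QuadratureError",
    "PARAM_NAMES",
    "hazard",
    "cumulative_hazard",
    "survival",
    "death_density",
    "life_expectancy",
    "remaining_life_expectancy",
    "lifespan_inequality",
    "lifespan_equality",
    "pace_shape_summary",
]

#: canonical ordering of the Siler parameters
PARAM_NAMES = ("a0", "a1", "c", "b0", "b1")

# below this, a1 or b1 is treated as exactly zero and the analytic limit
# of the closed-form cumulative hazard (e^{a0}*x, e^{b0}*x) is used
_SMALL = 1e-12


class QuadratureError(RuntimeError):
    """Raised when an improper integral cannot be truncated reliably."""


@dataclass(frozen=True)
class SilerParams:
    """The five Siler mortality parameters.

    a0 : log initial infant hazard (real)
    a1 : decline rate of the infant hazard, per year (>= 0)
    c  : age-independent hazard, per year (>= 0)
    b0 : log initial senescent hazard (real)
    b1 : rate of ageing, per year (>= 0)
    """

    a0: float
    a1: float
    c: float
    b0: float
    b1: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        for name in ("a1", "c", "b1"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"parameter {name} must be non-negative, got {getattr(self, name)}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.c, self.b0, self.b1])

    @classmethod
    def from_array(cls, arr) -> "SilerParams":
        a0, a1, c, b0, b1 = (float(v) for v in arr)
        return cls(a0, a1, c, b0, b1)

    def replace(self, **kwargs) -> "SilerParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class QuadratureConfig:
    """Numerical settings for the improper demographic integrals.

    upper_age : explicit truncation age in years, or None to choose it
        adaptively (doubling until ``survival < surv_tol``, capped at
        ``max_upper``).
    abs_tol, rel_tol : adaptive-quadrature tolerances; ``abs_tol`` is also
        the hard ceiling on the survival remaining at the truncation age.
    surv_tol : survival level targeted by the adaptive truncation.
    max_upper : cap on the adaptive truncation age, years.
    """

    upper_age: Optional[float] = None
    abs_tol: float = 1e-10
    rel_tol: float = 1e-8
    surv_tol: float = 1e-12
    max_upper: float = 200.0


#: default quadrature settings shared across the package
DEFAULT_QUAD = QuadratureConfig()


@dataclass(frozen=True)
class PaceShapeSummary:
    """Pace (life expectancy) and shape (equality) of a mortality schedule."""

    e: float
    H: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (self.e > 0 and self.H > 0):
            raise ValueError("life expectancy and lifespan inequality must be positive")
        if not math.isclose(self.epsilon, -math.log(self.H), rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("epsilon must equal -log(H)")


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    return x


def hazard(params: SilerParams, x):
    """Siler hazard mu(x) = exp(a0 - a1 x) + c + exp(b0 + b1 x), per year."""
    x = _check_age(x)
    out = (
        np.exp(params.a0 - params.a1 * x)
        + params.c
        + np.exp(params.b0 + params.b1 * x)
    )
    return out if out.ndim else float(out)


def cumulative_hazard(params: SilerParams, x):
    """Closed-form cumulative hazard U(x) = int_0^x mu(t) dt.

    U(x) = (e^a0/a1)(1 - e^{-a1 x}) + c x + (e^b0/b1)(e^{b1 x} - 1),
    with the a1 -> 0 / b1 -> 0 limits e^{a0} x and e^{b0} x.
    """
    x = _check_age(x)
    if params.a1 > _SMALL:
        infant = np.exp(params.a0) * (-np.expm1(-params.a1 * x)) / params.a1
    else:
        infant = np.exp(params.a0) * x
    if params.b1 > _SMALL:
        senescent = np.exp(params.b0) * np.expm1(params.b1 * x) / params.b1
    else:
        senescent = np.exp(params.b0) * x
    out = infant + params.c * x + senescent
    return out if out.ndim else float(out)


def survival(params: SilerParams, x):
    """Survival function S(x) = exp(-U(x))."""
    return np.exp(-np.asarray(cumulative_hazard(params, x)))[()]


def death_density(params: SilerParams, x):
    """Density of ages at death f(x) = mu(x) S(x)."""
    return hazard(params, x) * survival(params, x)


def resolve_upper_age(params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD) -> float:
    """Truncation age for the improper integrals.

    An explicit ``upper_age`` is validated against ``abs_tol``; otherwise the
    age is doubled from 1 year until survival drops below ``surv_tol`` or the
    cap ``max_upper`` is hit.  Survival above ``abs_tol`` at the truncation
    age raises :class:`QuadratureError` because the truncated integral would
    not approximate the improper one.
    """
    if quad.upper_age is not None:
        if survival(params, quad.upper_age) >= quad.abs_tol:
            raise QuadratureError(
                f"survival at upper_age={quad.upper_age} is "
                f"{survival(params, quad.upper_age):.3g} >= abs_tol={quad.abs_tol}"
            )
        return float(quad.upper_age)
    upper = 1.0
    while upper < quad.max_upper and survival(params, upper) >= quad.surv_tol:
        upper *= 2.0
    upper = min(upper, quad.max_upper)
    s_up = survival(params, upper)
    if s_up >= quad.abs_tol:
        raise QuadratureError(
            f"survival still {s_up:.3g} at the age cap {quad.max_upper} y; "
            "raise max_upper (long-lived low-mortality schedule)"
        )
    return upper


def _quad(f, lo: float, hi: float, quad: QuadratureConfig) -> float:
    val, _ = integrate.quad(f, lo, hi, epsabs=quad.abs_tol, epsrel=quad.rel_tol, limit=200)
    return val


def life_expectancy(params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD) -> float:
    """Life expectancy at birth, e = int_0^inf S(x) dx, years."""
    upper = resolve_upper_age(params, quad)
    return _quad(lambda t: survival(params, t), 0.0, upper, quad)


def remaining_life_expectancy(
    params: SilerParams, x: float, quad: QuadratureConfig = DEFAULT_QUAD
) -> float:
    """Remaining life expectancy at age x: int_x^inf S(t) dt / S(x)."""
    x = float(_check_age(x))
    sx = survival(params, x)
    if sx < 1e-300:
        raise QuadratureError(f"survival at age {x} is numerically zero")
    upper = resolve_upper_age(params, quad)
    if x >= upper:
        raise QuadratureError(f"age {x} is beyond the truncation age {upper}")
    return _quad(lambda t: survival(params, t), x, upper, quad) / sx


def lifespan_inequality(params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD) -> float:
    """Lifespan inequality H (Keyfitz entropy): int S*U dx / e.

    Equivalently -int S log S dx / e; equals 1 for a constant hazard,
    below 1 when deaths concentrate at old ages.
    """
    upper = resolve_upper_age(params, quad)
    e = _quad(lambda t: survival(params, t), 0.0, upper, quad)
    num = _quad(lambda t: survival(params, t) * cumulative_hazard(params, t), 0.0, upper, quad)
    return num / e


def lifespan_equality(params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD) -> float:
    """Lifespan equality eps = -log(H)."""
    return -math.log(lifespan_inequality(params, quad))


def pace_shape_summary(params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD) -> PaceShapeSummary:
    """Compute (e, H, eps) with a single shared truncation."""
    upper = resolve_upper_age(params, quad)
    e = _quad(lambda t: survival(params, t), 0.0, upper, quad)
    num = _quad(lambda t: survival(params, t) * cumulative_hazard(params, t), 0.0, upper, quad)
    H = num / e
    return PaceShapeSummary(e=e, H=H, epsilon=-math.log(H))
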