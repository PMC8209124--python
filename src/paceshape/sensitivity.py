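"""Closed-form sensitivities of survival, life expectancy and lifespan
equality to each Siler mortality parameter.

Writing S(x) = exp(-U(x)), the sensitivity of survival to a parameter theta
is S_theta = -S * U_theta, where U_theta is the partial derivative of the
closed-form cumulative hazard.  Integrating,

    e_theta   = int_0^inf S_theta dx
    eps_theta = [ e_theta (1 + 1/H) - (1/H) int_0^inf S_theta U dx ] / e

These give, for each parameter, the displacement (e_theta, eps_theta) a unit
parameter change produces in the life-expectancy / lifespan-equality plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .siler import (
    DEFAULT_QUAD,
    PARAM_NAMES,
    QuadratureConfig,
    SilerParams,
    _quad,
    cumulative_hazard,
    resolve_upper_age,
    survival,
)

__all__ = [
    "SensitivityVector",
    "survival_sensitivity",
    "life_expectancy_sensitivity",
    "lifespan_equality_sensitivity",
    "gradient_vector",
    "gradient_field",
]

# switch to series expansions of U_theta below this to avoid catastrophic
# cancellation in the a1, b1 derivatives
_SERIES_CUTOFF = 1e-5


@dataclass(frozen=True)
class SensitivityVector:
    """Gradient of (e, eps) with respect to one mortality parameter."""

    param: str
    e_theta: float
    eps_theta: float

    @property
    def norm(self) -> float:
        return float(np.hypot(self.e_theta, self.eps_theta))


def _check_param(param: str) -> None:
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown Siler parameter {param!r}; expected one of {PARAM_NAMES}")


def cumulative_hazard_sensitivity(params: SilerParams, x, param: str):
    """U_theta(x): partial derivative of the cumulative hazard.

    Closed forms, with series limits as a1 or b1 -> 0:

        U_a0 = (e^a0/a1)(1 - e^{-a1 x})
        U_a1 = e^a0 [ x e^{-a1 x}/a1 - (1 - e^{-a1 x})/a1^2 ]
        U_c  = x
        U_b0 = (e^b0/b1)(e^{b1 x} - 1)
        U_b1 = e^b0 [ x e^{b1 x}/b1 - (e^{b1 x} - 1)/b1^2 ]
    """
    _check_param(param)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    a0, a1, c, b0, b1 = params.a0, params.a1, params.c, params.b0, params.b1
    if param == "a0":
        if a1 > _SERIES_CUTOFF:
            out = np.exp(a0) * (-np.expm1(-a1 * x)) / a1
        else:
            out = np.exp(a0) * x * (1.0 - a1 * x / 2.0)
    elif param == "a1":
        if a1 > _SERIES_CUTOFF:
            out = np.exp(a0) * (x * np.exp(-a1 * x) / a1 + np.expm1(-a1 * x) / a1**2)
        else:
            # d/da1 [x - a1 x^2/2 + a1^2 x^3/6 - ...]
            out = np.exp(a0) * (-(x**2) / 2.0 + a1 * x**3 / 3.0)
    elif param == "c":
        out = x
    elif param == "b0":
        if b1 > _SERIES_CUTOFF:
            out = np.exp(b0) * np.expm1(b1 * x) / b1
        else:
            out = np.exp(b0) * x * (1.0 + b1 * x / 2.0)
    else:  # b1
        if b1 > _SERIES_CUTOFF:
            out = np.exp(b0) * (x * np.exp(b1 * x) / b1 - np.expm1(b1 * x) / b1**2)
        else:
            out = np.exp(b0) * (x**2 / 2.0 + b1 * x**3 / 3.0)
    return out if out.ndim else float(out)


def survival_sensitivity(params: SilerParams, x, param: str):
    """S_theta(x) = -S(x) * U_theta(x); vanishes at x = 0 for every parameter."""
    return -survival(params, x) * cumulative_hazard_sensitivity(params, x, param)


def life_expectancy_sensitivity(
    params: SilerParams, param: str, quad: QuadratureConfig = DEFAULT_QUAD
) -> float:
    """e_theta = int_0^inf S_theta dx, years per unit parameter change."""
    _check_param(param)
    upper = resolve_upper_age(params, quad)
    return _quad(lambda t: survival_sensitivity(params, t, param), 0.0, upper, quad)


def lifespan_equality_sensitivity(
    params: SilerParams, param: str, quad: QuadratureConfig = DEFAULT_QUAD
) -> float:
    """eps_theta = [e_theta (1 + 1/H) - (1/H) int S_theta U dx] / e."""
    _check_param(param)
    upper = resolve_upper_age(params, quad)
    e = _quad(lambda t: survival(params, t), 0.0, upper, quad)
    su = _quad(lambda t: survival(params, t) * cumulative_hazard(params, t), 0.0, upper, quad)
    H = su / e
    e_th = _quad(lambda t: survival_sensitivity(params, t, param), 0.0, upper, quad)
    s_th_u = _quad(
        lambda t: survival_sensitivity(params, t, param) * cumulative_hazard(params, t),
        0.0,
        upper,
        quad,
    )
    return (e_th * (1.0 + 1.0 / H) - s_th_u / H) / e


def pace_shape_sensitivity(
    params: SilerParams, param: str, quad: QuadratureConfig = DEFAULT_QUAD
) -> Tuple[float, float, float, float]:
    """(e, H, e_theta, eps_theta) for one parameter in four quadratures."""
    _check_param(param)
    upper = resolve_upper_age(params, quad)
    e = _quad(lambda t: survival(params, t), 0.0, upper, quad)
    su = _quad(lambda t: survival(params, t) * cumulative_hazard(params, t), 0.0, upper, quad)
    H = su / e
    e_th = _quad(lambda t: survival_sensitivity(params, t, param), 0.0, upper, quad)
    s_th_u = _quad(
        lambda t: survival_sensitivity(params, t, param) * cumulative_hazard(params, t),
        0.0,
        upper,
        quad,
    )
    eps_th = (e_th * (1.0 + 1.0 / H) - s_th_u / H) / e
    return e, H, e_th, eps_th


def gradient_vector(
    params: SilerParams, quad: QuadratureConfig = DEFAULT_QUAD
) -> Dict[str, SensitivityVector]:
    """All five (e_theta, eps_theta) sensitivity vectors at one parameter set.

    Shares the integrals of S and S*U across parameters for efficiency.
    """
    upper = resolve_upper_age(params, quad)
    e = _quad(lambda t: survival(params, t), 0.0, upper, quad)
    su = _quad(lambda t: survival(params, t) * cumulative_hazard(params, t), 0.0, upper, quad)
    H = su / e
    out: Dict[str, SensitivityVector] = {}
    for param in PARAM_NAMES:
        e_th = _quad(lambda t: survival_sensitivity(params, t, param), 0.0, upper, quad)
        s_th_u = _quad(
            lambda t: survival_sensitivity(params, t, param) * cumulative_hazard(params, t),
            0.0,
            upper,
            quad,
        )
        eps_th = (e_th * (1.0 + 1.0 / H) - s_th_u / H) / e
        out[param] = SensitivityVector(param=param, e_theta=e_th, eps_theta=eps_th)
    return out


def gradient_field(
    param_sets: Iterable[SilerParams], param: str, quad: QuadratureConfig = DEFAULT_QUAD
) -> List[Tuple[float, float, float, float]]:
    """Sensitivity vectors for one parameter, anchored at each set's (e, eps).

    Returns (e, eps, e_theta, eps_theta) per parameter set — the gradient
    field of the chosen parameter over the pace-shape landscape.
    """
    _check_param(param)
    param_sets = list(param_sets)
    if not param_sets:
        raise ValueError("param_sets must be non-empty")
    out = []
    for p in param_sets:
        e, H, e_th, eps_th = pace_shape_sensitivity(p, param, quad)
        out.append((e, -np.log(H), e_th, eps_th))
    return out
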