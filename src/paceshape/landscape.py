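"""Genus lines in the life-expectancy / lifespan-equality landscape and
parameter change along them.

Populations of one genus fall close to a line eps = beta0 + beta1 * e
(fitted by weighted least squares, weights typically 1/SE of the estimated
life expectancies).  Three questions are answered here:

* how does the pace-shape point (e, eps) move when one Siler parameter is
  perturbed (perturbation curves, sensitivity gradient vectors);
* how collinear is each parameter's gradient vector with the genus line
  (|cos| of the angle: 1 parallel, 0 perpendicular);
* how much must each parameter change, on the log scale, to traverse the
  line — the path integral Theta of the gradient of log(theta) along the
  line, scaled by the line's length.

The path integral needs theta as a function of position on the line; the
package defines that via interpolation of the populations' fitted
parameters in e (linear for the log-scale parameters a0 and b0, log-linear
for the positive parameters), an explicit modelling choice isolated in
:func:`parameter_trajectory`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .sensitivity import SensitivityVector, gradient_vector, pace_shape_sensitivity
from .siler import (
    DEFAULT_QUAD,
    PARAM_NAMES,
    QuadratureConfig,
    SilerParams,
    pace_shape_summary,
)

__all__ = [
    "PopulationPoint",
    "GenusLine",
    "PathIntegralResult",
    "SingularPathError",
    "fit_genus_line",
    "perturbation_curve",
    "collinearity",
    "parameter_trajectory",
    "path_integral_change",
    "rank_parameter_changes",
]


class SingularPathError(RuntimeError):
    """A reciprocal sensitivity (or the parameter itself) crosses zero on the path."""

    def __init__(self, param: str, location: float, quantity: str):
        self.param = param
        self.location = location
        self.quantity = quantity
        super().__init__(
            f"path integral for {param} is singular near e = {location:.3g} "
            f"({quantity} crosses zero)"
        )


@dataclass(frozen=True)
class PopulationPoint:
    """One population's position in the landscape, with its fitted parameters."""

    e: float
    epsilon: float
    weight: float = 1.0
    params: Optional[SilerParams] = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class GenusLine:
    """Weighted least-squares line eps = beta0 + beta1 * e for one genus."""

    beta0: float
    beta1: float
    slope_se: float
    p_value: float
    e_range: Tuple[float, float]
    populations: Tuple[PopulationPoint, ...]

    def predict(self, e) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(e, dtype=float)

    @property
    def length(self) -> float:
        """Euclidean length of the fitted segment over the e-range."""
        return abs(self.e_range[1] - self.e_range[0]) * math.sqrt(1.0 + self.beta1**2)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the line in the (e, eps) plane."""
        d = np.array([1.0, self.beta1])
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class PathIntegralResult:
    """Length-scaled line integral of grad log(theta) along a genus line."""

    param: str
    theta_total: float
    n_segments: int
    unscaled: float


def fit_genus_line(
    points: Sequence[Tuple[float, float] | PopulationPoint],
    weights: Optional[Sequence[float]] = None,
    params_list: Optional[Sequence[SilerParams]] = None,
) -> GenusLine:
    """Weighted least-squares fit of the genus line.

    ``points`` may be (e, eps) pairs or :class:`PopulationPoint` objects;
    weights (typically 1/SE(e)) default to 1.  The slope's standard error
    and the two-sided t-test p-value for H0: beta1 = 0 (n - 2 df) are
    returned with the coefficients.
    """
    pops: List[PopulationPoint] = []
    for i, pt in enumerate(points):
        if isinstance(pt, PopulationPoint):
            pops.append(pt)
        else:
            e, eps = pt
            w = 1.0 if weights is None else float(weights[i])
            p = None if params_list is None else params_list[i]
            pops.append(PopulationPoint(e=float(e), epsilon=float(eps), weight=w, params=p))
    e = np.array([p.e for p in pops])
    eps = np.array([p.epsilon for p in pops])
    w = np.array([p.weight for p in pops])
    if len(np.unique(e)) < 2:
        raise ValueError("need at least two distinct life-expectancy values to fit a line")

    model = sm.WLS(eps, sm.add_constant(e), weights=w)
    with np.errstate(divide="ignore", invalid="ignore"):  # 2-point fits have 0 df
        res = model.fit()
    beta0, beta1 = (float(v) for v in res.params)
    slope_se = float(res.bse[1])
    p_value = float(res.pvalues[1])
    return GenusLine(
        beta0=beta0,
        beta1=beta1,
        slope_se=slope_se,
        p_value=p_value,
        e_range=(float(e.min()), float(e.max())),
        populations=tuple(sorted(pops, key=lambda p: p.e)),
    )


def perturbation_curve(
    mid_params: SilerParams,
    param: str,
    values: Sequence[float],
    quad: QuadratureConfig = DEFAULT_QUAD,
) -> List[Tuple[float, float]]:
    """(e, eps) traced by varying one parameter with the other four fixed."""
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown Siler parameter {param!r}")
    out = []
    for v in values:
        summ = pace_shape_summary(mid_params.replace(**{param: float(v)}), quad)
        out.append((summ.e, summ.epsilon))
    return out


def collinearity(line: GenusLine | float, vector: SensitivityVector) -> float:
    """|cos| of the angle between the genus line and a sensitivity vector.

    1 means the vector is parallel to the line (a unit change in the
    parameter moves populations along the line), 0 perpendicular.
    Invariant to positive rescaling of the vector; accepts a bare slope in
    place of a fitted line.
    """
    beta1 = line.beta1 if isinstance(line, GenusLine) else float(line)
    v = np.array([vector.e_theta, vector.eps_theta])
    nv = np.linalg.norm(v)
    if nv == 0 or not np.isfinite(nv):
        raise ValueError("sensitivity vector must be non-zero and finite")
    d = np.array([1.0, beta1]) / math.sqrt(1.0 + beta1**2)
    return float(abs(d @ v) / nv)


def parameter_trajectory(line: GenusLine) -> Callable[[float], SilerParams]:
    """Siler parameters as a function of life expectancy along a genus line.

    Populations are ordered by e and each parameter interpolated in e:
    linear for a0 and b0 (already log-scale quantities), linear in log for
    a1, c, b1 when positive throughout (falling back to linear if any
    population has a zero).  Evaluation is clamped to the line's e-range;
    the line's midpoint parameters are the trajectory at mid-range.
    """
    pops = [p for p in line.populations if p.params is not None]
    if len(pops) < 2:
        raise ValueError("trajectory needs at least two populations with fitted parameters")
    e_knots = np.array([p.e for p in pops])
    order = np.argsort(e_knots)
    e_knots = e_knots[order]
    values: Dict[str, np.ndarray] = {}
    log_scale: Dict[str, bool] = {}
    for name in PARAM_NAMES:
        v = np.array([getattr(pops[i].params, name) for i in order])
        use_log = name in ("a1", "c", "b1") and np.all(v > 0)
        values[name] = np.log(v) if use_log else v
        log_scale[name] = use_log

    lo, hi = line.e_range

    def trajectory(e: float) -> SilerParams:
        e = float(np.clip(e, lo, hi))
        kw = {}
        for name in PARAM_NAMES:
            y = float(np.interp(e, e_knots, values[name]))
            kw[name] = math.exp(y) if log_scale[name] else y
        return SilerParams(**kw)

    return trajectory


def path_integral_change(
    line: GenusLine,
    trajectory: Callable[[float], SilerParams],
    param: str,
    n_segments: int = 200,
    quad: QuadratureConfig = DEFAULT_QUAD,
) -> PathIntegralResult:
    """Total log-scale change of one parameter along the genus line.

    The gradient of g(theta) = log theta in the landscape is
    (1/theta)(1/e_theta, 1/eps_theta); dotted with dr = (de, beta1 de)
    along the line and integrated by the midpoint rule over the e-range:

        Theta = int (1/theta) [1/e_theta + beta1/eps_theta] de

    then divided by the line length (e_max - e_min) sqrt(1 + beta1^2).
    When beta1 = 0 the eps-term is a removable 0; otherwise e_theta,
    eps_theta or theta crossing zero along the path raises
    :class:`SingularPathError` (the integral is genuinely improper there).
    """
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown Siler parameter {param!r}")
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    lo, hi = line.e_range  # may be reversed to integrate in the opposite direction
    if hi == lo:
        raise ValueError("degenerate e-range")
    edges = np.linspace(lo, hi, n_segments + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    de = (hi - lo) / n_segments

    e_th = np.empty(n_segments)
    eps_th = np.empty(n_segments)
    theta_val = np.empty(n_segments)
    for i, e_m in enumerate(mids):
        p = trajectory(e_m)
        _, _, e_th[i], eps_th[i] = pace_shape_sensitivity(p, param, quad)
        theta_val[i] = getattr(p, param)

    def check_sign(arr: np.ndarray, what: str) -> None:
        s = np.sign(arr)
        if np.any(s == 0) or np.any(s[1:] != s[:-1]):
            j = int(np.argmax(s[1:] != s[:-1])) if np.all(s != 0) else int(np.argmax(s == 0))
            raise SingularPathError(param, float(mids[j]), what)

    check_sign(theta_val, f"{param} itself")
    check_sign(e_th, "e_theta")
    beta1 = 0.0 if abs(line.beta1) < 1e-10 else line.beta1  # flat line: eps-term removable
    if beta1 != 0.0:
        check_sign(eps_th, "eps_theta")
        integrand = (1.0 / theta_val) * (1.0 / e_th + beta1 / eps_th)
    else:
        integrand = (1.0 / theta_val) * (1.0 / e_th)
    unscaled = float(np.sum(integrand) * de)
    return PathIntegralResult(
        param=param,
        theta_total=unscaled / line.length,
        n_segments=n_segments,
        unscaled=unscaled,
    )


def rank_parameter_changes(
    line: GenusLine,
    trajectory: Callable[[float], SilerParams],
    quad: QuadratureConfig = DEFAULT_QUAD,
    n_segments: int = 200,
) -> Tuple[List[Tuple[str, float]], Dict[str, SingularPathError]]:
    """|Theta| for all five parameters, sorted descending.

    Returns the ranking (param, |Theta|) and a dict of parameters whose
    path integral was singular (reported, not silently dropped).  Values
    are customarily displayed as log10(|Theta|) since the early-life
    parameters change orders of magnitude more than the ageing parameters.
    """
    results: List[Tuple[str, float]] = []
    errors: Dict[str, SingularPathError] = {}
    for param in PARAM_NAMES:
        try:
            res = path_integral_change(line, trajectory, param, n_segments=n_segments, quad=quad)
            results.append((param, abs(res.theta_total)))
        except SingularPathError as err:
            errors[param] = err
    results.sort(key=lambda kv: kv[1], reverse=True)
    return results, errors
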