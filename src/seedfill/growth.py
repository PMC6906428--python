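"""Logistic model of seed filling and its derived characteristic traits.

Seed dry weight accumulation in maize follows a sigmoid trajectory.  The
50-seed dry weight ``w`` (g) at ``t`` days after pollination (DAP) is modelled
as a three-parameter logistic curve

    w(t) = k / (1 + a * exp(-b * t))

where ``k`` is the asymptotic final dry weight (g), ``b`` the relative filling
rate (per DAP) and ``a`` a dimensionless shape parameter that, together with
``b``, places the curve in time.  The instantaneous filling rate is the first
derivative

    v(t) = k * a * b * exp(-b*t) / (1 + a * exp(-b*t))**2

which peaks at the curve's inflexion point (t = ln(a)/b, w = k/2) with maximum
value v_max = k*b/4.

From a fitted (k, a, b) twelve characteristic filling traits are available in
closed form: the onset and end of the fast-growth phase t1, t2 (the zeros of
the second derivative of the rate curve, at a*exp(-b*t) = 2 ± sqrt(3)), the
total filling duration t3 (the time at which w reaches a completion fraction,
0.99*k by default), the dry-matter gains w1, w2, w3 of the three phases, the
average rate v_bar = k*b/6, the active filling period T = 6/b and v_max.
The three phase gains satisfy w1 + w2 + w3 = 0.99*k identically and contribute
~21%, 58% and 20% of the final weight for every parameter combination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "WeightSeries",
    "LogisticFit",
    "FillingParameters",
    "DegenerateInputError",
    "logistic_weight",
    "filling_rate",
    "fit_logistic",
    "derive_parameters",
    "goodness_of_fit",
    "PARAMETER_COLUMNS",
]

_SQRT3 = math.sqrt(3.0)
#: column order of the derived-trait table written by the fitting pipeline
PARAMETER_COLUMNS = [
    "k", "b", "lna_b", "t1", "t2", "t3",
    "w1", "w2", "w3", "v_bar", "T", "v_max",
]


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. constant weights)."""


def _check_params(k: float, a: float, b: float) -> None:
    if not (k > 0 and a > 0 and b > 0):
        raise ValueError(
            f"logistic parameters must be strictly positive, got k={k}, a={a}, b={b}"
        )


@dataclass(frozen=True)
class WeightSeries:
    """One line x environment dry-weight trajectory.

    ``times`` are DAP values (strictly increasing, positive); ``weights`` the
    matching 50-seed dry weights in grams (non-negative).  At least four
    points are required to fit the three logistic parameters.
    """

    line_id: str
    environment: str
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.ndim != 1 or w.ndim != 1 or len(t) != len(w):
            raise ValueError("times and weights must be 1-D arrays of equal length")
        if len(t) < 4:
            raise ValueError(
                f"need at least 4 time points to fit 3 parameters, got {len(t)}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t <= 0):
            raise ValueError("times (DAP) must be positive")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic parameters for one trajectory."""

    k: float
    a: float
    b: float
    r_squared: float
    n_obs: int
    converged: bool
    line_id: str = ""
    environment: str = ""


@dataclass(frozen=True)
class FillingParameters:
    """The twelve characteristic seed-filling traits derived from (k, a, b).

    Units: weights in g, times in DAP, rates in g/DAP.  ``pre_pollination_inflexion``
    flags fits with a <= 2 + sqrt(3), for which t1 falls at or before pollination.
    """

    k: float
    b: float
    lna_b: float
    t1: float
    t2: float
    t3: float
    w1: float
    w2: float
    w3: float
    v_bar: float
    T: float
    v_max: float
    completion_fraction: float = 0.99
    pre_pollination_inflexion: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_COLUMNS}


def logistic_weight(t, k: float, a: float, b: float):
    """Seed dry weight at ``t`` DAP: k / (1 + a*exp(-b*t)).

    Strictly increasing in ``t`` and bounded in (0, k); passes through the
    inflexion point (ln(a)/b, k/2).
    """
    _check_params(k, a, b)
    t = np.asarray(t, dtype=float)
    out = k / (1.0 + a * np.exp(-b * t))
    return float(out) if out.ndim == 0 else out


def filling_rate(t, k: float, a: float, b: float):
    """Instantaneous filling rate dw/dt at ``t`` DAP.

    Equals k*a*b*exp(-b*t) / (1 + a*exp(-b*t))**2; symmetric about the
    inflexion time ln(a)/b where it attains its maximum k*b/4.
    """
    _check_params(k, a, b)
    t = np.asarray(t, dtype=float)
    u = a * np.exp(-b * t)
    out = k * b * u / (1.0 + u) ** 2
    return float(out) if out.ndim == 0 else out


def _self_start(t: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Initial (k, a, b) from the logit transform of the observed trajectory.

    k0 is 5% above the largest observation; regressing ln(k0/w - 1) on t is
    linear with slope -b and intercept ln(a) under the model, which makes the
    start values self-generating for any S-shaped series.
    """
    k0 = 1.05 * float(np.max(w))
    w_clip = np.clip(w, 1e-9 * k0, k0 * (1.0 - 1e-9))
    z = np.log(k0 / w_clip - 1.0)
    slope, intercept = np.polyfit(t, z, 1)
    b0 = -float(slope)
    a0 = float(np.exp(np.clip(intercept, -500, 500)))
    if not (np.isfinite(b0) and b0 > 0 and np.isfinite(a0) and a0 > 0):
        # flat or inverted series: fall back to a generic S placed mid-series
        b0 = 4.0 / (t[-1] - t[0])
        a0 = math.exp(b0 * float(np.median(t)))
    return k0, a0, b0


def _residuals(p: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    k, a, b = p
    return k / (1.0 + a * np.exp(-b * t)) - w


def _jacobian(p: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    k, a, b = p
    e = np.exp(-b * t)
    denom = 1.0 + a * e
    J = np.empty((len(t), 3))
    J[:, 0] = 1.0 / denom
    J[:, 1] = -k * e / denom**2
    J[:, 2] = k * a * t * e / denom**2
    return J


def fit_logistic(
    series: WeightSeries,
    init: tuple[float, float, float] | None = None,
    max_iter: int = 200,
) -> LogisticFit:
    """Nonlinear least-squares fit of the logistic curve to one trajectory.

    Minimises sum((w_obs - w_model)**2) by Levenberg-Marquardt with the
    analytic Jacobian, starting from the logit-transform self-start (or a
    user-supplied ``init``).  If LM wanders out of the positive-parameter
    domain the fit is retried with a bounded trust-region solver; a fit that
    still fails is returned with ``converged=False`` rather than raising.

    Raises :class:`DegenerateInputError` for constant (e.g. all-zero) weights.
    """
    t, w = series.times, series.weights
    if np.ptp(w) < 1e-12:
        raise DegenerateInputError(
            f"weights of {series.line_id}/{series.environment} are constant; "
            "no curve can be fitted"
        )
    if init is None:
        init = _self_start(t, w)
    x0 = np.asarray(init, dtype=float)
    _check_params(*x0)

    res = optimize.least_squares(
        _residuals, x0, jac=_jacobian, args=(t, w), method="lm",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_iter * 4,
    )
    ok = res.success and np.all(res.x > 0) and np.all(np.isfinite(res.x))
    if not ok:
        # retry within the admissible (positive) box
        res = optimize.least_squares(
            _residuals, np.abs(x0) + 1e-9, jac=_jacobian, args=(t, w),
            method="trf", bounds=(1e-12, np.inf),
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_iter * 4,
        )
        ok = res.success and np.all(res.x > 0) and np.all(np.isfinite(res.x))

    k, a, b = (float(v) for v in res.x)
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return LogisticFit(
        k=k, a=a, b=b, r_squared=r2, n_obs=len(series), converged=bool(ok),
        line_id=series.line_id, environment=series.environment,
    )


def goodness_of_fit(fit: LogisticFit, series: WeightSeries) -> float:
    """Coefficient of determination of ``fit`` against ``series``.

    R^2 = 1 - SS_res/SS_tot.  A negative value (fit worse than the mean) is
    returned as computed, with a warning.  Constant series have no total
    variance and raise :class:`DegenerateInputError`.
    """
    w = series.weights
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    if ss_tot <= 0:
        raise DegenerateInputError("series has zero total variance; R^2 undefined")
    pred = logistic_weight(series.times, fit.k, fit.a, fit.b)
    r2 = 1.0 - float(np.sum((w - pred) ** 2)) / ss_tot
    if r2 < 0:
        warnings.warn("R^2 is negative: the fit is worse than the series mean")
    return r2


def derive_parameters(
    fit: LogisticFit | tuple[float, float, float],
    completion_fraction: float = 0.99,
) -> FillingParameters:
    """Closed-form characteristic filling traits from a converged fit.

    t1 and t2 are the zeros of the second derivative of the rate curve, at
    a*exp(-b*t) = 2 + sqrt(3) and 2 - sqrt(3); t3 solves w(t) = c*k for the
    completion fraction c (0.99 by default, giving t3 = ln(99*a)/b).  The
    phase gains are w1 = k/(3+sqrt(3)), w2 = k*sqrt(3)/3 and
    w3 = (c - (3+sqrt(3))/6)*k, so w1+w2+w3 = c*k identically.  v_bar = k*b/6,
    T = 6/b and v_max = k*b/4 do not depend on c.

    If a <= 2+sqrt(3), t1 falls at or before pollination; the values are
    still returned with ``pre_pollination_inflexion=True``.
    """
    if isinstance(fit, LogisticFit):
        k, a, b = fit.k, fit.a, fit.b
    else:
        k, a, b = fit
    _check_params(k, a, b)
    c = completion_fraction
    if not 0.0 < c < 1.0:
        raise ValueError(f"completion fraction must lie in (0, 1), got {c}")
    t1 = -math.log((2.0 + _SQRT3) / a) / b
    t2 = -math.log((2.0 - _SQRT3) / a) / b
    t3 = math.log(a * c / (1.0 - c)) / b
    return FillingParameters(
        k=k,
        b=b,
        lna_b=math.log(a) / b,
        t1=t1,
        t2=t2,
        t3=t3,
        w1=k / (3.0 + _SQRT3),
        w2=k * _SQRT3 / 3.0,
        w3=(c - (3.0 + _SQRT3) / 6.0) * k,
        v_bar=k * b / 6.0,
        T=6.0 / b,
        v_max=k * b / 4.0,
        completion_fraction=c,
        pre_pollination_inflexion=bool(a <= 2.0 + _SQRT3),
    )
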