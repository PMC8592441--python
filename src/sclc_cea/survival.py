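"""Parametric survival laws, per-cycle transition probabilities, and fitting.

Time is measured in model cycles (21 days by default) throughout. The four
supported families are the ones routinely screened in health-technology
assessment when extrapolating digitized Kaplan-Meier curves: exponential,
Weibull, log-normal and log-logistic. The log-logistic law is parameterized
as

    S(t) = 1 / (1 + theta * t**gamma)

with a scale-like rate ``theta`` and shape ``gamma``. Published parameter
tables for this model class sometimes print the rate inside an ``exp(.)``;
substituting the printed value directly (``rate_transform="identity"``)
reproduces the trial arm medians, so that is the default, with
``rate_transform="exp"`` available as a switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats


class Family(str, Enum):
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


#: Fixed family order used as the last tie-break in model selection.
FAMILY_ORDER = (Family.EXPONENTIAL, Family.WEIBULL, Family.LOGNORMAL, Family.LOGLOGISTIC)

_N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.LOGNORMAL: 2,
    Family.LOGLOGISTIC: 2,
}


class NoMedianError(ValueError):
    """Raised when a (degenerate) survival law never reaches S(t) = 0.5."""


@dataclass(frozen=True)
class SurvivalParams:
    """A parametric survival law.

    Parameters
    ----------
    family : Family
        One of the four supported distributions.
    params : tuple of float
        Ordered parameter vector:

        - exponential: ``(rate,)`` with ``S(t) = exp(-rate * t)``
        - weibull: ``(theta, gamma)`` with ``S(t) = exp(-theta * t**gamma)``
        - lognormal: ``(mu, sigma)`` on the log-time scale
        - loglogistic: ``(theta, gamma)`` with ``S(t) = 1/(1 + theta * t**gamma)``
    rate_transform : str
        ``"identity"`` (default) uses the rate parameter as printed;
        ``"exp"`` substitutes ``exp(theta)`` for the rate (log-logistic and
        Weibull and exponential rate-like first parameter).
    """

    family: Family
    params: tuple
    rate_transform: str = "identity"

    def __post_init__(self):
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.rate_transform not in ("identity", "exp"):
            raise ValueError(f"unknown rate_transform {self.rate_transform!r}")
        if len(self.params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family.value} expects {_N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        if self.family is Family.LOGNORMAL:
            if self.params[1] <= 0:
                raise ValueError("lognormal sigma must be positive")
        else:
            # theta == 0 is tolerated as the degenerate immortal law
            if self.params[0] < 0:
                raise ValueError("rate parameter must be non-negative")
            if len(self.params) == 2 and self.params[1] <= 0:
                raise ValueError("shape parameter must be positive")

    @property
    def rate(self) -> float:
        r = self.params[0]
        return math.exp(r) if self.rate_transform == "exp" else r

    @property
    def theta(self) -> float:
        return self.params[0]

    @property
    def gamma(self) -> float:
        return self.params[1]

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]


def survival_probability(sp: SurvivalParams, t):
    """S(t) for scalar or array ``t`` in cycles; raises on negative times."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be non-negative")
    if sp.family is Family.EXPONENTIAL:
        out = np.exp(-sp.rate * t_arr)
    elif sp.family is Family.WEIBULL:
        out = np.exp(-sp.rate * np.power(t_arr, sp.gamma))
    elif sp.family is Family.LOGNORMAL:
        mu, sigma = sp.params
        with np.errstate(divide="ignore"):
            z = (np.log(t_arr) - mu) / sigma
        out = stats.norm.sf(z)
        out = np.where(t_arr == 0, 1.0, out)
    else:  # log-logistic
        out = 1.0 / (1.0 + sp.rate * np.power(t_arr, sp.gamma))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def inverse_survival(sp: SurvivalParams, s):
    """Time t with S(t) = s, for scalar or array s in (0, 1)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr <= 0.0) | (s_arr >= 1.0)):
        raise ValueError("s must lie strictly between 0 and 1")
    if sp.family is not Family.LOGNORMAL and sp.rate == 0.0:
        raise NoMedianError("degenerate law: S(t) = 1 for all t")
    if sp.family is Family.EXPONENTIAL:
        out = -np.log(s_arr) / sp.rate
    elif sp.family is Family.WEIBULL:
        out = (-np.log(s_arr) / sp.rate) ** (1.0 / sp.gamma)
    elif sp.family is Family.LOGNORMAL:
        mu, sigma = sp.params
        out = np.exp(mu + sigma * stats.norm.ppf(1.0 - s_arr))
    else:
        out = ((1.0 - s_arr) / (sp.rate * s_arr)) ** (1.0 / sp.gamma)
    return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out


def median_survival(sp: SurvivalParams) -> float:
    """Closed-form median in cycles; the log-logistic one is (1/theta)**(1/gamma)."""
    return inverse_survival(sp, 0.5)


def tp_die(sp_os: SurvivalParams, t, u: float = 1.0):
    """Conditional per-cycle death probability 1 - S(t)/S(t-u).

    ``t`` is the cycle end time (integer multiples of the cycle), ``u`` the
    cycle length in the same unit. The probability conditions on being alive
    at ``t - u``.
    """
    t_arr = np.asarray(t, dtype=float)
    if u <= 0:
        raise ValueError("cycle length u must be positive")
    if np.any(t_arr < u):
        raise ValueError("t must be at least one cycle length u")
    out = 1.0 - survival_probability(sp_os, t_arr) / survival_probability(sp_os, t_arr - u)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def tp_progress(sp_pfs: SurvivalParams, sp_os: SurvivalParams, t, u: float = 1.0):
    """Per-cycle probability of moving from progression-free to progressed.

    Death (from the overall-survival law) is evaluated first; among
    survivors of the cycle the conditional probability of remaining
    progression-free is ``[S_pfs(t)/S_pfs(t-u)] / (1 - tp_die)``, so the
    unconditional stay probability is the plain progression-free survival
    ratio and the progression probability is the remainder

        tp_progress = 1 - tp_die - S_pfs(t)/S_pfs(t-u)

    clipped into [0, 1 - tp_die]: numerically the fitted progression-free
    law can decay more slowly than the overall-survival law over a cycle, in
    which case the progression probability is floored at zero.
    """
    t_arr = np.asarray(t, dtype=float)
    d = tp_die(sp_os, t_arr, u)
    ratio = survival_probability(sp_pfs, t_arr) / survival_probability(sp_pfs, t_arr - u)
    out = np.clip(1.0 - d - ratio, 0.0, 1.0 - d)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    params: SurvivalParams
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    sse: float | None = field(default=None)

    @property
    def family(self) -> Family:
        return self.params.family


def _information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    return 2 * k - 2 * loglik, k * math.log(n) - 2 * loglik


def fit_ipd(times: Sequence[float], event_flags: Sequence[int], family: Family | str) -> FitResult:
    """Maximum-likelihood fit to right-censored individual patient data.

    Delegates the likelihood maximization to ``lifelines`` and re-expresses
    the fitted parameters in this module's rate/shape convention.
    """
    from lifelines import (
        ExponentialFitter,
        LogLogisticFitter,
        LogNormalFitter,
        WeibullFitter,
    )
    from lifelines.exceptions import ConvergenceError

    family = Family(family)
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and event_flags must have equal length")
    n = times.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if events.sum() == 0:
        raise ValueError("non-identifiable: all observations are censored")

    fitters = {
        Family.EXPONENTIAL: ExponentialFitter,
        Family.WEIBULL: WeibullFitter,
        Family.LOGNORMAL: LogNormalFitter,
        Family.LOGLOGISTIC: LogLogisticFitter,
    }
    fitter = fitters[family]()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(times, event_observed=events)
    except ConvergenceError:
        raise ValueError(f"{family.value} fit did not converge")

    if family is Family.EXPONENTIAL:
        params = (1.0 / fitter.lambda_,)  # lifelines parameterizes the scale
    elif family is Family.WEIBULL:
        params = (fitter.lambda_ ** (-fitter.rho_), fitter.rho_)
    elif family is Family.LOGNORMAL:
        params = (fitter.mu_, fitter.sigma_)
    else:
        params = (fitter.alpha_ ** (-fitter.beta_), fitter.beta_)

    sp = SurvivalParams(family, params)
    loglik = float(fitter.log_likelihood_)
    aic, bic = _information_criteria(loglik, sp.n_params, n)
    return FitResult(sp, loglik, aic, bic, n, converged)


def _ls_initial_guess(family: Family, t: np.ndarray, s: np.ndarray) -> tuple:
    # crude time at which the curve crosses 1/2 (extrapolated if needed)
    below = np.nonzero(s <= 0.5)[0]
    t50 = t[below[0]] if below.size else t[-1] * (0.5 / max(s[-1], 1e-6))
    t50 = max(t50, 1e-6)
    if family is Family.EXPONENTIAL:
        return (math.log(2.0) / t50,)
    if family is Family.WEIBULL:
        return (math.log(2.0) / t50 ** 1.5, 1.5)
    if family is Family.LOGNORMAL:
        return (math.log(t50), 1.0)
    return (t50 ** -1.5, 1.5)


def fit_km_points(
    points: Iterable[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    family: Family | str,
    pseudo_n: int | None = None,
) -> FitResult:
    """Least-squares fit of a survival law to digitized (t, S) curve points.

    The objective is unweighted nonlinear least squares on the survival
    scale. Non-monotone inputs are isotonically corrected (decreasing) with
    a warning first. ``pseudo_n`` (default: the number of points) enters the
    Gaussian-equivalent log-likelihood used for AIC/BIC, which makes the
    criteria comparable across families fitted to the same points.
    """
    family = Family(family)
    if isinstance(points, tuple) and len(points) == 2 and np.ndim(points[0]) > 0:
        t, s = (np.asarray(a, dtype=float) for a in points)
    else:
        arr = np.asarray(list(points), dtype=float)
        t, s = arr[:, 0], arr[:, 1]
    if t.size < 5:
        raise ValueError("need at least 5 digitized points")
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("survival points must lie in (0, 1]")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(t)
    t, s = t[order], s[order]
    if np.ptp(t) == 0 or np.ptp(s) == 0:
        raise ValueError("non-identifiable: digitized points carry no curvature")
    if np.any(np.diff(s) > 0):
        from sklearn.isotonic import IsotonicRegression

        warnings.warn("digitized survival points are not non-increasing; applying isotonic correction")
        s = IsotonicRegression(increasing=False).fit_transform(t, s)

    def model(tt, *p):
        return survival_probability(SurvivalParams(family, p), tt)

    p0 = _ls_initial_guess(family, t, s)
    lower = [1e-12] * len(p0)
    upper = [np.inf] * len(p0)
    if family is Family.LOGNORMAL:
        lower[0] = -np.inf  # mu is unconstrained
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(model, t, s, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError:
        popt, converged = np.asarray(p0), False

    sp = SurvivalParams(family, tuple(popt))
    resid = s - survival_probability(sp, t)
    sse = float(resid @ resid)
    n = int(pseudo_n if pseudo_n is not None else t.size)
    # Gaussian-equivalent log-likelihood of the least-squares fit
    loglik = -0.5 * n * (math.log(2 * math.pi * max(sse, 1e-300) / n) + 1.0)
    aic, bic = _information_criteria(loglik, sp.n_params, n)
    return FitResult(sp, loglik, aic, bic, n, converged, sse=sse)


def select_distribution(fits: Sequence[FitResult]) -> Family:
    """Family with the lowest AIC; ties broken by BIC, then fixed family order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    return min(
        fits, key=lambda f: (f.aic, f.bic, FAMILY_ORDER.index(f.family))
    ).family
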