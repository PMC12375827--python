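"""Parametric survival fitting with right censoring, and AIC/BIC selection.

Five families are supported, in the parameterisations below (all parameters
positive unless noted):

========== ===================== =========================================
family     params                survival function
========== ===================== =========================================
exponential (rate λ)             exp(−λt)
weibull     (shape k, scale σ)   exp(−(t/σ)^k)
gamma       (shape α, rate β)    Q(α, βt)   (regularized upper gamma)
loglogistic (scale α, shape β)   1 / (1 + (t/α)^β)
lognormal   (μ ∈ ℝ, σ)           1 − Φ((ln t − μ)/σ)
========== ===================== =========================================

Maximum likelihood uses the censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t), optimized on a transformed scale
(log for positive parameters, identity for the lognormal μ) from a
deterministic method-of-moments start, so fits are exactly reproducible.
The covariance of the estimator, from the inverse observed information
(numerical Hessian on the transformed scale), is retained for sampling
survival-parameter uncertainty in probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .reconstruction import PseudoIPD

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ParametricFit",
    "FitError",
    "frozen_distribution",
    "log_likelihood",
    "fit_parametric",
    "fit_all",
    "select_distribution",
    "survival_at",
    "median_of_fit",
]

#: family order is also the deterministic tie-break order for selection
FAMILIES = ("exponential", "weibull", "gamma", "loglogistic", "lognormal")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
}


class FitError(RuntimeError):
    """Raised when a maximum-likelihood fit cannot be produced."""


def frozen_distribution(family: str, params: Sequence[float]):
    """scipy frozen distribution for ``family`` under this package's
    parameterisation."""
    p = [float(x) for x in params]
    if family == "exponential":
        (rate,) = p
        if rate <= 0:
            raise ValueError("exponential rate must be > 0")
        return stats.expon(scale=1.0 / rate)
    if family == "weibull":
        shape, scale = p
        if shape <= 0 or scale <= 0:
            raise ValueError("weibull shape and scale must be > 0")
        return stats.weibull_min(shape, scale=scale)
    if family == "gamma":
        shape, rate = p
        if shape <= 0 or rate <= 0:
            raise ValueError("gamma shape and rate must be > 0")
        return stats.gamma(shape, scale=1.0 / rate)
    if family == "loglogistic":
        scale, shape = p
        if shape <= 0 or scale <= 0:
            raise ValueError("loglogistic scale and shape must be > 0")
        return stats.fisk(shape, scale=scale)
    if family == "lognormal":
        mu, sigma = p
        if sigma <= 0:
            raise ValueError("lognormal sigma must be > 0")
        return stats.lognorm(sigma, scale=math.exp(mu))
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass(frozen=True)
class ParametricFit:
    """A fitted survival family with its information criteria."""

    family: str
    params: tuple[float, ...]
    loglik: float
    n_obs: int
    covariance: np.ndarray | None = None   # on the transformed scale

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_obs) - 2.0 * self.loglik

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    def distribution(self):
        return frozen_distribution(self.family, self.params)

    def survival(self, t) -> np.ndarray | float:
        return survival_at(self, t)

    def median(self) -> float:
        return median_of_fit(self)

    def sample_params(self, rng: np.random.Generator,
                      size: int = 1) -> np.ndarray:
        """Draw parameter vectors from the asymptotic multivariate normal of
        the estimator (on the transformed scale, back-transformed)."""
        if self.covariance is None:
            return np.tile(np.asarray(self.params), (size, 1))
        theta_hat = _to_transformed(self.family, self.params)
        draws = rng.multivariate_normal(theta_hat, self.covariance, size=size,
                                        method="svd")
        return np.apply_along_axis(
            lambda th: _from_transformed(self.family, th), 1, draws
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {n: p for n, p in zip(self.param_names, self.params)},
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricFit":
        family = d["family"]
        params = tuple(d["params"][n] for n in PARAM_NAMES[family])
        return cls(family=family, params=params, loglik=float(d["loglik"]),
                   n_obs=int(d["n_obs"]))


# ---------------------------------------------------------------------------
# likelihood and optimization
# ---------------------------------------------------------------------------

def log_likelihood(family: str, params: Sequence[float],
                   times: np.ndarray, events: np.ndarray) -> float:
    """Censored log-likelihood Σ_events log f + Σ_censored log S."""
    dist = frozen_distribution(family, params)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    ll = 0.0
    if e.any():
        ll += float(np.sum(dist.logpdf(t[e])))
    if (~e).any():
        ll += float(np.sum(dist.logsf(t[~e])))
    return ll


def _to_transformed(family: str, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if family == "lognormal":
        return np.array([p[0], math.log(p[1])])
    return np.log(p)


def _from_transformed(family: str, theta: np.ndarray) -> tuple[float, ...]:
    theta = np.asarray(theta, dtype=float)
    if family == "lognormal":
        return (float(theta[0]), float(math.exp(theta[1])))
    return tuple(float(x) for x in np.exp(theta))


def _initial_params(family: str, times: np.ndarray,
                    events: np.ndarray) -> tuple[float, ...]:
    """Deterministic method-of-moments style starting values."""
    total_time = float(times.sum())
    n_events = int(events.sum())
    rate0 = n_events / total_time            # exact exponential MLE
    event_times = times[events.astype(bool)]
    if family == "exponential":
        return (rate0,)
    if family == "weibull":
        return (1.0, 1.0 / rate0)
    if family == "gamma":
        m = float(event_times.mean())
        v = float(event_times.var())
        if v <= 0:
            return (1.0, rate0)
        shape0 = float(np.clip(m * m / v, 0.05, 100.0))
        return (shape0, shape0 / m)
    if family == "loglogistic":
        return (float(np.median(event_times)), 1.5)
    if family == "lognormal":
        logs = np.log(event_times)
        sigma0 = float(max(logs.std(), 0.1))
        return (float(logs.mean()), sigma0)
    raise ValueError(f"unknown family {family!r}")


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h ** 2)
    return H


def fit_parametric(ipd: PseudoIPD, family: str,
                   compute_covariance: bool = True) -> ParametricFit:
    """Maximum-likelihood fit of one family to right-censored pseudo-IPD."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    times = np.asarray(ipd.times, dtype=float)
    events = np.asarray(ipd.events, dtype=int)
    if times.size == 0 or events.sum() == 0:
        raise FitError("cannot fit with zero events")

    theta0 = _to_transformed(family, _initial_params(family, times, events))

    def nll(theta: np.ndarray) -> float:
        params = _from_transformed(family, theta)
        with np.errstate(all="ignore"):
            ll = log_likelihood(family, params, times, events)
        return 1e12 if not np.isfinite(ll) else -ll

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    polish = optimize.minimize(nll, res.x, method="BFGS",
                               options={"gtol": 1e-10, "maxiter": 2000})
    best = polish if polish.fun <= res.fun else res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError(
            f"{family} fit did not converge: {getattr(best, 'message', '')}"
        )

    theta_hat = np.asarray(best.x, dtype=float)
    params = _from_transformed(family, theta_hat)
    loglik = -float(best.fun)

    cov = None
    if compute_covariance:
        H = _numerical_hessian(nll, theta_hat)
        try:
            cov = np.linalg.inv(H)
            # a valid covariance must be positive definite
            if not np.all(np.linalg.eigvalsh(cov) > 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None

    return ParametricFit(family=family, params=params, loglik=loglik,
                         n_obs=int(times.size), covariance=cov)


def fit_all(ipd: PseudoIPD,
            families: Iterable[str] = FAMILIES) -> dict[str, ParametricFit]:
    """Fit every requested family to the same data."""
    return {family: fit_parametric(ipd, family) for family in families}


def select_distribution(fits: Sequence[ParametricFit],
                        criterion: str = "AIC") -> ParametricFit:
    """The fit with minimal AIC or BIC.

    Ties go to the family with fewer parameters, then to the fixed family
    order (exponential < weibull < gamma < loglogistic < lognormal).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    if criterion.upper() not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    if len({f.n_obs for f in fits}) > 1:
        raise ValueError("fits were not computed on the same data "
                         "(mixed n_obs)")
    key = (lambda f: (f.aic, f.n_params, FAMILIES.index(f.family))) \
        if criterion.upper() == "AIC" else \
        (lambda f: (f.bic, f.n_params, FAMILIES.index(f.family)))
    return min(fits, key=key)


def survival_at(fit: ParametricFit, t) -> np.ndarray | float:
    """S(t) of a fitted family; defined for t >= 0 with S(0) = 1."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("survival is defined for t >= 0 only")
    out = np.asarray(fit.distribution().sf(t_arr), dtype=float)
    out[t_arr == 0.0] = 1.0
    return out if np.ndim(t) else float(out[0])


def median_of_fit(fit: ParametricFit) -> float:
    """The time t with S(t) = 0.5 (closed form where one exists)."""
    p = fit.params
    if fit.family == "exponential":
        return math.log(2.0) / p[0]
    if fit.family == "weibull":
        k, sigma = p
        return sigma * math.log(2.0) ** (1.0 / k)
    if fit.family == "lognormal":
        return math.exp(p[0])
    if fit.family == "loglogistic":
        return p[0]
    # gamma: no closed form — bracketed root-find on S(t) - 0.5
    dist = fit.distribution()
    f = lambda t: dist.sf(t) - 0.5
    hi = float(dist.mean()) or 1.0
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-10, rtol=1e-12))
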