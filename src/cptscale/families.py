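"""Log-location-scale survival families for carcass persistence models.

Removal time T follows a log-location-scale law: log T = mu + sigma * W,
where W is a standard error distribution.  The four families in routine use
for carcass persistence work are

========== ===================== ==========================================
family     W                     S(t)
========== ===================== ==========================================
weibull    Gumbel (minimum)      exp(-(t / e^mu)^(1/sigma))
exponential weibull, sigma = 1   exp(-t / e^mu)
loglogistic logistic             1 / (1 + (t / e^mu)^(1/sigma))
lognormal  standard normal       1 - Phi((log t - mu) / sigma)
========== ===================== ==========================================

``mu`` is the location (log-days) and ``sigma > 0`` the scale.  All
functions are vectorised over ``t``, ``mu`` and ``sigma`` and accept
``t = +inf`` (survival 0).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal")

__all__ = [
    "FAMILIES",
    "survival_function",
    "log_survival",
    "median_time",
    "sample_removal_times",
]


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}; expected one of {FAMILIES}")
    return family


def _zstat(t, mu, sigma):
    """Standardised log-time (log t - mu) / sigma; -inf at t = 0, +inf at t = inf."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.log(t)
    return (logt - mu) / sigma


def log_survival(family: str, t, mu, sigma=1.0):
    """log S(t); numerically stable in both tails.

    ``t`` may contain ``+inf`` (-> -inf) and 0 (-> 0).  Negative times raise.
    """
    _check_family(family)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    if family == "exponential":
        sigma = 1.0
        family = "weibull"
    z = _zstat(t, mu, sigma)
    if family == "weibull":
        # S = exp(-exp(z)); overflow of exp(z) correctly saturates to -inf
        with np.errstate(over="ignore"):
            out = -np.exp(z)
    elif family == "loglogistic":
        # S = 1 / (1 + exp(z))
        out = -np.logaddexp(0.0, z)
    else:  # lognormal
        out = stats.norm.logsf(z)
    # t == inf yields z == inf and the formulas above already give -inf;
    # t == 0 gives z == -inf and log S == 0 exactly.
    return np.where(np.isposinf(t), -np.inf, out)


def survival_function(family: str, t, mu, sigma=1.0):
    """S(t) = P(T > t) for the given family; S(0) = 1, S(inf) = 0."""
    return np.exp(log_survival(family, t, mu, sigma))


def median_time(family: str, mu, sigma=1.0):
    """Closed-form median removal time.

    exponential: e^mu log 2; weibull: e^mu (log 2)^sigma;
    loglogistic and lognormal: e^mu (symmetric error laws).
    """
    _check_family(family)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if family == "exponential":
        return np.exp(mu) * np.log(2.0)
    if family == "weibull":
        return np.exp(mu) * np.log(2.0) ** sigma
    return np.exp(mu) + 0.0 * sigma


def sample_removal_times(family: str, mu, sigma, n: int, rng: np.random.Generator):
    """Draw ``n`` removal times as T = exp(mu + sigma W).

    W is standard normal (lognormal), logistic (loglogistic), Gumbel-minimum
    (weibull, i.e. log of a unit exponential), and the weibull law with
    sigma = 1 for exponential.
    """
    _check_family(family)
    if family == "exponential":
        family, sigma = "weibull", 1.0
    if family == "weibull":
        w = np.log(rng.exponential(size=n))
    elif family == "loglogistic":
        w = rng.logistic(size=n)
    else:
        w = rng.standard_normal(size=n)
    return np.exp(mu + sigma * w)
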