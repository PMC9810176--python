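"""Interval-censored survival regression for carcass persistence.

The model: removal time T of carcass i follows a log-location-scale family
with location mu_i = x_i' beta and scale sigma_i = exp(z_i' gamma), where
x_i and z_i are treatment-coded design rows built from categorical
covariates (region, habitat, season, ...).  Each carcass contributes the
interval-censored likelihood term S(L_i) - S(R_i) with S(+inf) = 0.

Model objects follow the statsmodels convention:

>>> model = IntervalCensoredSurvReg(obs, ModelSpec("weibull"))
>>> res = model.fit(seed=0)
>>> res.median_time({}), res.avg_persistence(30, {})

Results carry the coefficient vector, its covariance (inverse observed
information), the log-likelihood and AICc, and expose the derived
persistence quantities: median time, the average probability of persistence

    r(t) = (1/t) * integral_0^t S(u) du,

and parametric-bootstrap confidence intervals (multivariate-normal draws on
the estimator, scale coefficients drawn on the log link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import quad
from statsmodels.tools import numdiff

from . import families as fam
from .trials import ObservationSet

__all__ = [
    "ModelSpec",
    "FitError",
    "IntervalCensoredSurvReg",
    "SurvRegResults",
    "aicc",
    "select_model",
    "avg_persistence_scalar",
    "avg_persistence_batch",
    "percentile_ci",
]

#: strata smaller than this refuse to fit (mirrors the >= 8 carcass
#: aggregation threshold used when curating multi-study persistence data)
MIN_CARCASSES = 8


class FitError(RuntimeError):
    """Fit refused or failed (degenerate data, non-convergence, singular
    information)."""


def _normalise_terms(terms):
    """Terms are covariate names or ':'-joined interactions; normalise to
    tuples of factor names, e.g. 'season:region' -> ('season', 'region')."""
    out = []
    for t in terms or ():
        if isinstance(t, str):
            t = tuple(t.split(":"))
        out.append(tuple(t))
    return tuple(out)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: family plus covariate terms on location and scale.

    Terms are categorical covariate names; a two-way interaction is written
    ``"a:b"`` (or a tuple).  Any interaction requires both main effects in
    the same term list.  The exponential family has no free scale, so its
    ``scale_terms`` must be empty and sigma is fixed at 1.
    """

    family: str
    location_terms: tuple = ()
    scale_terms: tuple = ()

    def __post_init__(self):
        if self.family not in fam.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "location_terms", _normalise_terms(self.location_terms))
        object.__setattr__(self, "scale_terms", _normalise_terms(self.scale_terms))
        if self.family == "exponential" and self.scale_terms:
            raise ValueError("exponential model has no scale parameter to model")
        for terms in (self.location_terms, self.scale_terms):
            mains = {t[0] for t in terms if len(t) == 1}
            for t in terms:
                if len(t) > 1 and not set(t) <= mains:
                    raise ValueError(
                        f"interaction {':'.join(t)} requires its main effects "
                        "in the same term list"
                    )

    @property
    def has_scale(self) -> bool:
        return self.family != "exponential"

    def label(self) -> str:
        def side(terms):
            return " + ".join(":".join(t) for t in terms) or "1"

        s = f"{self.family}: loc ~ {side(self.location_terms)}"
        if self.has_scale:
            s += f", scale ~ {side(self.scale_terms)}"
        return s


def _design_matrix(cov: pd.DataFrame, terms, levels: dict) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept.

    ``levels`` maps covariate -> ordered observed levels; the first level is
    the reference absorbed in the intercept.  Interaction columns are
    products of main-effect dummies, restricted to level pairs observed in
    the data (all-zero interaction columns are dropped).
    """
    n = len(cov)
    cols = [np.ones(n)]
    names = ["intercept"]
    dummies = {}
    for c, levs in levels.items():
        codes = pd.Categorical(cov[c], categories=levs)
        if codes.isna().any():
            bad = sorted(set(cov[c]) - set(levs))
            raise FitError(f"covariate {c!r} has unfitted levels {bad}")
        arr = np.asarray(codes.codes)
        dummies[c] = {lev: (arr == i).astype(float) for i, lev in enumerate(levs)}
    for term in terms:
        if len(term) == 1:
            c = term[0]
            for lev in levels[c][1:]:
                cols.append(dummies[c][lev])
                names.append(f"{c}[{lev}]")
        else:
            a, b = term
            for la in levels[a][1:]:
                for lb in levels[b][1:]:
                    col = dummies[a][la] * dummies[b][lb]
                    if col.any():
                        cols.append(col)
                        names.append(f"{a}[{la}]:{b}[{lb}]")
    X = np.column_stack(cols)
    return X, names


def _observed_levels(cov: pd.DataFrame, terms) -> dict:
    """Ordered observed levels per covariate used by ``terms`` (first =
    reference, alphabetical for determinism)."""
    needed = sorted({c for t in terms for c in t})
    out = {}
    for c in needed:
        if c not in cov.columns:
            raise FitError(f"covariate {c!r} not present in the observations")
        out[c] = sorted(pd.unique(cov[c]))
    return out


class IntervalCensoredSurvReg:
    """Interval-censored survival regression model (statsmodels style).

    Parameters
    ----------
    obs : ObservationSet
        ``[L, R)`` intervals with covariate labels (``R = +inf`` for
        right-censored carcasses).
    spec : ModelSpec
        Family and covariate structure.
    """

    def __init__(self, obs: ObservationSet, spec: ModelSpec):
        self.obs = obs
        self.spec = spec
        all_terms = spec.location_terms + spec.scale_terms
        self.levels = _observed_levels(obs.covariates, all_terms)
        loc_levels = {c: l for c, l in self.levels.items() if any(c in t for t in spec.location_terms)}
        sc_levels = {c: l for c, l in self.levels.items() if any(c in t for t in spec.scale_terms)}
        self.X_loc, self.loc_names = _design_matrix(obs.covariates, spec.location_terms, loc_levels)
        if spec.has_scale:
            self.X_scale, self.scale_names = _design_matrix(obs.covariates, spec.scale_terms, sc_levels)
        else:
            self.X_scale, self.scale_names = np.zeros((len(obs), 0)), []
        self.k_loc = self.X_loc.shape[1]
        self.k_scale = self.X_scale.shape[1]
        self.k = self.k_loc + self.k_scale
        self.param_names = [f"loc.{n}" for n in self.loc_names] + [
            f"logscale.{n}" for n in self.scale_names
        ]
        self._aggregate()

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, spec: ModelSpec, camera_delta: float = 0.04):
        from .trials import intervals_from_frame

        return cls(intervals_from_frame(trials, camera_delta=camera_delta), spec)

    def _aggregate(self):
        """Collapse identical (L, R, design-row) observations into weights —
        discretised check schedules produce many duplicates, and the
        likelihood cost then scales with unique rows, not carcasses."""
        key = np.column_stack([self.obs.left, self.obs.right, self.X_loc, self.X_scale])
        _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
        w = np.zeros(len(idx))
        np.add.at(w, inv, self.obs.weights)
        self._L = self.obs.left[idx]
        self._R = self.obs.right[idx]
        self._Xl = self.X_loc[idx]
        self._Xs = self.X_scale[idx]
        self._w = w

    # --- likelihood ----------------------------------------------------

    def _split(self, params):
        params = np.asarray(params, dtype=float)
        return params[: self.k_loc], params[self.k_loc :]

    def nloglik(self, params) -> float:
        """Negative log-likelihood sum_i -w_i log[S(L_i) - S(R_i)].

        Returns ``+inf`` (not an exception) when any interval carries zero
        probability mass, so optimisers can back off.
        """
        beta, gamma = self._split(params)
        mu = self._Xl @ beta
        sigma = np.exp(self._Xs @ gamma) if self.spec.has_scale else 1.0
        logS_L = fam.log_survival(self.spec.family, self._L, mu, sigma)
        finite = np.isfinite(self._R)
        logp = np.array(logS_L, dtype=float)
        if finite.any():
            mu_f = mu[finite] if np.ndim(mu) else mu
            sig_f = sigma[finite] if np.ndim(sigma) else sigma
            logS_R = fam.log_survival(self.spec.family, self._R[finite], mu_f, sig_f)
            # log(S(L) - S(R)) = log S(L) + log(1 - exp(log S(R) - log S(L)))
            with np.errstate(divide="ignore", invalid="ignore"):
                diff = logS_R - logS_L[finite]
                logp[finite] = logS_L[finite] + np.log(-np.expm1(diff))
        if not np.all(np.isfinite(logp)):
            return np.inf
        return float(-(self._w * logp).sum())

    # --- fitting -------------------------------------------------------

    def _start_values(self, rng: np.random.Generator, jitter: float = 0.0):
        """Moment-style start: log interval midpoints (censored rows imputed
        at 1.25x their left bound), optionally jittered."""
        R_eff = np.where(np.isfinite(self._R), self._R, 1.25 * np.maximum(self._L, 1.0))
        mid = np.maximum(0.5 * (np.maximum(self._L, 1e-3) + R_eff), 1e-3)
        logs = np.repeat(np.log(mid), np.maximum(self._w, 1).astype(int))
        mu0 = float(np.mean(logs))
        s0 = float(max(np.std(logs), 0.3))
        params = np.zeros(self.k)
        params[0] = mu0
        if self.spec.has_scale:
            params[self.k_loc] = np.log(s0)
        if jitter:
            params = params + jitter * rng.standard_normal(self.k)
        return params

    def fit(self, n_starts: int = 5, seed: int = 0, min_n: int = MIN_CARCASSES) -> "SurvRegResults":
        """Maximise the likelihood from multiple starts (quasi-Newton).

        Raises :class:`FitError` for degenerate data (fewer than ``min_n``
        carcasses, all rows right-censored, too few observations for the
        parameter count), if no start converges, or if the observed
        information at the optimum is singular.
        """
        n = self.obs.n
        if n < max(min_n, self.k + 2):
            raise FitError(
                f"refusing to fit: {n} carcasses for {self.k} parameters "
                f"(minimum {max(min_n, self.k + 2)})"
            )
        if not np.isfinite(self._R).any():
            raise FitError("all observations are right-censored; likelihood "
                           "is maximised at the boundary")
        rng = np.random.default_rng(seed)
        best = None
        with warnings.catch_warnings():
            # the likelihood legitimately returns +inf at zero-mass intervals;
            # finite-difference gradients then emit benign invalid-value noise
            warnings.simplefilter("ignore", RuntimeWarning)
            for i in range(n_starts):
                x0 = self._start_values(rng, jitter=0.0 if i == 0 else 0.5)
                try:
                    res = optimize.minimize(
                        self.nloglik, x0, method="BFGS",
                        options={"maxiter": 500, "gtol": 1e-7},
                    )
                except (ValueError, FloatingPointError):  # pragma: no cover
                    continue
                if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
                    best = res
        if best is None:
            raise FitError("optimisation failed from every start")
        # polish with Nelder-Mead if the gradient stop was rough
        polish = optimize.minimize(self.nloglik, best.x, method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        params = polish.x if polish.fun <= best.fun else best.x
        nll = min(polish.fun, best.fun)
        hess = numdiff.approx_hess1(params, self.nloglik)
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            raise FitError("singular observed information (boundary/degenerate fit)") from None
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
            raise FitError("observed information not positive definite at the optimum")
        return SurvRegResults(self, params, vcov, -nll)


class SurvRegResults:
    """Fitted interval-censored survival model.

    Attributes
    ----------
    params : ndarray
        Location coefficients followed by log-scale coefficients.
    vcov : ndarray
        Inverse observed information at the optimum.
    llf : float
        Maximised log-likelihood.
    aicc : float
        Small-sample corrected AIC with n = carcass count.
    """

    def __init__(self, model: IntervalCensoredSurvReg, params, vcov, llf):
        self.model = model
        self.spec = model.spec
        self.params = np.asarray(params, dtype=float)
        self.vcov = np.asarray(vcov, dtype=float)
        self.llf = float(llf)
        self.k = model.k
        self.nobs = model.obs.n
        self.aicc = aicc(self.llf, self.k, self.nobs)

    # --- parameter access ---------------------------------------------

    @property
    def beta_location(self):
        return self.params[: self.model.k_loc]

    @property
    def gamma_scale(self):
        return self.params[self.model.k_loc :]

    def bse(self):
        return np.sqrt(np.diag(self.vcov))

    def _cell_design(self, cell: dict):
        cov = pd.DataFrame([{c: cell.get(c) for c in self.model.levels} or {}])
        loc_levels = {c: l for c, l in self.model.levels.items()
                      if any(c in t for t in self.spec.location_terms)}
        sc_levels = {c: l for c, l in self.model.levels.items()
                     if any(c in t for t in self.spec.scale_terms)}
        for c in loc_levels | sc_levels:
            if cell.get(c) is None:
                raise ValueError(f"cell is missing covariate {c!r}")
        # a cell may produce fewer interaction columns than the fit (the fit
        # dropped unobserved pairs); align by column name against the fit
        return self._align(cov, loc_levels, sc_levels)

    def _align(self, cov, loc_levels, sc_levels):
        Xl_full, names_l = _design_matrix(cov, self.spec.location_terms, loc_levels)
        Xs_full, names_s = (
            _design_matrix(cov, self.spec.scale_terms, sc_levels)
            if self.spec.has_scale
            else (np.zeros((1, 0)), [])
        )
        out_l = np.zeros(self.model.k_loc)
        for j, name in enumerate(self.model.loc_names):
            if name in names_l:
                out_l[j] = Xl_full[0, names_l.index(name)]
        out_s = np.zeros(self.model.k_scale)
        for j, name in enumerate(self.model.scale_names):
            if name in names_s:
                out_s[j] = Xs_full[0, names_s.index(name)]
        return out_l, out_s

    def mu_sigma(self, cell: dict, params=None):
        """Location and scale for a covariate cell (dict of labels)."""
        params = self.params if params is None else np.asarray(params, dtype=float)
        beta = params[: self.model.k_loc]
        gamma = params[self.model.k_loc :]
        xl, xs = self._cell_design(cell or {})
        mu = float(xl @ beta)
        sigma = float(np.exp(xs @ gamma)) if self.spec.has_scale else 1.0
        return mu, sigma

    # --- derived quantities --------------------------------------------

    def survival(self, t, cell: dict | None = None, params=None):
        """S(t) for a covariate cell; t may be an array."""
        mu, sigma = self.mu_sigma(cell or {}, params)
        return fam.survival_function(self.spec.family, t, mu, sigma)

    def median_time(self, cell: dict | None = None, params=None) -> float:
        """Median persistence time in days (closed form per family)."""
        mu, sigma = self.mu_sigma(cell or {}, params)
        return float(fam.median_time(self.spec.family, mu, sigma))

    def avg_persistence(self, t: float, cell: dict | None = None, params=None) -> float:
        """Average probability of persistence r(t) = (1/t) int_0^t S(u) du."""
        mu, sigma = self.mu_sigma(cell or {}, params)
        return avg_persistence_scalar(self.spec.family, mu, sigma, t)

    # --- uncertainty ----------------------------------------------------

    def bootstrap_draws(self, n_boot: int, seed: int) -> np.ndarray:
        """Parametric bootstrap on the estimator: multivariate-normal draws
        centred at the estimates with covariance ``vcov``.  Scale
        coefficients live on the log link, so every draw has sigma > 0.
        A non-positive-semidefinite covariance raises (no silent repair).
        """
        eig = np.linalg.eigvalsh(0.5 * (self.vcov + self.vcov.T))
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise FitError("coefficient covariance is not positive semidefinite")
        rng = np.random.default_rng(seed)
        return rng.multivariate_normal(self.params, self.vcov, size=n_boot,
                                       method="eigh")

    def avg_persistence_draws(self, t: float, cell: dict | None, draws: np.ndarray) -> np.ndarray:
        """r(t) for a covariate cell under each bootstrap coefficient draw
        (vectorised Gauss-Legendre quadrature)."""
        xl, xs = self._cell_design(cell or {})
        mu = draws[:, : self.model.k_loc] @ xl
        if self.spec.has_scale:
            sigma = np.exp(draws[:, self.model.k_loc :] @ xs)
        else:
            sigma = np.ones(len(draws))
        return avg_persistence_batch(self.spec.family, mu, sigma, t)

    def persistence_estimates(
        self,
        cells: list[dict],
        intervals=(14, 30, 60, 90),
        n_boot: int = 1000,
        seed: int = 0,
        level: float = 0.90,
    ) -> pd.DataFrame:
        """Median time and r(t) per cell and interval, with percentile
        bootstrap CIs.  One row per cell x interval."""
        draws = self.bootstrap_draws(n_boot, seed) if n_boot else None
        rows = []
        for cell in cells:
            med = self.median_time(cell)
            if draws is not None:
                med_d = np.array([self.median_time(cell, params=d) for d in draws])
                med_ci = percentile_ci(med_d, level)
            else:
                med_ci = (np.nan, np.nan)
            for t in intervals:
                r = self.avg_persistence(t, cell)
                if draws is not None:
                    mu_s = np.array([self.mu_sigma(cell, params=d) for d in draws])
                    r_d = avg_persistence_batch(self.spec.family, mu_s[:, 0], mu_s[:, 1], t)
                    ci = percentile_ci(r_d, level)
                else:
                    ci = (np.nan, np.nan)
                rows.append({**cell, "interval": t, "median_days": med,
                             "median_lo": med_ci[0], "median_hi": med_ci[1],
                             "r_hat": r, "r_lo": ci[0], "r_hi": ci[1],
                             "n_boot": n_boot})
        return pd.DataFrame(rows)

    # --- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Interval-censored survival regression",
            f"  model:  {self.spec.label()}",
            f"  n = {self.nobs} carcasses, k = {self.k} parameters",
            f"  log-likelihood = {self.llf:.3f}, AICc = {self.aicc:.3f}",
            "",
            f"  {'coefficient':<34s}{'estimate':>10s}{'std err':>10s}",
        ]
        for name, est, se in zip(self.model.param_names, self.params, self.bse()):
            lines.append(f"  {name:<34s}{est:>10.4f}{se:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "location_terms": [":".join(t) for t in self.spec.location_terms],
            "scale_terms": [":".join(t) for t in self.spec.scale_terms],
            "param_names": list(self.model.param_names),
            "params": self.params.tolist(),
            "vcov": self.vcov.tolist(),
            "llf": self.llf,
            "k": self.k,
            "n": self.nobs,
            "aicc": self.aicc,
        }

    def plot_survival(self, cells, t_max=90.0, ax=None, labels=None):
        """Plot fitted S(t) for one or more covariate cells."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0, t_max, 200)
        for i, cell in enumerate(cells):
            lab = labels[i] if labels else ", ".join(f"{v}" for v in cell.values()) or "all"
            ax.plot(t, self.survival(t, cell), label=lab)
        ax.set_xlabel("days since placement")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


# --- model comparison ----------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 llf + 2k + 2k(k+1)/(n-k-1).

    Returns ``+inf`` when n <= k + 1 (model inadmissible at this sample
    size).
    """
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_model(fits):
    """Most parsimonious model within 2 AICc points of the best.

    Among candidates with ``aicc - min(aicc) <= 2``, return the one with the
    fewest parameters; ties on parameter count break to the smaller AICc.
    Deterministic and invariant to input order.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_model requires at least one candidate")
    best = min(f.aicc for f in fits)
    window = [f for f in fits if f.aicc - best <= 2.0]
    return min(window, key=lambda f: (f.k, f.aicc))


# --- average probability of persistence ----------------------------------


def avg_persistence_scalar(family: str, mu: float, sigma: float, t: float) -> float:
    """r(t) = (1/t) int_0^t S(u) du by adaptive quadrature (abs tol 1e-8).

    The exponential closed form (e^mu / t)(1 - exp(-t/e^mu)) is available as
    an independent cross-check in the tests.
    """
    if t <= 0:
        raise ValueError("search interval t must be positive")
    val, _ = quad(
        lambda u: fam.survival_function(family, u, mu, sigma),
        0.0, t, epsabs=1e-8, epsrel=1e-10, limit=200,
    )
    return val / t


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)


def avg_persistence_batch(family: str, mu, sigma, t: float) -> np.ndarray:
    """Vectorised r(t) over arrays of (mu, sigma) — fixed 256-node
    Gauss-Legendre quadrature on [0, t], used for bootstrap batches.
    Agrees with the adaptive scalar path to well below 1e-6 for these
    smooth survival curves."""
    if t <= 0:
        raise ValueError("search interval t must be positive")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))[:, None]
    u = 0.5 * t * (_GL_NODES + 1.0)[None, :]
    s = fam.survival_function(family, u, mu, sigma)
    return (0.5 * t * (s * _GL_WEIGHTS[None, :]).sum(axis=1)) / t


def percentile_ci(values, level: float = 0.90) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval with linear interpolation
    between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("percentile_ci needs at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)
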