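"""Two-stage scaling of game bird persistence to raptor persistence.

Game bird carcasses are the routine surrogate in post-construction fatality
monitoring, but they persist much shorter than raptor carcasses, so fatality
estimates built on game bird persistence are biased high for raptors.  The
scaling procedure corrects this:

**Stage 0 — analysis groups.** Studies with both bird types are aggregated
(same site first, then same state and habitat) until each group holds at
least 8 carcasses of each bird type; groups never span states.

**Stage 1 — per-group persistence.** For each group and bird type an
interval-censored survival model is selected by AICc (season enters as a
candidate covariate only when every season in the group has at least 8
carcasses), 1,000 parameter sets are drawn by parametric bootstrap, and the
average probability of persistence r(t) is computed per draw for 14-, 30-,
60- and 90-day search intervals.  Game bird and raptor draws are paired by
replicate index.

**Stage 2 — logit-linear mixed-effects model.** On the pooled pairs,

    logit r_raptor = b0 + b1 * r_gamebird + season/region/habitat offsets
                     + (u0_g + u1_g * r_gamebird) + eps,

with correlated random intercept and slope by analysis group.  Candidate
fixed-effect sets (all subsets of {season, region, habitat}; the game bird
slope is always included; no interactions) are fit by maximum likelihood
and ranked by AICc with the parsimony-within-2 rule.  Baseline levels
absorbed in the intercept are fall, Region 1 (R1) and cropland when present.

The fitted model predicts raptor persistence from game bird persistence for
new sites (fixed effects only) or for groups in the training data (adding
their BLUPs).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .survival import (
    FitError,
    IntervalCensoredSurvReg,
    ModelSpec,
    aicc,
    percentile_ci,
    select_model,
)
from .trials import intervals_from_frame

log = logging.getLogger(__name__)

#: probabilities are clipped into this open interval before the logit
CLIP_EPS = 1e-6

#: reference levels absorbed in the Stage-2 intercept when present
BASELINES = {"season": "fall", "region": "R1", "habitat": "cropland"}

STAGE2_COVARIATES = ("season", "region", "habitat")

__all__ = [
    "AnalysisGroup",
    "ScalingData",
    "build_analysis_groups",
    "summarize_studies",
    "stage1_pairs",
    "PersistenceScaling",
    "PersistenceScalingResults",
]


def clipped_logit(p):
    return logit(np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS))


@dataclass
class AnalysisGroup:
    """A study, or an aggregation of studies at the same site or in the same
    state and habitat, holding at least ``min_n`` carcasses per bird type."""

    group_id: str
    member_studies: list
    state: str
    region: str
    habitat: str
    n_raptor: int
    n_gamebird: int
    seasons_present: set = field(default_factory=set)

    def deficient(self, min_n: int = 8) -> bool:
        return self.n_raptor < min_n or self.n_gamebird < min_n


def summarize_studies(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-study summary (site, state, region, habitat, carcass counts per
    bird type, seasons present) from a trial table."""
    rows = []
    for study, df in trials.groupby("study_id"):
        rows.append({
            "study_id": study,
            "site_id": df["site_id"].iloc[0],
            "state": df["state"].iloc[0],
            "region": df["region"].iloc[0],
            "habitat": df["habitat"].iloc[0],
            "n_raptor": int((df["bird_type"] == "raptor").sum()),
            "n_gamebird": int((df["bird_type"] == "gamebird").sum()),
            "seasons": set(df["season"]),
        })
    return pd.DataFrame(rows).sort_values(["site_id", "study_id"]).reset_index(drop=True)


def _merge(a: AnalysisGroup, b: AnalysisGroup) -> AnalysisGroup:
    if a.state != b.state or a.habitat != b.habitat:
        raise ValueError("groups may only merge within the same state and habitat")
    return AnalysisGroup(
        group_id=a.group_id,
        member_studies=sorted(a.member_studies + b.member_studies),
        state=a.state,
        region=a.region,
        habitat=a.habitat,
        n_raptor=a.n_raptor + b.n_raptor,
        n_gamebird=a.n_gamebird + b.n_gamebird,
        seasons_present=a.seasons_present | b.seasons_present,
    )


def build_analysis_groups(studies: pd.DataFrame, min_n: int = 8) -> list[AnalysisGroup]:
    """Greedy aggregation of study summaries into analysis groups.

    Order of aggregation: studies at the same site first (alphabetical by
    site then study id), then remaining deficient units with others in the
    same state and habitat.  Groups never span states.  Units still below
    ``min_n`` for either bird type after exhausting candidates are excluded
    with a logged reason (exclusion is an outcome, not an exception).
    """
    studies = studies.sort_values(["site_id", "study_id"]).reset_index(drop=True)
    units = [
        AnalysisGroup(
            group_id=str(r.study_id),
            member_studies=[str(r.study_id)],
            state=str(r.state),
            region=str(r.region),
            habitat=str(r.habitat),
            n_raptor=int(r.n_raptor),
            n_gamebird=int(r.n_gamebird),
            seasons_present=set(r.seasons) if hasattr(r, "seasons") and isinstance(r.seasons, (set, list, tuple)) else set(),
        )
        for r in studies.itertuples(index=False)
    ]
    # phase 1: merge within site
    by_site = {}
    for u, site in zip(units, studies["site_id"].astype(str)):
        by_site.setdefault(site, []).append(u)
    merged = []
    for site in sorted(by_site):
        done, acc = [], None
        for u in by_site[site]:
            acc = u if acc is None else _merge(acc, u)
            if not acc.deficient(min_n):
                done.append(acc)
                acc = None
        if acc is not None:
            if done:  # leftover deficient unit folds into the site's last group
                done[-1] = _merge(done[-1], acc)
            else:
                done.append(acc)
        merged.extend(done)
    # phase 2: merge remaining deficient units within state + habitat
    adequate = [u for u in merged if not u.deficient(min_n)]
    deficient = [u for u in merged if u.deficient(min_n)]
    by_cell = {}
    for u in deficient:
        by_cell.setdefault((u.state, u.habitat), []).append(u)
    for cell in sorted(by_cell):
        pool = sorted(by_cell[cell], key=lambda u: u.group_id)
        acc = None
        for u in pool:
            acc = u if acc is None else _merge(acc, u)
            if not acc.deficient(min_n):
                adequate.append(acc)
                acc = None
        if acc is not None:
            hosts = [g for g in adequate if (g.state, g.habitat) == cell]
            if hosts:
                host = min(hosts, key=lambda g: g.group_id)
                adequate[adequate.index(host)] = _merge(host, acc)
            else:
                log.info(
                    "excluding %s (state %s, habitat %s): only %d raptor / %d "
                    "game bird carcasses and no same-state candidates",
                    acc.group_id, acc.state, acc.habitat, acc.n_raptor, acc.n_gamebird,
                )
    return sorted(adequate, key=lambda g: g.group_id)


@dataclass
class ScalingData:
    """Stage-1 output: paired bootstrap draws and point estimates.

    ``draws`` has one row per (group, season, interval, replicate) with the
    paired game bird and raptor r-hat values; ``points`` the corresponding
    point estimates (one row per group, season, interval).
    """

    draws: pd.DataFrame
    points: pd.DataFrame


def _stage1_candidates(season_eligible: bool):
    term_sets = [(), (("season",),)] if season_eligible else [()]
    specs = []
    for family in ("exponential", "weibull", "loglogistic", "lognormal"):
        scale_sets = [()] if family == "exponential" else term_sets
        for loc in term_sets:
            for sc in scale_sets:
                specs.append(ModelSpec(family, loc, sc))
    return specs


def stage1_pairs(
    groups: list[AnalysisGroup],
    trials: pd.DataFrame,
    intervals=(14, 30, 60, 90),
    B: int = 1000,
    seed: int = 0,
    camera_delta: float = 0.04,
    min_per_season: int = 8,
) -> ScalingData:
    """Fit per-group survival models and emit paired bootstrap r-hat draws.

    For each group and bird type: candidate families are fit (season is a
    candidate covariate only if every season represented in that bird
    type's data holds at least ``min_per_season`` carcasses), the AICc
    parsimony rule selects the model, ``B`` parameter sets are drawn by
    parametric bootstrap, and r(t) is evaluated per draw for every season
    cell and search interval.  Game bird and raptor values are paired by
    replicate index within (group, season, interval).  Groups for which
    either bird type fails to fit are dropped with a logged reason.
    """
    rows_d, rows_p = [], []
    root = np.random.SeedSequence(seed)
    for gi, group in enumerate(groups):
        gdf = trials[trials["study_id"].astype(str).isin(group.member_studies)]
        per_bird = {}
        failed = None
        for bi, bird in enumerate(("gamebird", "raptor")):
            bdf = gdf[gdf["bird_type"] == bird]
            if bdf.empty:
                failed = f"no {bird} records"
                break
            season_counts = bdf["season"].value_counts()
            eligible = bool((season_counts >= min_per_season).all()) and len(season_counts) > 1
            obs = intervals_from_frame(bdf, camera_delta=camera_delta)
            child = np.random.SeedSequence([seed, gi, bi]).generate_state(1)[0] % (2**31)
            fits = []
            for spec in _stage1_candidates(eligible):
                try:
                    fits.append(IntervalCensoredSurvReg(obs, spec).fit(seed=int(child)))
                except (FitError, ValueError) as exc:
                    log.debug("group %s %s candidate %s dropped: %s",
                              group.group_id, bird, spec.label(), exc)
            if not fits:
                failed = f"every {bird} candidate failed"
                break
            res = select_model(fits)
            draws = res.bootstrap_draws(B, seed=int(child) + 1)
            per_bird[bird] = (res, draws, set(bdf["season"]))
        if failed:
            log.warning("analysis group %s dropped: %s", group.group_id, failed)
            continue
        seasons = sorted(per_bird["gamebird"][2] & per_bird["raptor"][2])
        if not seasons:
            seasons = sorted(per_bird["gamebird"][2] | per_bird["raptor"][2])
        for season in seasons:
            cell = {"season": season}
            skip = False
            for bird in ("gamebird", "raptor"):
                res = per_bird[bird][0]
                if "season" in res.model.levels and season not in res.model.levels["season"]:
                    log.info("group %s: season %s not fitted for %s; skipped",
                             group.group_id, season, bird)
                    skip = True
            if skip:
                continue
            for t in intervals:
                vals = {}
                for bird in ("gamebird", "raptor"):
                    res, draws, _ = per_bird[bird]
                    c = cell if "season" in res.model.levels else {}
                    vals[bird] = np.clip(res.avg_persistence_draws(t, c, draws),
                                         CLIP_EPS, 1 - CLIP_EPS)
                    vals[bird + "_pt"] = float(
                        np.clip(res.avg_persistence(t, c), CLIP_EPS, 1 - CLIP_EPS)
                    )
                base = {
                    "group_id": group.group_id, "season": season,
                    "region": group.region, "habitat": group.habitat,
                    "interval": t,
                }
                rows_p.append({**base, "gamebird_r": vals["gamebird_pt"],
                               "raptor_r": vals["raptor_pt"]})
                for b in range(B):
                    rows_d.append({**base, "replicate": b + 1,
                                   "gamebird_r": vals["gamebird"][b],
                                   "raptor_r": vals["raptor"][b]})
    return ScalingData(pd.DataFrame(rows_d), pd.DataFrame(rows_p))


# --- Stage 2: logit-linear mixed-effects scaling model --------------------


def _ordered_levels(series: pd.Series, covariate: str) -> list[str]:
    levels = sorted(pd.unique(series))
    base = BASELINES.get(covariate)
    if base in levels:
        levels = [base] + [l for l in levels if l != base]
    return levels


class _CandidateFit:
    """Holds one fitted Stage-2 candidate for AICc comparison."""

    def __init__(self, covariates, result, k, nobs, levels):
        self.covariates = covariates
        self.result = result
        self.k = k
        self.nobs = nobs
        self.levels = levels
        self.llf = result.llf
        self.aicc = aicc(result.llf, k, nobs)


class PersistenceScaling:
    """Stage-2 model: logit raptor r-hat on game bird r-hat (statsmodels
    style; ``fit`` returns a :class:`PersistenceScalingResults`).

    Parameters
    ----------
    data : DataFrame
        Stage-1 pairs with columns group_id, season, region, habitat,
        interval, replicate, gamebird_r, raptor_r (``ScalingData.draws``).
    """

    def __init__(self, data: pd.DataFrame):
        need = {"group_id", "gamebird_r", "raptor_r"}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"scaling data is missing columns {sorted(missing)}")
        if data["group_id"].nunique() < 2:
            raise ValueError("at least 2 analysis groups are required")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_stage1(cls, scaling_data: ScalingData):
        return cls(scaling_data.draws)

    def _design(self, covariates):
        """Fixed-effect design: intercept, game bird slope, then treatment
        dummies per covariate (reference = fall / R1 / cropland when
        present).  Covariates constant in the data are dropped with a note."""
        used, levels = [], {}
        for cov in covariates:
            levs = _ordered_levels(self.data[cov], cov)
            if len(levs) < 2:
                log.info("covariate %r has a single level (%s); dropped from "
                         "the candidate", cov, levs[0])
                continue
            used.append(cov)
            levels[cov] = levs
        cols = {"intercept": np.ones(len(self.data)),
                "gamebird_r": self.data["gamebird_r"].to_numpy(float)}
        for cov in used:
            for lev in levels[cov][1:]:
                cols[f"{cov}[{lev}]"] = (self.data[cov] == lev).to_numpy(float)
        return pd.DataFrame(cols), levels

    def fit(self, candidate_fixed=None, seed: int = 0) -> "PersistenceScalingResults":
        """Fit all candidate fixed-effect sets by ML, rank by AICc, refit
        nothing (the winner is reported from the same ML fit).

        ``candidate_fixed``: iterable of covariate-name tuples; defaults to
        all 8 subsets of {season, region, habitat}.  Every candidate
        includes the game bird slope; the random structure is fixed at a
        correlated random intercept and slope by analysis group.
        """
        if candidate_fixed is None:
            candidate_fixed = [
                c
                for r in range(len(STAGE2_COVARIATES) + 1)
                for c in itertools.combinations(STAGE2_COVARIATES, r)
            ]
        y = clipped_logit(self.data["raptor_r"].to_numpy(float))
        groups = self.data["group_id"].to_numpy()
        exog_re = pd.DataFrame({
            "intercept": np.ones(len(self.data)),
            "gamebird_r": self.data["gamebird_r"].to_numpy(float),
        })
        fits = []
        for covs in candidate_fixed:
            X, levels = self._design(covs)
            model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=False, method=["lbfgs", "bfgs", "powell"],
                                    maxiter=500)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    raise FitError(
                        f"stage-2 candidate {covs or ('intercept-only',)} failed: {exc}"
                    ) from exc
            # k: fixed effects + 3 random-effect (co)variances + residual
            k = X.shape[1] + 4
            fits.append(_CandidateFit(tuple(covs), res, k, len(self.data), levels))
        winner = select_model(fits)
        return PersistenceScalingResults(winner, fits, self.data)


class PersistenceScalingResults:
    """Fitted scaling model: fixed effects, random-effect dispersions,
    residual error, ICC, per-group BLUPs, and the prediction interface."""

    def __init__(self, winner: _CandidateFit, candidates=None, data=None):
        res = winner.result
        fe = res.fe_params
        self.fixed = {name: float(v) for name, v in fe.items()}
        self.fixed_se = {name: float(v) for name, v in res.bse_fe.items()}
        self.cov_fixed = np.asarray(res.cov_params())[: len(fe), : len(fe)]
        cov_re = np.asarray(res.cov_re)
        self.sd_intercept = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        self.sd_slope = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        denom = self.sd_intercept * self.sd_slope
        self.re_correlation = float(cov_re[0, 1] / denom) if denom > 0 else 0.0
        self.resid_sd = float(np.sqrt(res.scale))
        # declared ICC: intercept variance over intercept + residual variance
        self.icc = float(cov_re[0, 0] / (cov_re[0, 0] + res.scale))
        self.icc_formula = "sd_intercept^2 / (sd_intercept^2 + resid_sd^2)"
        self.blups = {
            str(g): (float(v.iloc[0]), float(v.iloc[1]))
            for g, v in res.random_effects.items()
        }
        self.n_groups = len(self.blups)
        self.levels = winner.levels
        self.covariates = winner.covariates
        self.llf = float(res.llf)
        self.k = winner.k
        self.nobs = winner.nobs
        self.aicc = winner.aicc
        self.candidate_table = (
            pd.DataFrame(
                [{"fixed_effects": " + ".join(("gamebird_r",) + f.covariates),
                  "k": f.k, "llf": f.llf, "aicc": f.aicc}
                 for f in candidates]
            ).sort_values("aicc").reset_index(drop=True)
            if candidates
            else None
        )
        self._mixedlm = res

    # --- constructors ---------------------------------------------------

    @classmethod
    def from_coefficients(cls, fixed: dict, levels: dict | None = None,
                          resid_sd: float = np.nan, sd_intercept: float = 0.0,
                          sd_slope: float = 0.0, re_correlation: float = 0.0,
                          blups: dict | None = None):
        """Build a predictor from published fixed-effect coefficients.

        ``fixed`` maps coefficient names (``intercept``, ``gamebird_r``,
        ``season[spring]``, ``region[R3]``, ...) to values.  ``levels``
        (covariate -> level list with the baseline first) defaults to the
        levels implied by the coefficient names plus the standard baselines.
        """
        self = cls.__new__(cls)
        self.fixed = {k: float(v) for k, v in fixed.items()}
        if "intercept" not in self.fixed or "gamebird_r" not in self.fixed:
            raise ValueError("fixed effects must include 'intercept' and 'gamebird_r'")
        if levels is None:
            levels = {}
            for name in self.fixed:
                if "[" in name:
                    cov, lev = name[:-1].split("[")
                    levels.setdefault(cov, [BASELINES.get(cov)])
                    levels[cov].append(lev)
            levels = {c: [l for l in ls if l is not None] for c, ls in levels.items()}
        self.levels = levels
        self.covariates = tuple(levels)
        self.fixed_se = {}
        self.cov_fixed = None
        self.sd_intercept = float(sd_intercept)
        self.sd_slope = float(sd_slope)
        self.re_correlation = float(re_correlation)
        self.resid_sd = float(resid_sd)
        self.icc = np.nan
        self.icc_formula = "sd_intercept^2 / (sd_intercept^2 + resid_sd^2)"
        self.blups = blups or {}
        self.n_groups = len(self.blups)
        self.llf = np.nan
        self.k = len(self.fixed) + 4
        self.nobs = 0
        self.aicc = np.nan
        self.candidate_table = None
        self._mixedlm = None
        return self

    # --- prediction -----------------------------------------------------

    def _offset(self, covariate: str, label) -> float:
        if covariate not in self.levels:
            return 0.0  # covariate not in the selected model
        if label is None:
            raise ValueError(f"prediction requires a {covariate!r} label")
        levels = self.levels[covariate]
        key = f"{covariate}[{label}]"
        if key in self.fixed:
            return self.fixed[key]
        if levels and label == levels[0]:
            return 0.0  # baseline absorbed in the intercept
        raise ValueError(
            f"{covariate} level {label!r} was not fitted (known: {levels})"
        )

    def linear_predictor(self, gamebird_r: float, season=None, region=None,
                         habitat=None, group_id=None) -> float:
        if not 0.0 < gamebird_r < 1.0:
            raise ValueError("gamebird_r must lie strictly between 0 and 1")
        b0 = self.fixed["intercept"]
        b1 = self.fixed["gamebird_r"]
        if group_id is not None and str(group_id) in self.blups:
            u0, u1 = self.blups[str(group_id)]
            b0, b1 = b0 + u0, b1 + u1
        eta = b0 + b1 * gamebird_r
        for cov, lab in (("season", season), ("region", region), ("habitat", habitat)):
            eta += self._offset(cov, lab)
        return float(eta)

    def predict(self, gamebird_r: float, season=None, region=None, habitat=None,
                group_id=None, with_interval: bool = False, level: float = 0.90,
                n_sim: int = 4000, seed: int = 0):
        """Predicted raptor average probability of persistence.

        A known ``group_id`` adds that group's BLUP intercept/slope; an
        unknown (or None) group uses fixed effects only.  With
        ``with_interval=True`` an interval is simulated from the fixed-effect
        covariance plus, for unknown groups, the random-effect law; returns
        ``(point, (lo, hi))``.
        """
        eta = self.linear_predictor(gamebird_r, season, region, habitat, group_id)
        point = float(expit(eta))
        if not with_interval:
            return point
        if self.cov_fixed is None:
            raise ValueError("no coefficient covariance available for intervals")
        rng = np.random.default_rng(seed)
        names = list(self.fixed)
        beta = rng.multivariate_normal(
            np.array([self.fixed[n] for n in names]), self.cov_fixed, size=n_sim,
            method="eigh",
        )
        x = np.zeros(len(names))
        x[names.index("intercept")] = 1.0
        x[names.index("gamebird_r")] = gamebird_r
        for cov, lab in (("season", season), ("region", region), ("habitat", habitat)):
            if cov in self.levels:
                key = f"{cov}[{lab}]"
                if key in names:
                    x[names.index(key)] = 1.0
        etas = beta @ x
        known = group_id is not None and str(group_id) in self.blups
        if known:
            u0, u1 = self.blups[str(group_id)]
            etas = etas + u0 + u1 * gamebird_r
        else:
            c = self.re_correlation * self.sd_intercept * self.sd_slope
            re_cov = np.array([[self.sd_intercept ** 2, c], [c, self.sd_slope ** 2]])
            u = rng.multivariate_normal(np.zeros(2), re_cov, size=n_sim, method="eigh")
            etas = etas + u[:, 0] + u[:, 1] * gamebird_r
        return point, percentile_ci(expit(etas), level)

    # --- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Logit-linear mixed-effects scaling model (raptor ~ game bird r-hat)",
            f"  n obs = {self.nobs}, analysis groups = {self.n_groups}, "
            f"k = {self.k}, AICc = {self.aicc:.2f}",
            "",
            f"  {'fixed effect':<26s}{'estimate':>10s}{'std err':>10s}",
        ]
        for name, v in self.fixed.items():
            se = self.fixed_se.get(name, np.nan)
            lines.append(f"  {name:<26s}{v:>10.3f}{se:>10.3f}")
        lines += [
            "",
            f"  random effects by analysis group:",
            f"    sd(intercept) = {self.sd_intercept:.3f}, sd(slope) = "
            f"{self.sd_slope:.3f}, corr = {self.re_correlation:.3f}",
            f"    residual sd = {self.resid_sd:.3f}",
            f"    ICC = {self.icc:.3f}   [{self.icc_formula}]",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed,
            "fixed_se": self.fixed_se,
            "levels": {c: list(l) for c, l in self.levels.items()},
            "sd_intercept": self.sd_intercept,
            "sd_slope": self.sd_slope,
            "re_correlation": self.re_correlation,
            "resid_sd": self.resid_sd,
            "icc": self.icc,
            "icc_formula": self.icc_formula,
            "blups": self.blups,
            "n_groups": self.n_groups,
            "llf": self.llf,
            "k": self.k,
            "n": self.nobs,
            "aicc": self.aicc,
            "cov_fixed": None if self.cov_fixed is None else np.asarray(self.cov_fixed).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PersistenceScalingResults":
        with open(path) as fh:
            d = json.load(fh)
        self = cls.from_coefficients(
            d["fixed"], levels=d.get("levels"),
            resid_sd=d.get("resid_sd", np.nan),
            sd_intercept=d.get("sd_intercept", 0.0),
            sd_slope=d.get("sd_slope", 0.0),
            re_correlation=d.get("re_correlation", 0.0),
            blups={k: tuple(v) for k, v in (d.get("blups") or {}).items()},
        )
        self.fixed_se = d.get("fixed_se", {})
        if d.get("cov_fixed") is not None:
            self.cov_fixed = np.asarray(d["cov_fixed"])
        self.icc = d.get("icc", np.nan)
        self.llf = d.get("llf", np.nan)
        self.nobs = d.get("n", 0)
        self.aicc = d.get("aicc", np.nan)
        return self

    def plot_scaling(self, data: pd.DataFrame | None = None, ax=None,
                     season=None, region=None, habitat=None):
        """Predicted raptor vs game bird persistence curve, optionally over
        the Stage-1 pairs used for fitting."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if data is not None:
            ax.plot(data["gamebird_r"], data["raptor_r"], ".", ms=2, alpha=0.2,
                    color="grey", label="stage-1 bootstrap pairs")
        g = np.linspace(0.01, 0.99, 99)
        labels = {c: (season, region, habitat)[i]
                  for i, c in enumerate(("season", "region", "habitat"))}
        for c in self.levels:
            if labels[c] is None:
                labels[c] = self.levels[c][0]
        pred = [self.predict(x, **labels) for x in g]
        ax.plot(g, pred, lw=2, label="scaling model")
        ax.set_xlabel("game bird average probability of persistence")
        ax.set_ylabel("predicted raptor average probability of persistence")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
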