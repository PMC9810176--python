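"""Synthetic carcass persistence trials with known ground truth.

Two layers of simulation:

1. **Removal-time cells** (:func:`simulate_removal_times`): removal times
   drawn from a log-location-scale family, discretised by a realistic check
   schedule (:func:`apply_check_schedule`) — daily checks in the first week,
   then weekly out to the 56-day trial end — with right-censoring at the
   final check, or camera-exact removal times.

2. **Paired-group meta-datasets** (:func:`simulate_meta_dataset`): analysis
   groups each holding a game bird cell and a raptor cell whose average
   probabilities of persistence obey a known logit-linear scaling law

       logit r_raptor(t) = (b0 + u0_g) + (b1 + u1_g) * r_gamebird(t)
                           + covariate offsets + noise,

   with correlated group-level random intercepts/slopes (u0, u1) — the
   ground truth the two-stage pipeline must recover.  Raptor survival
   parameters are obtained by solving for the Weibull (mu, sigma) whose
   logit r-hat at the search intervals best matches that law.

Every stochastic operation takes an explicit integer seed and uses one
named ``numpy`` generator; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from . import families as fam
from .survival import avg_persistence_batch
from .trials import TrialRecord, HABITATS, REGIONS, SEASONS

#: modal in-person protocol: daily checks on days 1-4, then 7, 10, 14, and
#: weekly to the 56-day trial end
DEFAULT_SCHEDULE = (1, 2, 3, 4, 7, 10, 14, 21, 28, 35, 42, 49, 56)
DEFAULT_TRIAL_LENGTH = 56.0

__all__ = [
    "CellSpec",
    "ScalingTruth",
    "MetaSimConfig",
    "simulate_removal_times",
    "apply_check_schedule",
    "simulate_meta_dataset",
    "simulate_scaling_pairs",
    "DEFAULT_SCHEDULE",
]


@dataclass
class CellSpec:
    """One homogeneous simulated stratum: family, location mu (log-days),
    scale sigma, covariate labels, and carcass count."""

    family: str
    location: float
    scale: float
    labels: dict
    n: int

    def __post_init__(self):
        if self.family not in fam.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "exponential" and self.scale != 1.0:
            raise ValueError("exponential cells have scale fixed at 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.n < 1:
            raise ValueError("cell must contain at least one carcass")


@dataclass
class ScalingTruth:
    """Parameters of the generating logit-linear scaling law."""

    intercept: float = -0.7
    slope: float = 4.0
    fixed_offsets: dict = field(default_factory=dict)  # e.g. {"region[R6]": 1.2}
    re_sd_intercept: float = 0.5
    re_sd_slope: float = 2.0
    re_correlation: float = 0.0
    resid_sd: float = 0.3


@dataclass
class MetaSimConfig:
    """Configuration for a paired-group meta-dataset simulation."""

    cells: list = field(default_factory=list)  # gamebird CellSpecs, one per group
    schedule: tuple = DEFAULT_SCHEDULE
    trial_length: float = DEFAULT_TRIAL_LENGTH
    camera_fraction: float = 0.0
    scaling_truth: ScalingTruth = field(default_factory=ScalingTruth)
    intervals: tuple = (14, 30, 60, 90)
    seed: int = 0

    def __post_init__(self):
        sched = tuple(float(s) for s in self.schedule)
        if not sched:
            raise ValueError("check schedule must be nonempty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("check schedule must be strictly increasing")
        if sched[-1] > self.trial_length:
            raise ValueError("last check must not exceed trial_length")
        if not 0.0 <= self.camera_fraction <= 1.0:
            raise ValueError("camera_fraction must be a proportion")
        self.schedule = sched


def simulate_removal_times(cell: CellSpec, seed: int) -> np.ndarray:
    """Draw ``cell.n`` removal times from the cell's generating law."""
    rng = np.random.default_rng(seed)
    return fam.sample_removal_times(cell.family, cell.location, cell.scale, cell.n, rng)


def apply_check_schedule(
    times,
    schedule=DEFAULT_SCHEDULE,
    trial_length: float = DEFAULT_TRIAL_LENGTH,
    mode: str = "in_person",
    labels: dict | None = None,
    id_prefix: str = "c",
    study_id: str = "sim",
    site_id: str = "site",
    state: str = "XX",
) -> list[TrialRecord]:
    """Discretise exact removal times by a check schedule into trial records.

    A removal at t maps to last_present = greatest check (or placement, day
    0) strictly before t, and first_absent = least check >= t.  Removals
    after the final check are right-censored there.  ``mode="camera"``
    records t exactly (in both fields).
    """
    schedule = tuple(float(s) for s in schedule)
    if not schedule:
        raise ValueError("check schedule must be nonempty")
    checks = np.array(schedule)
    labels = labels or {}
    base = dict(
        study_id=study_id,
        site_id=site_id,
        state=state,
        region=labels.get("region", "R1"),
        habitat=labels.get("habitat", "grassland"),
        season=labels.get("season", "fall"),
        bird_type=labels.get("bird_type", "gamebird"),
        placement_time=0.0,
        trial_length=float(trial_length),
    )
    records = []
    for i, t in enumerate(np.asarray(times, dtype=float)):
        cid = f"{id_prefix}{i:04d}"
        if t > checks[-1]:
            rec = TrialRecord(carcass_id=cid, last_present=checks[-1],
                              first_absent=None, monitor_mode=mode, **base)
        elif mode == "camera":
            rec = TrialRecord(carcass_id=cid, last_present=t, first_absent=t,
                              monitor_mode="camera", **base)
        else:
            j = int(np.searchsorted(checks, t, side="left"))
            last = 0.0 if j == 0 else checks[j - 1]
            rec = TrialRecord(carcass_id=cid, last_present=last,
                              first_absent=checks[j], monitor_mode="in_person",
                              **base)
        records.append(rec.validate())
    return records


def _weibull_matching_targets(target_logit_r, intervals):
    """Weibull (mu, log sigma) whose logit r-hat at ``intervals`` is closest
    (least squares) to the target linear predictors."""

    def resid(p):
        vals = np.array([
            avg_persistence_batch("weibull", p[0], np.exp(p[1]), t)[0]
            for t in intervals
        ])
        vals = np.clip(vals, 1e-9, 1 - 1e-9)
        return logit(vals) - target_logit_r

    sol = optimize.least_squares(resid, x0=np.array([np.log(60.0), 0.0]),
                                 bounds=([np.log(0.5), -2.5], [np.log(5000.0), 1.5]))
    return sol.x[0], float(np.exp(sol.x[1]))


def simulate_meta_dataset(config: MetaSimConfig):
    """Simulate a paired raptor/game-bird meta-dataset with known truth.

    Each game bird :class:`CellSpec` in ``config.cells`` defines one
    analysis group (its ``labels`` must carry region/habitat/season and a
    ``group`` name; ``bird_type`` is overridden).  Per group the raptor cell
    is constructed so the (gamebird r-hat, raptor r-hat) curve follows the
    scaling truth with that group's random effects.

    Returns ``(records, truth)`` where truth is a dict holding every cell
    spec, the scaling law, the per-group random effects and the per-group
    target/achieved persistence probabilities.
    """
    rng = np.random.default_rng(config.seed)
    st = config.scaling_truth
    cov = np.array([
        [st.re_sd_intercept ** 2,
         st.re_correlation * st.re_sd_intercept * st.re_sd_slope],
        [st.re_correlation * st.re_sd_intercept * st.re_sd_slope,
         st.re_sd_slope ** 2],
    ])
    intervals = np.asarray(config.intervals, dtype=float)
    records: list[TrialRecord] = []
    truth = {
        "scaling_truth": asdict(st),
        "intervals": list(map(float, intervals)),
        "groups": {},
        "cells": [],
    }
    for gi, gb_cell in enumerate(config.cells):
        labels = dict(gb_cell.labels)
        group = labels.get("group", f"G{gi:02d}")
        re_int, re_slope = rng.multivariate_normal(np.zeros(2), cov)
        # true gamebird r-hat at each interval
        r_gb = np.array([
            avg_persistence_batch(gb_cell.family, gb_cell.location, gb_cell.scale, t)[0]
            for t in intervals
        ])
        offset = sum(
            st.fixed_offsets.get(f"{k}[{v}]", 0.0) for k, v in labels.items()
        )
        eta = (st.intercept + re_int) + (st.slope + re_slope) * r_gb + offset
        eta = eta + rng.normal(0.0, st.resid_sd, size=len(intervals))
        mu_r, sigma_r = _weibull_matching_targets(eta, intervals)
        rap_cell = CellSpec("weibull", mu_r, sigma_r,
                            {**labels, "bird_type": "raptor"}, gb_cell.n)
        for cell, bird in ((gb_cell, "gamebird"), (rap_cell, "raptor")):
            times = fam.sample_removal_times(cell.family, cell.location,
                                             cell.scale, cell.n, rng)
            camera = rng.random() < config.camera_fraction
            recs = apply_check_schedule(
                times, config.schedule, config.trial_length,
                mode="camera" if camera else "in_person",
                labels={**labels, "bird_type": bird},
                id_prefix=f"{group}_{bird}_", study_id=group,
                site_id=f"site_{group}", state=labels.get("state", "XX"),
            )
            records.extend(recs)
            truth["cells"].append({**asdict(cell), "group": group, "bird_type": bird})
        truth["groups"][group] = {
            "re_intercept": float(re_int),
            "re_slope": float(re_slope),
            "labels": labels,
            "gamebird_r": r_gb.tolist(),
            "target_logit_raptor_r": eta.tolist(),
            "raptor_mu": float(mu_r),
            "raptor_sigma": float(sigma_r),
        }
    return records, truth


def default_group_cells(
    n_groups: int = 30,
    n_per_cell: int = 40,
    seed: int = 0,
    median_range=(2.0, 35.0),
) -> list[CellSpec]:
    """Game bird cells for ``simulate_meta_dataset``: one group per cell,
    Weibull removal laws with median persistence spread log-uniformly over
    ``median_range`` days (game bird medians in multi-study persistence data
    run from about 2 to 48 days), sigma near 0.9, and labels cycling through
    regions/habitats/seasons."""
    rng = np.random.default_rng(seed)
    regions = ("R1", "R2", "R6")
    habitats = ("cropland", "grassland", "shrub_scrub")
    cells = []
    for g in range(n_groups):
        med = np.exp(rng.uniform(np.log(median_range[0]), np.log(median_range[1])))
        sigma = rng.uniform(0.7, 1.1)
        mu = np.log(med) - sigma * np.log(np.log(2.0))
        labels = {
            "group": f"G{g:02d}",
            "region": regions[g % len(regions)],
            "habitat": habitats[(g // len(regions)) % len(habitats)],
            "season": "fall",
            "state": f"S{g:02d}",
        }
        cells.append(CellSpec("weibull", float(mu), float(sigma), labels, n_per_cell))
    return cells


def simulate_scaling_pairs(
    truth: ScalingTruth,
    n_groups: int = 30,
    B: int = 200,
    intervals=(14, 30, 60, 90),
    group_labels: list[dict] | None = None,
    gamebird_spread: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a Stage-2 regression dataset from the scaling law
    (no survival layer) — the unit-test oracle for ``fit_scaling``.

    Group point gamebird r-hat values are spread over (0.1, 0.8); bootstrap
    replicates jitter them with sd ``gamebird_spread``.  The response is
    logit-linear in gamebird r-hat with the truth's random effects and
    residual noise.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([
        [truth.re_sd_intercept ** 2,
         truth.re_correlation * truth.re_sd_intercept * truth.re_sd_slope],
        [truth.re_correlation * truth.re_sd_intercept * truth.re_sd_slope,
         truth.re_sd_slope ** 2],
    ])
    rows = []
    for g in range(n_groups):
        labels = (group_labels[g] if group_labels else
                  {"region": "R1", "habitat": "cropland", "season": "fall"})
        u0, u1 = rng.multivariate_normal(np.zeros(2), cov)
        base = rng.uniform(0.1, 0.8)
        offset = sum(truth.fixed_offsets.get(f"{k}[{v}]", 0.0)
                     for k, v in labels.items())
        for t in intervals:
            # longer search intervals see smaller persistence
            center = np.clip(base * (30.0 / t) ** 0.25, 0.02, 0.95)
            x = np.clip(center + rng.normal(0.0, gamebird_spread, size=B),
                        1e-4, 1 - 1e-4)
            eta = (truth.intercept + u0) + (truth.slope + u1) * x + offset
            y = expit(eta + rng.normal(0.0, truth.resid_sd, size=B))
            for b in range(B):
                rows.append({
                    "group_id": f"G{g:02d}", "season": labels["season"],
                    "region": labels["region"], "habitat": labels["habitat"],
                    "interval": t, "replicate": b + 1,
                    "gamebird_r": x[b], "raptor_r": y[b],
                })
    return pd.DataFrame(rows)
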