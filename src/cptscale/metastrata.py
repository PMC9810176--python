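"""Covariate-grid model selection and strata-restricted persistence tables.

For multi-study persistence data the candidate set crosses the four
survival families with every admissible combination of categorical
covariates (season, habitat, region) on the location and/or scale
parameter.  Two-way interactions are admitted only when both main effects
appear in the same term list; the exponential family carries no scale
terms.  Candidates are ranked by AICc and the most parsimonious model
within 2 points of the best is selected; estimates are reported only for
strata actually sampled in the data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import families as fam
from .survival import (
    FitError,
    IntervalCensoredSurvReg,
    ModelSpec,
    select_model,
)
from .trials import ObservationSet

log = logging.getLogger(__name__)

COVARIATE_POOL = ("season", "habitat", "region")

__all__ = ["candidate_grid", "fit_meta", "CandidateGrid"]


@dataclass
class CandidateGrid:
    specs: list
    covariates: tuple

    def __len__(self):
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)


def _term_sets(covariates, allow_interactions: bool):
    """All admissible term lists over ``covariates``: every subset of the
    main effects, optionally extended by any subset of two-way interactions
    among the included mains.  Deterministic ordering."""
    covariates = tuple(covariates)
    out = []
    for r in range(len(covariates) + 1):
        for mains in itertools.combinations(covariates, r):
            pairs = list(itertools.combinations(mains, 2)) if allow_interactions else []
            for pr in range(len(pairs) + 1):
                for inter in itertools.combinations(pairs, pr):
                    out.append(tuple(mains) + tuple(inter))
    return out


def candidate_grid(
    covariates=COVARIATE_POOL,
    families=fam.FAMILIES,
    allow_interactions: bool = True,
) -> CandidateGrid:
    """Enumerate every admissible (family, location terms, scale terms).

    Interactions are limited to two-way and require their main effects in
    the same term list; exponential specs have no scale terms.
    """
    covariates = tuple(covariates)
    unknown = set(covariates) - set(COVARIATE_POOL)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}; pool is {COVARIATE_POOL}")
    term_sets = _term_sets(covariates, allow_interactions)
    specs = []
    for family in families:
        scale_sets = [()] if family == "exponential" else term_sets
        for loc in term_sets:
            for sc in scale_sets:
                specs.append(ModelSpec(family, loc, sc))
    return CandidateGrid(specs, covariates)


def fit_meta(
    obs: ObservationSet,
    bird_type: str,
    grid: CandidateGrid | None = None,
    intervals=(30, 60, 90),
    n_boot: int = 1000,
    seed: int = 0,
    n_starts: int = 5,
):
    """Fit the candidate grid to one bird type and tabulate estimates for
    sampled strata.

    Specs that fail to fit (degenerate design, non-convergence) are dropped
    from selection with a logged warning.  Returns ``(selected_fit,
    strata_estimates)`` where the estimates DataFrame has one row per
    sampled (region, habitat, season) stratum and search interval, with
    median persistence time, r-hat, and percentile-bootstrap 90% CIs.
    """
    if grid is None:
        grid = candidate_grid()
    mask = (obs.covariates["bird_type"] == bird_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no observations for bird_type {bird_type!r}")
    sub = obs.subset(mask)
    fits = []
    for spec in grid:
        try:
            fits.append(IntervalCensoredSurvReg(sub, spec).fit(n_starts=n_starts, seed=seed))
        except (FitError, ValueError) as exc:
            log.warning("candidate %s dropped: %s", spec.label(), exc)
    if not fits:
        raise FitError("every candidate model failed to fit")
    best = select_model(fits)
    strata_cols = [c for c in grid.covariates if c in sub.covariates.columns]
    if strata_cols:
        strata = sub.covariates[strata_cols].drop_duplicates().sort_values(strata_cols)
        counts = sub.covariates.groupby(strata_cols).size()
        cells = [dict(zip(strata_cols, row)) for row in strata.itertuples(index=False)]
    else:
        counts = None
        cells = [{}]
    est = best.persistence_estimates(cells, intervals=intervals, n_boot=n_boot, seed=seed)
    if strata_cols:
        est["n_carcasses"] = [
            int(counts.loc[tuple(r[c] for c in strata_cols)] if len(strata_cols) > 1
                else counts.loc[r[strata_cols[0]]])
            for _, r in est.iterrows()
        ]
    else:
        est["n_carcasses"] = sub.n
    est["bird_type"] = bird_type
    return best, est
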