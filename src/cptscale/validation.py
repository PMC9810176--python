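"""Stratified cross-validation of the persistence scaling model.

Analysis groups are split into training and out-of-sample (OOS) sets,
stratified by the Region x habitat cell: any cell with a single group keeps
that group in training (so the selected mixed model can be refit), every
other cell contributes at least one training group, and the total training
fraction is pushed as close to the target (52%) as those constraints allow.
Per split the selected Stage-2 model form is refit on the training pairs,
each hold-out group's raptor r-hat is predicted from its game bird r-hat
point estimate (fixed effects only — hold-out groups are new to the model),
and four out-of-sample metrics are computed against the hold-out groups'
own Stage-1 raptor point estimates: RMSE, Pearson correlation, the
proportion of predictions exceeding the OOS estimate, and mean absolute
error.
"""

from __future__ import annotations

import logging
from collections import namedtuple

import numpy as np
import pandas as pd

from .scaling import PersistenceScaling, ScalingData
from .survival import FitError

log = logging.getLogger(__name__)

OOSMetrics = namedtuple("OOSMetrics", ["rmse", "pearson", "prop_over", "mae"])

__all__ = ["stratified_splits", "oos_metrics", "cross_validate", "OOSMetrics"]


def _group_cells(groups) -> pd.DataFrame:
    """(group_id, region, habitat) table from AnalysisGroups or a frame."""
    if isinstance(groups, pd.DataFrame):
        return groups[["group_id", "region", "habitat"]].drop_duplicates()
    return pd.DataFrame(
        [{"group_id": g.group_id, "region": g.region, "habitat": g.habitat}
         for g in groups]
    )


def stratified_splits(groups, n_sets: int = 10, train_target: float = 0.52,
                      seed: int = 0) -> list[tuple[list, list]]:
    """Random stratified training / hold-out splits of the analysis groups.

    Per split: every singleton Region x habitat cell's group goes to
    training; every multi-group cell contributes at least one random
    training group; further groups are added at random until the training
    fraction is as close to ``train_target`` as the constraints allow.
    Each split draws from an independent child seed, so adding splits never
    perturbs earlier ones.  Raises if every cell is a singleton (nothing
    could ever be held out).
    """
    cells = _group_cells(groups)
    if len(cells) < 2:
        raise ValueError("cross-validation requires at least 2 analysis groups")
    by_cell = {
        key: sorted(sub["group_id"])
        for key, sub in cells.groupby(["region", "habitat"])
    }
    if all(len(v) == 1 for v in by_cell.values()):
        raise ValueError(
            "every Region x habitat cell holds a single analysis group; "
            "no group can be held out"
        )
    n_total = len(cells)
    target = int(round(train_target * n_total))
    splits = []
    for s in range(n_sets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, s]))
        train = set()
        for key in sorted(by_cell):
            members = by_cell[key]
            if len(members) == 1:
                train.add(members[0])
            else:
                train.add(members[rng.integers(len(members))])
        pool = sorted(set(cells["group_id"]) - train)
        # cells must keep >= 1 hold-out overall, not per cell; top up to target
        n_extra = max(0, min(target - len(train), len(pool) - 1))
        if n_extra:
            extra = rng.choice(pool, size=n_extra, replace=False)
            train.update(extra.tolist())
        holdout = sorted(set(cells["group_id"]) - train)
        splits.append((sorted(train), holdout))
    return splits


def oos_metrics(predicted, actual) -> OOSMetrics:
    """Four out-of-sample prediction metrics.

    rmse = sqrt(mean((p-a)^2)); mae = mean |p-a|; prop_over = mean(p > a);
    pearson = sample correlation (NaN when ``actual`` is constant).
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 2:
        raise ValueError("predicted and actual must be equal-length with >= 2 values")
    err = p - a
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    prop_over = float(np.mean(p > a))
    if np.ptp(a) == 0.0 or np.ptp(p) == 0.0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(p, a)[0, 1])
    return OOSMetrics(rmse, pearson, prop_over, mae)


def cross_validate(
    data: ScalingData | pd.DataFrame,
    groups,
    candidate_fixed=None,
    n_sets: int = 10,
    train_target: float = 0.52,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified cross-validation report for the scaling model.

    The model form is selected once on the full Stage-1 pairs; per split it
    is refit (that form only) on the training groups' pairs and evaluated on
    the hold-out groups' point estimates.  A split whose training fit fails
    is recorded as failed and the run continues.  Returns one row per split
    with the four metrics (NaN for failed splits) plus split metadata.
    """
    if isinstance(data, ScalingData):
        draws, points = data.draws, data.points
    else:
        draws = data
        points = (
            draws.groupby(["group_id", "season", "region", "habitat", "interval"],
                          as_index=False)[["gamebird_r", "raptor_r"]].median()
        )
        log.info("no point estimates supplied; using per-cell medians of the draws")
    selected = PersistenceScaling(draws).fit(candidate_fixed=candidate_fixed)
    form = [selected.covariates]
    splits = stratified_splits(groups, n_sets=n_sets, train_target=train_target,
                               seed=seed)
    rows = []
    for i, (train, holdout) in enumerate(splits):
        row = {"split": i + 1, "n_train": len(train), "n_holdout": len(holdout),
               "failed": False}
        try:
            fit = PersistenceScaling(
                draws[draws["group_id"].isin(train)]
            ).fit(candidate_fixed=form)
            oos = points[points["group_id"].isin(holdout)]
            pred = [
                fit.predict(r.gamebird_r, season=r.season, region=r.region,
                            habitat=r.habitat, group_id=None)
                for r in oos.itertuples(index=False)
            ]
            m = oos_metrics(pred, oos["raptor_r"].to_numpy())
            row.update(m._asdict())
        except (FitError, ValueError) as exc:
            log.warning("split %d failed: %s", i + 1, exc)
            row.update({"failed": True, "rmse": np.nan, "pearson": np.nan,
                        "prop_over": np.nan, "mae": np.nan})
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["n_splits"] = n_sets
    report.attrs["seed"] = seed
    report.attrs["n_failed"] = int(report["failed"].sum())
    return report
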