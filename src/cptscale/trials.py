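"""Carcass persistence trial records and their interval-censored representation.

A carcass persistence trial (CPT) places a fresh carcass on the landscape at
time 0 and monitors it — in-person on a check schedule, or continuously by
game camera — until it is removed by scavengers or the trial ends (typically
56 days).  The removal time is therefore known only to an interval:

* in-person check: last check at which the carcass was present (``last_present``)
  and first check at which it was absent (``first_absent``) bracket the removal;
* camera: the removal time is effectively exact (both fields hold it);
* right-censored: the carcass survived the whole trial; ``first_absent`` is open.

``make_intervals`` turns validated records into the ``[L, R)`` interval table
(an :class:`ObservationSet`) consumed by the survival regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = tuple(f"R{i}" for i in range(1, 9))
HABITATS = ("cropland", "grassland", "forest", "shrub_scrub")
SEASONS = ("spring", "summer", "fall", "winter")
BIRD_TYPES = ("raptor", "gamebird")
MONITOR_MODES = ("in_person", "camera")

#: columns a trial CSV must provide (``species`` is optional)
REQUIRED_COLUMNS = (
    "carcass_id",
    "study_id",
    "site_id",
    "state",
    "region",
    "habitat",
    "season",
    "bird_type",
    "placement_time",
    "last_present",
    "first_absent",
    "monitor_mode",
    "trial_length",
)

COVARIATE_COLUMNS = ("region", "habitat", "season", "bird_type")


class SchemaError(ValueError):
    """The trial file is missing a required column or uses an unknown label."""


class TrialDataError(ValueError):
    """A row violates the trial-record invariants."""


@dataclass
class TrialRecord:
    """One carcass in a persistence trial.

    Times are days since placement (placement is day 0).  A right-censored
    carcass has ``first_absent = None``.  For camera-monitored carcasses the
    removal time is known to camera precision and is stored in both
    ``last_present`` and ``first_absent``.
    """

    carcass_id: str
    study_id: str
    site_id: str
    state: str
    region: str
    habitat: str
    season: str
    bird_type: str
    placement_time: float
    last_present: float
    first_absent: float | None
    monitor_mode: str
    trial_length: float
    species: str | None = None

    @property
    def right_censored(self) -> bool:
        return self.first_absent is None

    def validate(self) -> "TrialRecord":
        cid = self.carcass_id
        for name, value, vocab in (
            ("region", self.region, REGIONS),
            ("habitat", self.habitat, HABITATS),
            ("season", self.season, SEASONS),
            ("bird_type", self.bird_type, BIRD_TYPES),
            ("monitor_mode", self.monitor_mode, MONITOR_MODES),
        ):
            if value not in vocab:
                raise SchemaError(
                    f"carcass {cid!r}: unknown {name} label {value!r}; expected one of {vocab}"
                )
        if self.last_present < 0:
            raise TrialDataError(f"carcass {cid!r}: last_present must be >= 0")
        if self.trial_length <= 0:
            raise TrialDataError(f"carcass {cid!r}: trial_length must be positive")
        if self.right_censored:
            if self.last_present > self.trial_length:
                raise TrialDataError(
                    f"carcass {cid!r}: right-censored beyond trial_length"
                )
        else:
            # camera removals carry an exact time: both fields equal
            lo_ok = (
                self.first_absent >= self.last_present
                if self.monitor_mode == "camera"
                else self.first_absent > self.last_present
            )
            if not lo_ok:
                raise TrialDataError(
                    f"carcass {cid!r}: first_absent ({self.first_absent}) must exceed "
                    f"last_present ({self.last_present})"
                )
        return self


@dataclass
class ObservationSet:
    """Interval-censored observations ``[left, right)`` with covariate labels.

    ``right`` is ``+inf`` for right-censored carcasses.  ``weights`` counts
    identical rows (the likelihood aggregates duplicates for speed);
    construction from records always uses weight 1 per carcass.
    """

    left: np.ndarray
    right: np.ndarray
    covariates: pd.DataFrame
    weights: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.left < 0) or np.any(self.right <= self.left):
            raise TrialDataError("intervals must satisfy 0 <= left < right")

    @property
    def n(self) -> int:
        return int(round(self.weights.sum()))

    def __len__(self) -> int:
        return len(self.left)

    def subset(self, mask) -> "ObservationSet":
        mask = np.asarray(mask)
        return ObservationSet(
            self.left[mask],
            self.right[mask],
            self.covariates.loc[mask].reset_index(drop=True),
            self.weights[mask],
        )


def _parse_time(value, column: str, carcass_id: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.lower() in {"na", "nan", "none", "inf"}:
            return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise TrialDataError(
            f"carcass {carcass_id!r}: cannot parse {column} value {value!r} as days"
        ) from None
    if math.isnan(out):
        return None
    return out


def read_trials(path, schema_version: str = "1") -> list[TrialRecord]:
    """Read and validate a trial CSV into a list of :class:`TrialRecord`.

    The header must contain every column in :data:`REQUIRED_COLUMNS`
    (``species`` is optional).  A blank / NA ``first_absent`` marks right
    censoring.  Row count is preserved; any invalid row raises with its
    carcass id.
    """
    if schema_version != "1":
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trial file {path} is missing required column {col!r}")
    records = []
    for row in df.to_dict("records"):
        cid = row["carcass_id"]
        rec = TrialRecord(
            carcass_id=cid,
            study_id=row["study_id"],
            site_id=row["site_id"],
            state=row["state"],
            region=row["region"],
            habitat=row["habitat"],
            season=row["season"],
            bird_type=row["bird_type"],
            placement_time=_parse_time(row["placement_time"], "placement_time", cid) or 0.0,
            last_present=_parse_time(row["last_present"], "last_present", cid),
            first_absent=_parse_time(row["first_absent"], "first_absent", cid),
            monitor_mode=row["monitor_mode"],
            trial_length=_parse_time(row["trial_length"], "trial_length", cid),
            species=row.get("species") or None,
        )
        if rec.last_present is None:
            raise TrialDataError(f"carcass {cid!r}: last_present is required")
        if rec.trial_length is None:
            raise TrialDataError(f"carcass {cid!r}: trial_length is required")
        records.append(rec.validate())
    return records


def write_trials(records: Iterable[TrialRecord], path) -> None:
    """Write records to CSV; ``read_trials`` round-trips all fields."""
    rows = []
    for rec in records:
        d = asdict(rec)
        d["first_absent"] = "" if rec.first_absent is None else repr(rec.first_absent)
        d["last_present"] = repr(rec.last_present)
        d["placement_time"] = repr(rec.placement_time)
        d["trial_length"] = repr(rec.trial_length)
        d["species"] = rec.species or ""
        rows.append(d)
    cols = list(REQUIRED_COLUMNS) + ["species"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def season_from_date(month: int, day: int) -> str:
    """Season label from a calendar date, following the field-trial windows:
    spring Mar 15 – Jun 14, summer Jun 15 – Sep 14, fall Sep 15 – Nov 14,
    winter Nov 15 – Mar 14."""
    md = (month, day)
    if (3, 15) <= md < (6, 15):
        return "spring"
    if (6, 15) <= md < (9, 15):
        return "summer"
    if (9, 15) <= md < (11, 15):
        return "fall"
    return "winter"


def make_intervals(
    records: Sequence[TrialRecord], camera_delta: float = 0.04
) -> ObservationSet:
    """Build the interval-censored representation of a record collection.

    * in-person, removed:   ``[last_present, first_absent)``
    * right-censored:       ``[last_present, +inf)``
    * camera, removed at t: ``[max(0, t - camera_delta), t)`` — the exact
      removal time becomes a narrow interval of width ``camera_delta``
      (default 0.04 d, about one hour) so one likelihood serves both
      monitoring modes.

    Covariate labels (region, habitat, season, bird_type) are copied through;
    one output row per input record.
    """
    if camera_delta <= 0:
        raise ValueError("camera_delta must be positive")
    left, right, cov = [], [], []
    for rec in records:
        rec.validate()
        if rec.right_censored:
            left.append(rec.last_present)
            right.append(np.inf)
        elif rec.monitor_mode == "camera":
            t = rec.first_absent
            if t <= 0:
                raise TrialDataError(
                    f"carcass {rec.carcass_id!r}: camera removal time must be positive"
                )
            left.append(max(0.0, t - camera_delta))
            right.append(t)
        else:
            if rec.first_absent <= rec.last_present:
                raise TrialDataError(
                    f"carcass {rec.carcass_id!r}: first_absent must exceed last_present"
                )
            left.append(rec.last_present)
            right.append(rec.first_absent)
        cov.append({c: getattr(rec, c) for c in COVARIATE_COLUMNS})
    return ObservationSet(
        np.array(left), np.array(right), pd.DataFrame(cov), np.ones(len(left))
    )


def intervals_from_frame(df: pd.DataFrame, camera_delta: float = 0.04) -> ObservationSet:
    """``make_intervals`` on a trial DataFrame (columns as in the CSV schema)."""
    records = [
        TrialRecord(
            carcass_id=str(r.carcass_id),
            study_id=str(r.study_id),
            site_id=str(r.site_id),
            state=str(r.state),
            region=r.region,
            habitat=r.habitat,
            season=r.season,
            bird_type=r.bird_type,
            placement_time=float(getattr(r, "placement_time", 0.0) or 0.0),
            last_present=float(r.last_present),
            first_absent=None if pd.isna(r.first_absent) else float(r.first_absent),
            monitor_mode=r.monitor_mode,
            trial_length=float(r.trial_length),
        )
        for r in df.itertuples(index=False)
    ]
    return make_intervals(records, camera_delta=camera_delta)
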