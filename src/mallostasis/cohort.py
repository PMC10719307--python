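"""Longitudinal biomarker cohorts with survival outcomes.

A cohort is a long-format table (one row per individual-visit) of biomarker
values and covariates, together with a per-individual event record (age at
death/event, or censoring age). Missing biomarker values are represented as
NaN. Within each individual, visit ages are strictly increasing and no visit
may fall after the event age unless explicitly flagged post-event (such rows
occur only when a fitted model synthesizes visits for dead individuals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ID_COL = "id"
AGE_COL = "age"
POST_EVENT_COL = "post_event"

__all__ = [
    "LongitudinalCohort",
    "TransitionPair",
    "CohortAudit",
    "ScalingRecord",
    "read_cohort",
    "write_cohort",
    "make_transition_pairs",
    "standardize",
]


@dataclass
class TransitionPair:
    """One (visit n, visit n+1) transition of a single individual."""

    individual_id: object
    y_from: np.ndarray
    y_to: np.ndarray
    x_from: np.ndarray  # covariates at the starting visit, without constant/age
    t_from: float
    dt: float

    def __post_init__(self) -> None:
        if self.dt == 0:
            raise ValueError("transition pair with dt == 0")


@dataclass
class CohortAudit:
    n_rows_read: int = 0
    n_post_event_dropped: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


@dataclass
class LongitudinalCohort:
    """Long-format visit table plus per-individual event data.

    ``data`` holds columns ``id``, ``age``, the biomarkers and the covariates
    (and optionally a boolean ``post_event`` flag). ``events`` is indexed by
    individual id with columns ``event_age`` and ``event_status``
    (1 = event observed, 0 = censored).
    """

    data: pd.DataFrame
    biomarker_names: list[str]
    covariate_names: list[str]
    events: pd.DataFrame | None = None
    time_unit: str = "years"

    def __post_init__(self) -> None:
        self.data = self.data.sort_values([ID_COL, AGE_COL], kind="stable").reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        cols = [ID_COL, AGE_COL] + self.biomarker_names + self.covariate_names
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if not np.isfinite(self.data[AGE_COL].to_numpy(float)).all():
            raise ValueError("non-finite visit age")
        if self.data.duplicated([ID_COL, AGE_COL]).any():
            dup = self.data[self.data.duplicated([ID_COL, AGE_COL])][ID_COL].iloc[0]
            raise ValueError(f"duplicate (id, age) rows for individual {dup!r}")
        ages = self.data.groupby(ID_COL, sort=False)[AGE_COL].diff().dropna()
        if (ages <= 0).any():
            raise ValueError("visit ages not strictly increasing within an individual")
        if self.events is not None:
            post = (
                self.data[POST_EVENT_COL].to_numpy(bool)
                if POST_EVENT_COL in self.data.columns
                else np.zeros(len(self.data), dtype=bool)
            )
            ev = self.events.reindex(self.data[ID_COL])
            late = (self.data[AGE_COL].to_numpy() > ev["event_age"].to_numpy(float)) & ~post
            late &= ev["event_status"].to_numpy(float) == 1
            if late.any():
                bad = self.data.loc[late, ID_COL].iloc[0]
                raise ValueError(
                    f"individual {bad!r} has a visit after its event age; "
                    "drop it (read_cohort does) or flag it post_event"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.data[ID_COL].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.data)

    @property
    def m(self) -> int:
        return len(self.biomarker_names)

    def biomarker_matrix(self) -> np.ndarray:
        return self.data[self.biomarker_names].to_numpy(float)

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariate_names:
            return np.empty((len(self.data), 0))
        return self.data[self.covariate_names].to_numpy(float)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_visits, m) mask of missing biomarker entries."""
        return self.data[self.biomarker_names].isna().to_numpy()

    def copy(self) -> "LongitudinalCohort":
        return LongitudinalCohort(
            data=self.data.copy(),
            biomarker_names=list(self.biomarker_names),
            covariate_names=list(self.covariate_names),
            events=None if self.events is None else self.events.copy(),
            time_unit=self.time_unit,
        )

    def with_biomarkers(self, values: np.ndarray, names: list[str] | None = None) -> "LongitudinalCohort":
        """Return a copy whose biomarker block is replaced by ``values``."""
        names = list(self.biomarker_names) if names is None else list(names)
        df = self.data.drop(columns=self.biomarker_names).copy()
        for j, name in enumerate(names):
            df[name] = values[:, j]
        return LongitudinalCohort(df, names, list(self.covariate_names),
                                  None if self.events is None else self.events.copy(),
                                  self.time_unit)

    def baseline(self) -> pd.DataFrame:
        """First visit per individual."""
        return self.data.groupby(ID_COL, sort=False).head(1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _load_schema(schema: dict | str | Path) -> dict:
    if isinstance(schema, (str, Path)):
        schema = yaml.safe_load(Path(schema).read_text())
    required = {"id", "age", "biomarkers"}
    missing = required - schema.keys()
    if missing:
        raise ValueError(f"schema missing keys: {sorted(missing)}")
    return schema


def read_cohort(path: str | Path, schema: dict | str | Path) -> tuple[LongitudinalCohort, CohortAudit]:
    """Read a long-format delimited table into a cohort.

    ``schema`` maps roles to column names: keys ``id``, ``age``,
    ``biomarkers`` (list), optional ``covariates`` (list), ``event_age``,
    ``event_status``, ``missing_tokens``, ``sep``, ``time_unit``.

    Visits dated after an individual's observed event are dropped and counted
    in the returned audit record (they are treated as coding errors, not
    imputed).
    """
    schema = _load_schema(schema)
    tokens = list(schema.get("missing_tokens", _DEFAULT_MISSING_TOKENS))
    raw = pd.read_csv(path, sep=schema.get("sep", ","), dtype=str, keep_default_na=False)

    out = pd.DataFrame()
    out[ID_COL] = raw[schema["id"]]
    out[AGE_COL] = pd.to_numeric(raw[schema["age"]])
    numeric_cols = list(schema["biomarkers"]) + list(schema.get("covariates", []))
    for col in numeric_cols:
        vals = raw[col].replace(dict.fromkeys(tokens, np.nan))
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col!r}: {exc}") from None

    audit = CohortAudit(n_rows_read=len(raw))

    events = None
    if "event_age" in schema:
        ev = pd.DataFrame(
            {
                "event_age": pd.to_numeric(raw[schema["event_age"]]).to_numpy(),
                "event_status": pd.to_numeric(raw[schema["event_status"]]).to_numpy(),
            },
            index=pd.Index(raw[schema["id"]].to_numpy(), name=ID_COL),
        )
        events = ev[~ev.index.duplicated()]
        events.index.name = ID_COL
        # drop post-event visits (observed events only)
        ev_rows = events.reindex(out[ID_COL])
        late = (out[AGE_COL].to_numpy() > ev_rows["event_age"].to_numpy(float)) & (
            ev_rows["event_status"].to_numpy(float) == 1
        )
        audit.n_post_event_dropped = int(late.sum())
        out = out[~late].reset_index(drop=True)

    cohort = LongitudinalCohort(
        data=out,
        biomarker_names=list(schema["biomarkers"]),
        covariate_names=list(schema.get("covariates", [])),
        events=events,
        time_unit=schema.get("time_unit", "years"),
    )
    return cohort, audit


def write_cohort(cohort: LongitudinalCohort, path: str | Path) -> None:
    """Write the visit table (and events, merged per-row) as CSV."""
    df = cohort.data.copy()
    if cohort.events is not None:
        df = df.merge(cohort.events, left_on=ID_COL, right_index=True, how="left")
    df.to_csv(path, index=False)


def default_schema(cohort: LongitudinalCohort) -> dict:
    """Schema dict that reads back a file written by :func:`write_cohort`."""
    schema = {
        "id": ID_COL,
        "age": AGE_COL,
        "biomarkers": list(cohort.biomarker_names),
        "covariates": list(cohort.covariate_names),
        "time_unit": cohort.time_unit,
    }
    if cohort.events is not None:
        schema["event_age"] = "event_age"
        schema["event_status"] = "event_status"
    return schema


# ---------------------------------------------------------------------------
# Transition pairs
# ---------------------------------------------------------------------------

def make_transition_pairs(cohort: LongitudinalCohort) -> list[TransitionPair]:
    """All consecutive-visit transitions; k visits yield k-1 pairs."""
    pairs: list[TransitionPair] = []
    y = cohort.biomarker_matrix()
    x = cohort.covariate_matrix()
    t = cohort.data[AGE_COL].to_numpy(float)
    ids = cohort.data[ID_COL].to_numpy()
    for start, stop in _individual_slices(ids):
        for n in range(start, stop - 1):
            pairs.append(
                TransitionPair(
                    individual_id=ids[n],
                    y_from=y[n],
                    y_to=y[n + 1],
                    x_from=x[n],
                    t_from=t[n],
                    dt=float(t[n + 1] - t[n]),
                )
            )
    return pairs


def _individual_slices(ids: np.ndarray):
    """(start, stop) row slices of each individual's contiguous block."""
    if len(ids) == 0:
        return
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(ids)]])
    for k in range(len(bounds) - 1):
        yield int(bounds[k]), int(bounds[k + 1])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class ScalingRecord:
    """Per-biomarker location/scale used to standardize; allows exact inversion."""

    means: dict[str, float]
    sds: dict[str, float]
    reference: str = "pooled"

    def invert(self, cohort: LongitudinalCohort) -> LongitudinalCohort:
        out = cohort.copy()
        for name in cohort.biomarker_names:
            out.data[name] = out.data[name] * self.sds[name] + self.means[name]
        return out

    def apply(self, cohort: LongitudinalCohort) -> LongitudinalCohort:
        out = cohort.copy()
        for name in cohort.biomarker_names:
            out.data[name] = (out.data[name] - self.means[name]) / self.sds[name]
        return out


def standardize(
    cohort: LongitudinalCohort, reference: str = "pooled"
) -> tuple[LongitudinalCohort, ScalingRecord]:
    """Scale each biomarker to mean 0, SD 1 (sample SD, denominator n-1).

    ``reference="pooled"`` uses all visits; ``"baseline"`` uses each
    individual's first visit only. Missing values are ignored when computing
    the statistics and stay missing afterwards.
    """
    if reference not in ("pooled", "baseline"):
        raise ValueError(f"unknown reference {reference!r}")
    ref = cohort.data if reference == "pooled" else cohort.baseline()
    means, sds = {}, {}
    for name in cohort.biomarker_names:
        vals = ref[name].dropna()
        if len(vals) < 2:
            raise ValueError(f"biomarker {name!r} has fewer than 2 observed values")
        sd = float(vals.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"biomarker {name!r} has zero variance; cannot standardize")
        means[name] = float(vals.mean())
        sds[name] = sd
    record = ScalingRecord(means=means, sds=sds, reference=reference)
    return record.apply(cohort), record
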