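"""Subject-level recurrent-event / survival data model and CSV round-trip.

A :class:`Subject` carries baseline prognostic covariates, the ordered
calendar times of its relapses (recurrent events), the last follow-up time
``T_D = min(death, censoring)`` and the death indicator.  A
:class:`Cohort` is a validated collection of subjects and is the in-memory
container every other module consumes.

Times are continuous years measured from the study origin (diagnosis);
intervals in the counting-process expansion are left-open/right-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_LEVELS",
    "GRADE_LEVELS",
    "COVARIATE_COLUMNS",
    "DESIGN_COLUMNS",
    "Subject",
    "Cohort",
    "CountingProcessRow",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "to_counting_process",
    "counting_process_frame",
    "design_row",
    "design_matrix",
]

AGE_LEVELS = ("le40", "40to55", "gt55")
GRADE_LEVELS = ("I", "II", "III")

#: covariate columns as stored in subjects.csv
COVARIATE_COLUMNS = ("age_group", "pvi", "size_gt20", "nodal", "grade")

#: dummy-coded design columns (reference levels: age >55, grade I)
DESIGN_COLUMNS = (
    "age_le40",
    "age_40to55",
    "pvi",
    "size_gt20",
    "nodal",
    "grade_II",
    "grade_III",
)


class SchemaError(ValueError):
    """A required column is missing or malformed in an input file."""


class CohortValidationError(ValueError):
    """Subject-level data violate an invariant (named subject in message)."""


@dataclass(frozen=True)
class Subject:
    """One patient: covariates, relapse calendar times, follow-up, death flag."""

    id: str
    covariates: Mapping[str, object]
    relapse_times: tuple[float, ...]
    followup_time: float
    death_indicator: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "relapse_times", tuple(float(t) for t in self.relapse_times))
        object.__setattr__(self, "covariates", dict(self.covariates))
        self._validate()

    def _validate(self) -> None:
        sid = self.id
        if self.followup_time <= 0:
            raise CohortValidationError(f"subject {sid!r}: followup_time must be > 0")
        if self.death_indicator not in (0, 1):
            raise CohortValidationError(f"subject {sid!r}: death_indicator must be 0 or 1")
        times = self.relapse_times
        if any(t <= 0 for t in times):
            raise CohortValidationError(f"subject {sid!r}: relapse times must be > 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CohortValidationError(
                f"subject {sid!r}: relapse times must be strictly increasing"
            )
        if times and times[-1] > self.followup_time:
            raise CohortValidationError(
                f"subject {sid!r}: relapse time {times[-1]} exceeds follow-up "
                f"{self.followup_time}"
            )
        cov = self.covariates
        for col in COVARIATE_COLUMNS:
            if col not in cov or cov[col] is None or (
                isinstance(cov[col], float) and np.isnan(cov[col])
            ):
                raise CohortValidationError(f"subject {sid!r}: missing covariate {col!r}")
        if cov["age_group"] not in AGE_LEVELS:
            raise CohortValidationError(
                f"subject {sid!r}: age_group must be one of {AGE_LEVELS}"
            )
        if cov["grade"] not in GRADE_LEVELS:
            raise CohortValidationError(
                f"subject {sid!r}: grade must be one of {GRADE_LEVELS}"
            )
        for col in ("pvi", "size_gt20", "nodal"):
            if int(cov[col]) not in (0, 1):
                raise CohortValidationError(f"subject {sid!r}: {col} must be 0/1")

    @property
    def n_relapses(self) -> int:
        return len(self.relapse_times)

    def relapses_before(self, s: float) -> tuple[float, ...]:
        """Relapse times X_ij <= s (the history available at prediction time s)."""
        return tuple(t for t in self.relapse_times if t <= s)


@dataclass
class Cohort:
    """Validated list of subjects with unique ids."""

    subjects: list[Subject]
    origin_description: str = "diagnosis"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_relapses(self) -> int:
        return sum(s.n_relapses for s in self.subjects)

    @property
    def n_deaths(self) -> int:
        return sum(s.death_indicator for s in self.subjects)

    def max_time(self) -> float:
        return max(s.followup_time for s in self.subjects)

    def subset(self, predicate) -> "Cohort":
        return Cohort([s for s in self.subjects if predicate(s)], self.origin_description)


@dataclass(frozen=True)
class CountingProcessRow:
    """One at-risk interval (t_start, t_stop] in the calendar-time expansion."""

    id: str
    t_start: float
    t_stop: float
    rec_event: int
    death_event: int
    covariates: Mapping[str, object] = field(default_factory=dict)


def design_row(covariates: Mapping[str, object]) -> np.ndarray:
    """Dummy-code one covariate map into the 7-column design layout."""
    return np.array(
        [
            1.0 if covariates["age_group"] == "le40" else 0.0,
            1.0 if covariates["age_group"] == "40to55" else 0.0,
            float(covariates["pvi"]),
            float(covariates["size_gt20"]),
            float(covariates["nodal"]),
            1.0 if covariates["grade"] == "II" else 0.0,
            1.0 if covariates["grade"] == "III" else 0.0,
        ]
    )


def design_matrix(subjects: Sequence[Subject]) -> np.ndarray:
    """(n, 7) dummy design matrix, rows in subject order."""
    if not subjects:
        return np.empty((0, len(DESIGN_COLUMNS)))
    return np.vstack([design_row(s.covariates) for s in subjects])


def read_cohort(subjects_path, recurrences_path) -> Cohort:
    """Read subjects.csv / recurrences.csv into a validated Cohort.

    Subjects with no recurrence rows are allowed; relapse times are sorted.
    """
    subj = pd.read_csv(subjects_path, dtype={"id": str}, float_precision="round_trip")
    required = ["id", *COVARIATE_COLUMNS, "followup_time", "death"]
    for col in required:
        if col not in subj.columns:
            raise SchemaError(f"subjects file missing column {col!r}")
    rec = pd.read_csv(recurrences_path, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "rec_time"):
        if col not in rec.columns:
            raise SchemaError(f"recurrences file missing column {col!r}")

    if subj["id"].duplicated().any():
        dup = sorted(subj.loc[subj["id"].duplicated(), "id"].unique())
        raise CohortValidationError(f"duplicate subject ids: {dup}")

    rec_by_id: dict[str, list[float]] = {}
    for sid, t in zip(rec["id"], rec["rec_time"]):
        rec_by_id.setdefault(sid, []).append(float(t))
    unknown = set(rec_by_id) - set(subj["id"])
    if unknown:
        raise CohortValidationError(
            f"recurrence rows reference unknown subject ids: {sorted(unknown)}"
        )

    subjects = []
    for row in subj.itertuples(index=False):
        times = sorted(rec_by_id.get(row.id, []))
        subjects.append(
            Subject(
                id=row.id,
                covariates={c: getattr(row, c) for c in COVARIATE_COLUMNS},
                relapse_times=tuple(times),
                followup_time=float(row.followup_time),
                death_indicator=int(row.death),
            )
        )
    return Cohort(subjects)


def write_cohort(cohort: Cohort, subjects_path, recurrences_path) -> None:
    """Write the two CSV files; read_cohort on the result round-trips exactly.

    Floats are written with repr precision (17 significant digits), so the
    round trip is bit-exact for binary64 times.
    """
    srows = []
    rrows = []
    for s in cohort:
        srows.append(
            {
                "id": s.id,
                **{c: s.covariates[c] for c in COVARIATE_COLUMNS},
                "followup_time": repr(float(s.followup_time)),
                "death": s.death_indicator,
            }
        )
        for t in s.relapse_times:
            rrows.append({"id": s.id, "rec_time": repr(float(t))})
    cols_s = ["id", *COVARIATE_COLUMNS, "followup_time", "death"]
    pd.DataFrame(srows, columns=cols_s).to_csv(subjects_path, index=False)
    pd.DataFrame(rrows, columns=["id", "rec_time"]).to_csv(recurrences_path, index=False)


def to_counting_process(cohort: Cohort) -> list[CountingProcessRow]:
    """Expand each subject into (0,X_1], (X_1,X_2], ..., (X_n, T_D] rows.

    A subject is at risk of the j-th relapse only after the (j-1)-st, so the
    j-th row closes at X_ij with rec_event=1.  If the last relapse coincides
    with T_D the degenerate final interval is dropped and the relapse row
    carries the death indicator.
    """
    rows: list[CountingProcessRow] = []
    for s in cohort:
        bounds = [0.0, *s.relapse_times]
        for j, t in enumerate(s.relapse_times):
            rows.append(CountingProcessRow(s.id, bounds[j], t, 1, 0, s.covariates))
        if s.relapse_times and s.relapse_times[-1] == s.followup_time:
            last = rows[-1]
            rows[-1] = replace(last, death_event=int(s.death_indicator))
        else:
            rows.append(
                CountingProcessRow(
                    s.id,
                    s.relapse_times[-1] if s.relapse_times else 0.0,
                    s.followup_time,
                    0,
                    int(s.death_indicator),
                    s.covariates,
                )
            )
    return rows


def counting_process_frame(cohort: Cohort) -> pd.DataFrame:
    """Counting-process rows as a DataFrame with dummy-coded covariates."""
    rows = to_counting_process(cohort)
    data = {
        "id": [r.id for r in rows],
        "t_start": [r.t_start for r in rows],
        "t_stop": [r.t_stop for r in rows],
        "rec_event": [r.rec_event for r in rows],
        "death_event": [r.death_event for r in rows],
    }
    design = np.vstack([design_row(r.covariates) for r in rows]) if rows else np.empty((0, 7))
    for k, col in enumerate(DESIGN_COLUMNS):
        data[col] = design[:, k]
    return pd.DataFrame(data)
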