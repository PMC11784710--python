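"""Cohort containers and canonical file formats.

A study cohort is a collection of subjects, each carrying minute-resolution
heart-rate (HR, beats/min) and respiratory-rate (RR, breaths/min) series over
an 80-minute protocol, plus — for training subjects — interstitial glucose
(mg/dL).  The protocol applies a brief 100% O2 (hyperoxia) stimulus after
minute 10 and a standardized meal at minute 21; the three minutes following
the stimulus (11-13 by default) are the window the downstream clustering
inspects.

Two on-disk layouts are supported:

* **tidy** (canonical, read/write): one row per subject-minute with header
  ``subject_id,group,minute,hr,rr,glucose``; the glucose cell may be empty.
* **wide** (read-only): a ``TIME`` column followed by one column per subject
  (HR or RR) or interleaved (RR, HR) column pairs for the combined variable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "VariableKind",
    "StimulusProtocol",
    "SubjectRecord",
    "Cohort",
    "PatientMatrix",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "extract_variable_matrix",
]


class CohortFormatError(ValueError):
    """Malformed cohort file (bad header, duplicate rows, unknown tokens)."""


class CohortValidationError(ValueError):
    """Structurally parseable cohort that violates an invariant."""


class Group(str, enum.Enum):
    PREDIABETES = "prediabetes"
    CONTROL = "control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class VariableKind(enum.Enum):
    """The three clustered variables, with their conventional integer codes."""

    HR = 1
    RR = 2
    RRxHR = 3

    @property
    def code(self) -> int:
        return self.value

    @classmethod
    def from_any(cls, value: "VariableKind | int | str") -> "VariableKind":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        key = str(value).replace("×", "x").replace("*", "x").upper()
        for member in cls:
            if member.name.upper() == key:
                return member
        raise ValueError(f"unknown variable kind: {value!r}")


VARIABLES: tuple[VariableKind, ...] = (
    VariableKind.HR,
    VariableKind.RR,
    VariableKind.RRxHR,
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the study protocol on the 1-based minute grid.

    Defaults follow the standard run: 10 baseline minutes, hyperoxia effects
    observed at minutes 11-13, meal at minute 21, 80 minutes total.
    """

    baseline_end_minute: int = 10
    postoxygen_window: tuple[int, int] = (11, 13)
    meal_minute: int = 21
    total_minutes: int = 80

    def __post_init__(self) -> None:
        lo, hi = self.postoxygen_window
        if not (
            self.baseline_end_minute < lo <= hi < self.meal_minute <= self.total_minutes
        ):
            raise CohortValidationError(
                "protocol ordering violated: require baseline_end < window start "
                "<= window end < meal_minute <= total_minutes, got "
                f"{self.baseline_end_minute} < {lo} <= {hi} < "
                f"{self.meal_minute} <= {self.total_minutes}"
            )

    @property
    def minutes(self) -> np.ndarray:
        return np.arange(1, self.total_minutes + 1)

    @property
    def window_minutes(self) -> np.ndarray:
        lo, hi = self.postoxygen_window
        return np.arange(lo, hi + 1)


def _as_float_array(name: str, values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise CohortValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's minute-indexed signals.

    ``glucose`` is optional: risk classification is non-invasive and needs
    only HR and RR; training requires glucose.
    """

    subject_id: str
    group: Group
    minutes: np.ndarray
    hr: np.ndarray
    rr: np.ndarray
    glucose: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "minutes", np.asarray(self.minutes, dtype=int))
        object.__setattr__(self, "hr", _as_float_array("hr", self.hr))
        object.__setattr__(self, "rr", _as_float_array("rr", self.rr))
        if self.glucose is not None:
            object.__setattr__(
                self, "glucose", _as_float_array("glucose", self.glucose)
            )
        m = self.minutes
        if m.size == 0:
            raise CohortValidationError(
                f"subject {self.subject_id}: empty minute grid"
            )
        if m[0] != 1 or not np.array_equal(m, np.arange(1, m.size + 1)):
            gaps = sorted(set(range(1, int(m.max()) + 1)) - set(m.tolist()))
            raise CohortValidationError(
                f"subject {self.subject_id}: minutes must be contiguous 1..T; "
                f"missing minutes {gaps}" if gaps else
                f"subject {self.subject_id}: minutes must be strictly increasing from 1"
            )
        for name, series in (("hr", self.hr), ("rr", self.rr)):
            if series.shape != m.shape:
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} length {series.size} "
                    f"!= minute grid length {m.size}"
                )
            if not np.all(series > 0):
                raise CohortValidationError(
                    f"subject {self.subject_id}: {name} must be strictly positive"
                )
        if self.glucose is not None:
            if self.glucose.shape != m.shape:
                raise CohortValidationError(
                    f"subject {self.subject_id}: glucose length "
                    f"{self.glucose.size} != minute grid length {m.size}"
                )
            if not np.all(self.glucose >= 0):
                raise CohortValidationError(
                    f"subject {self.subject_id}: glucose must be non-negative"
                )

    @property
    def n_minutes(self) -> int:
        return int(self.minutes.size)

    @property
    def has_glucose(self) -> bool:
        return self.glucose is not None

    def without_glucose(self) -> "SubjectRecord":
        return replace(self, glucose=None)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of subjects sharing one minute grid."""

    subjects: tuple[SubjectRecord, ...]
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        for s in self.subjects:
            if s.n_minutes != self.protocol.total_minutes:
                raise CohortValidationError(
                    f"subject {s.subject_id}: {s.n_minutes} minutes, protocol "
                    f"expects {self.protocol.total_minutes}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def group_subjects(self, group: Group | str) -> list[SubjectRecord]:
        group = Group(group)
        return [s for s in self.subjects if s.group is group]

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        wanted = list(subject_ids)
        return Cohort(
            subjects=tuple(self.subject(sid) for sid in wanted),
            protocol=self.protocol,
        )


@dataclass(frozen=True)
class PatientMatrix:
    """Time-by-subject value matrix for one variable and one group.

    The first column is the minute grid.  HR/RR contribute one value column
    per subject; the combined RRxHR variable contributes an interleaved
    (RR, HR) column pair per subject.
    """

    variable: VariableKind
    group: Group
    values: np.ndarray  # shape (T, 1 + n) or (T, 1 + 2n); column 0 is time
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n = len(self.subject_ids)
        per = 2 if self.variable is VariableKind.RRxHR else 1
        expected = 1 + per * n
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise CohortValidationError(
                f"PatientMatrix for {self.variable.name}: expected "
                f"{expected} columns for {n} subjects, got {self.values.shape}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.values[:, 0]

    def subject_points(self, subject_id: str) -> np.ndarray:
        """(time, value...) point set for one subject — the K-means input."""
        i = self.subject_ids.index(subject_id)
        if self.variable is VariableKind.RRxHR:
            cols = [0, 1 + 2 * i, 2 + 2 * i]
        else:
            cols = [0, 1 + i]
        return self.values[:, cols]


def extract_variable_matrix(
    cohort: Cohort, group: Group | str, variable: VariableKind | int | str
) -> PatientMatrix:
    """Assemble the per-group, per-variable time-by-subject matrix.

    For n subjects the result has 80 rows and 1+n columns (HR or RR) or
    1+2n columns (RRxHR, per-subject column pairs ordered RR then HR).
    """
    group = Group(group)
    variable = VariableKind.from_any(variable)
    members = cohort.group_subjects(group)
    if not members:
        raise CohortValidationError(f"no subjects in group {group.value!r}")
    columns = [cohort.protocol.minutes.astype(float)]
    for s in members:
        if variable is VariableKind.HR:
            columns.append(s.hr)
        elif variable is VariableKind.RR:
            columns.append(s.rr)
        else:
            columns.extend([s.rr, s.hr])
    return PatientMatrix(
        variable=variable,
        group=group,
        values=np.column_stack(columns),
        subject_ids=tuple(s.subject_id for s in members),
    )


# ---------------------------------------------------------------------------
# Tidy CSV (canonical) and wide (read-only) layouts
# ---------------------------------------------------------------------------

_TIDY_COLUMNS = ["subject_id", "group", "minute", "hr", "rr", "glucose"]


def read_cohort_csv(
    path: str | Path,
    layout: str = "tidy",
    *,
    group: Group | str | None = None,
    variable: VariableKind | int | str | None = None,
    protocol: StimulusProtocol | None = None,
) -> Cohort:
    """Read a cohort from CSV.

    ``layout='tidy'`` expects the canonical one-row-per-subject-minute file.
    ``layout='wide'`` expects a TIME column plus per-subject columns for a
    single variable; ``group`` and ``variable`` must then be given (the wide
    files carry neither).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "tidy":
        return _read_tidy(path, protocol)
    if layout == "wide":
        if group is None or variable is None:
            raise CohortFormatError(
                "wide layout carries no group/variable metadata; pass group= and variable="
            )
        return _read_wide(path, Group(group), VariableKind.from_any(variable), protocol)
    raise CohortFormatError(f"unknown layout {layout!r}")


def _read_tidy(path: Path, protocol: StimulusProtocol | None) -> Cohort:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _TIDY_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: tidy header missing columns {missing}")
    has_glucose = "glucose" in df.columns
    dupes = df.duplicated(subset=["subject_id", "minute"])
    if dupes.any():
        bad = df.loc[dupes, ["subject_id", "minute"]].iloc[0]
        raise CohortFormatError(
            f"{path}: duplicate row for subject {bad['subject_id']} minute "
            f"{int(bad['minute'])}"
        )
    bad_groups = set(df["group"].unique()) - {g.value for g in Group}
    if bad_groups:
        raise CohortFormatError(f"{path}: unknown group token(s) {sorted(bad_groups)}")

    subjects = []
    for sid in df["subject_id"].drop_duplicates():
        sub = df[df["subject_id"] == sid].sort_values("minute")
        glucose = None
        if has_glucose and sub["glucose"].notna().all():
            glucose = sub["glucose"].to_numpy(dtype=float)
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                group=Group(sub["group"].iloc[0]),
                minutes=sub["minute"].to_numpy(dtype=int),
                hr=sub["hr"].to_numpy(dtype=float),
                rr=sub["rr"].to_numpy(dtype=float),
                glucose=glucose,
            )
        )
    if protocol is None:
        total = subjects[0].n_minutes if subjects else StimulusProtocol().total_minutes
        protocol = StimulusProtocol(total_minutes=total)
    return Cohort(subjects=tuple(subjects), protocol=protocol)


def _read_wide(
    path: Path,
    group: Group,
    variable: VariableKind,
    protocol: StimulusProtocol | None,
) -> Cohort:
    df = pd.read_csv(path)
    first = df.columns[0]
    if first.strip().upper() != "TIME":
        raise CohortFormatError(f"{path}: wide layout must start with a TIME column")
    minutes = df[first].to_numpy(dtype=int)
    value_cols = list(df.columns[1:])
    if variable is VariableKind.RRxHR:
        if len(value_cols) % 2 != 0:
            raise CohortFormatError(
                f"{path}: RRxHR wide layout needs an even number of value columns "
                "(interleaved RR, HR pairs)"
            )
        n = len(value_cols) // 2
    else:
        n = len(value_cols)
    if n == 0:
        raise CohortFormatError(f"{path}: no subject columns")

    subjects = []
    for i in range(n):
        if variable is VariableKind.RRxHR:
            rr = df[value_cols[2 * i]].to_numpy(dtype=float)
            hr = df[value_cols[2 * i + 1]].to_numpy(dtype=float)
            sid = value_cols[2 * i + 1].replace("×", "x")
        else:
            series = df[value_cols[i]].to_numpy(dtype=float)
            sid = value_cols[i]
            # the complementary signal is absent in a single-variable wide
            # file; fill with a positive placeholder so the record validates
            placeholder = np.ones_like(series)
            hr = series if variable is VariableKind.HR else placeholder
            rr = series if variable is VariableKind.RR else placeholder
        subjects.append(
            SubjectRecord(
                subject_id=str(sid), group=group, minutes=minutes, hr=hr, rr=rr
            )
        )
    if protocol is None:
        protocol = StimulusProtocol(total_minutes=int(minutes.size))
    return Cohort(subjects=tuple(subjects), protocol=protocol)


def write_cohort_csv(cohort: Cohort, path: str | Path, layout: str = "tidy") -> Path:
    """Write a cohort as tidy CSV; returns the path written.

    The glucose column is omitted when no subject carries glucose.  An empty
    cohort yields a header-only file.  ``read_cohort_csv`` round-trips the
    result exactly.
    """
    if layout != "tidy":
        raise CohortFormatError(
            f"layout {layout!r} is read-only; cohorts are written in tidy layout"
        )
    path = Path(path)
    any_glucose = any(s.has_glucose for s in cohort)
    rows: list[dict] = []
    for s in cohort:
        for j, minute in enumerate(s.minutes):
            row = {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "minute": int(minute),
                "hr": s.hr[j],
                "rr": s.rr[j],
            }
            if any_glucose:
                row["glucose"] = s.glucose[j] if s.has_glucose else np.nan
            rows.append(row)
    columns = _TIDY_COLUMNS if any_glucose else _TIDY_COLUMNS[:5]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path
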