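"""Trial-level and subject-level data model with CSV readers/writers.

Every downstream stage consumes the tabular forms produced here: a trial
table with one row per task trial and a subject table with demographics and
SWAN symptom scores.  Times are stored in milliseconds in files; missing
values (no response -> no RT) are empty CSV cells, never numeric sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("TD", "ADHD")
TASKS = ("SST", "CSST")
SST_TRIAL_TYPES = ("go", "stop")
CSST_TRIAL_TYPES = ("certain_go", "uncertain_go", "stop")

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "task",
    "run",
    "trial_index",
    "trial_type",
    "ssd",
    "responded",
    "choice_correct",
    "rt",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "verbal_iq",
    "swan_inattention",
    "swan_hyperimpulsivity",
]


class TrialValidationError(ValueError):
    """A trial table row violates the data-model invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.

    ``ssd`` is present only on stop trials; ``rt`` and ``choice_correct``
    only when a response was made.  ``trial_index`` is 1-based within run.
    """

    subject_id: str
    group: str
    task: str
    run: int
    trial_index: int
    trial_type: str
    ssd: float | None = None
    responded: bool = False
    choice_correct: bool | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TrialValidationError(f"unknown group {self.group!r}")
        if self.task not in TASKS:
            raise TrialValidationError(f"unknown task {self.task!r}")
        allowed = SST_TRIAL_TYPES if self.task == "SST" else CSST_TRIAL_TYPES
        if self.trial_type not in allowed:
            raise TrialValidationError(
                f"trial_type {self.trial_type!r} invalid for task {self.task}"
            )
        if self.run < 1 or self.trial_index < 1:
            raise TrialValidationError("run and trial_index are 1-based")
        is_stop = self.trial_type == "stop"
        if is_stop != (self.ssd is not None):
            raise TrialValidationError("ssd must be present iff trial_type is stop")
        if self.ssd is not None and self.ssd < 0:
            raise TrialValidationError("ssd must be >= 0")
        if self.responded != (self.rt is not None):
            raise TrialValidationError("rt must be present iff responded")
        if self.rt is not None and self.rt <= 0:
            raise TrialValidationError("rt must be > 0")
        if self.responded != (self.choice_correct is not None):
            raise TrialValidationError("choice_correct must be present iff responded")


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert TrialRecords to the canonical trial DataFrame."""
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "task": r.task,
            "run": r.run,
            "trial_index": r.trial_index,
            "trial_type": r.trial_type,
            "ssd": np.nan if r.ssd is None else float(r.ssd),
            "responded": r.responded,
            "choice_correct": r.choice_correct,
            "rt": np.nan if r.rt is None else float(r.rt),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["choice_correct"] = df["choice_correct"].astype("boolean")
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Convert a trial DataFrame back to validated TrialRecords."""
    records = []
    for _, row in df.iterrows():
        records.append(
            TrialRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                task=str(row["task"]),
                run=int(row["run"]),
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                ssd=None if pd.isna(row["ssd"]) else float(row["ssd"]),
                responded=bool(row["responded"]),
                choice_correct=None
                if pd.isna(row["choice_correct"])
                else bool(row["choice_correct"]),
                rt=None if pd.isna(row["rt"]) else float(row["rt"]),
            )
        )
    return records


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial DataFrame against all row invariants.

    Returns the frame sorted by (subject, task, run, trial_index).  Raises
    :class:`TrialValidationError` naming the first offending row.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    df = df.sort_values(["subject_id", "task", "run", "trial_index"], kind="stable")
    df = df.reset_index(drop=True)
    key = ["subject_id", "task", "run", "trial_index"]
    dup = df.duplicated(key)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrialValidationError(f"duplicate trial key at row {i}: {df.loc[i, key].to_dict()}")
    for i, row in df.iterrows():
        try:
            TrialRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                task=str(row["task"]),
                run=int(row["run"]),
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                ssd=None if pd.isna(row["ssd"]) else float(row["ssd"]),
                responded=bool(row["responded"]),
                choice_correct=None
                if pd.isna(row["choice_correct"])
                else bool(row["choice_correct"]),
                rt=None if pd.isna(row["rt"]) else float(row["rt"]),
            )
        except TrialValidationError as exc:
            raise TrialValidationError(f"row {i} (subject {row['subject_id']}): {exc}") from exc
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Empty cells denote absent ssd / rt / choice_correct.  The returned frame
    is ordered by (subject, task, run, trial_index).
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "task": str, "trial_type": str},
    )
    if len(df) == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    for col in ("responded",):
        df[col] = df[col].astype(bool)
    df["choice_correct"] = df["choice_correct"].astype("boolean")
    return validate_trials(df)


def write_trials(df: pd.DataFrame | Sequence[TrialRecord], path: str | Path) -> None:
    """Write trials to CSV; absent values become empty cells."""
    if not isinstance(df, pd.DataFrame):
        df = trials_to_frame(df)
    df = df[TRIAL_COLUMNS]
    df.to_csv(path, index=False)


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the per-subject demographics/symptom table."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "gender": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"subject table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise TrialValidationError("duplicate subject_id in subject table")
    return df


def write_subjects(df: pd.DataFrame, path: str | Path) -> None:
    df[SUBJECT_COLUMNS].to_csv(path, index=False)
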