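"""Participant-level clinical records and the delimited clinical table.

A cohort row carries the transcriptomic ROR-P score and its risk group, the
ER/HER2 eligibility flag (performance metrics are reported on the
ER-positive, HER2-negative subset, the target population for ROR-P
testing), and the recurrence outcome (years to first recurrence or
censoring, plus the event indicator).  One participant may own multiple
slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .risk import categorize_rorp

__all__ = ["CohortRecord", "cohort_to_frame", "frame_to_cohort", "read_clinical", "write_clinical"]

CLINICAL_COLUMNS = [
    "participant_id",
    "slide_ids",
    "rorp_score",
    "rorp_group",
    "er_her2_eligible",
    "recurrence_time_years",
    "recurrence_event",
]


@dataclass
class CohortRecord:
    participant_id: str
    slide_ids: tuple[str, ...]
    rorp_score: float
    rorp_group: str
    er_her2_eligible: bool
    recurrence_time_years: float
    recurrence_event: bool

    def __post_init__(self) -> None:
        self.slide_ids = tuple(self.slide_ids)
        if len(self.slide_ids) < 1:
            raise ValueError("participant must own at least one slide")
        if self.recurrence_time_years < 0:
            raise ValueError("recurrence time must be non-negative")
        expected = categorize_rorp(self.rorp_score)
        if self.rorp_group != expected:
            raise ValueError(
                f"rorp_group {self.rorp_group!r} inconsistent with score "
                f"{self.rorp_score} (threshold coder gives {expected!r})"
            )


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one row per participant; slide ids joined with ';'."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "slide_ids": [";".join(r.slide_ids) for r in records],
            "rorp_score": [r.rorp_score for r in records],
            "rorp_group": [r.rorp_group for r in records],
            "er_her2_eligible": [r.er_her2_eligible for r in records],
            "recurrence_time_years": [r.recurrence_time_years for r in records],
            "recurrence_event": [r.recurrence_event for r in records],
        }
    )


def frame_to_cohort(frame: pd.DataFrame) -> list[CohortRecord]:
    missing = set(CLINICAL_COLUMNS) - set(frame.columns)
    if missing:
        raise KeyError(f"clinical table lacks columns: {sorted(missing)}")
    return [
        CohortRecord(
            participant_id=str(row.participant_id),
            slide_ids=tuple(str(row.slide_ids).split(";")),
            rorp_score=float(row.rorp_score),
            rorp_group=str(row.rorp_group),
            er_her2_eligible=bool(row.er_her2_eligible),
            recurrence_time_years=float(row.recurrence_time_years),
            recurrence_event=bool(row.recurrence_event),
        )
        for row in frame.itertuples(index=False)
    ]


def write_clinical(records: list[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_clinical(path: str | Path) -> list[CohortRecord]:
    return frame_to_cohort(pd.read_csv(path))
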