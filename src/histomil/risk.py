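"""ROR-P risk-group coding.

The PAM50-based risk-of-recurrence score (ROR-P) is a continuous score that
clinical assays stratify into three groups at fixed cutoffs:

* low:    score <  11.76471
* medium: 11.76471 <= score < 52.94118
* high:   score >= 52.94118

Binary evaluation treats high as the positive class and pools low/medium.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "LOW_MEDIUM_CUT",
    "MEDIUM_HIGH_CUT",
    "RISK_GROUPS",
    "categorize_rorp",
    "categorize_rorp_array",
    "binarize_group",
]

LOW_MEDIUM_CUT = 11.76471
MEDIUM_HIGH_CUT = 52.94118
RISK_GROUPS = ("low", "medium", "high")


def categorize_rorp(score: float) -> str:
    """Map a continuous ROR-P score to its risk group at the assay cutoffs."""
    if not math.isfinite(score):
        raise ValueError(f"ROR-P score must be finite, got {score!r}")
    if score < LOW_MEDIUM_CUT:
        return "low"
    if score < MEDIUM_HIGH_CUT:
        return "medium"
    return "high"


def categorize_rorp_array(scores: Iterable[float]) -> np.ndarray:
    """Vectorised :func:`categorize_rorp` returning an object array of group names."""
    arr = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ROR-P scores must be finite")
    out = np.where(arr < LOW_MEDIUM_CUT, "low", np.where(arr < MEDIUM_HIGH_CUT, "medium", "high"))
    return out.astype(object)


def binarize_group(group: str) -> int:
    """High -> 1 (positive class); low or medium -> 0."""
    if group == "high":
        return 1
    if group in ("low", "medium"):
        return 0
    raise ValueError(f"unknown risk group {group!r}")
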