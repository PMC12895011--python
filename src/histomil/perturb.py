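"""Perturbation-based interpretability for bag-level models.

Because attention weights only suggest where a MIL model may be looking,
region importance is tested here by *intervening* on the input: removing a
region from a bag (necessity), keeping only that region (sufficiency), or
inserting patches from one slide into another (sufficiency search and
transfer).  Since gated ABMIL is permutation-invariant, insertion is
realised by appending the donor patch's feature vector to the recipient
bag; coordinates for export are assigned on a reserved synthetic grid
appended below the recipient slide.

Effects are summarised per slide as perturbed-minus-original prediction
differences, with a two-sided paired t-test and paired Cohen's d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bag import EmbeddingBag
from .geometry import SlideGeometry
from .masks import RegionMask, patches_intersecting_mask
from .risk import MEDIUM_HIGH_CUT

__all__ = [
    "PerturbationResult",
    "SearchTrace",
    "remove_patches",
    "keep_only",
    "append_patches",
    "cohens_d_paired",
    "necessity_test",
    "sufficiency_test",
    "greedy_sufficiency_search",
    "transfer_test",
]

logger = logging.getLogger(__name__)

ScoreFn = Callable[[EmbeddingBag], float]


@dataclass
class PerturbationResult:
    """Paired original-vs-perturbed predictions and their effect summary."""

    table: pd.DataFrame  # slide_id, original, perturbed, delta
    t_statistic: float
    p_value: float
    cohens_d: float
    n: int
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"paired perturbation test on n={self.n} slides\n"
            f"mean delta = {self.table['delta'].mean(): .4f}\n"
            f"t = {self.t_statistic: .3f}, two-sided p = {self.p_value: .3g}, "
            f"Cohen's d = {self.cohens_d: .3f}"
            + ("  [degenerate: zero-variance deltas]" if self.degenerate else "")
        )


@dataclass
class SearchTrace:
    """Record of one greedy sufficiency search."""

    selected: list[int]  # donor patch indices, in insertion order
    predictions: list[float]  # prediction after each insertion
    initial_prediction: float
    stop_reason: str  # reached_threshold | exhausted_budget | no_improvement
    budget: int


def remove_patches(bag: EmbeddingBag, indices) -> EmbeddingBag:
    """Bag without the given feature rows (original bag untouched)."""
    drop = {int(i) for i in indices}
    keep = [i for i in range(bag.n_patches) if i not in drop]
    if not keep:
        raise ValueError("removal would leave an empty bag")
    return bag.subset(np.array(keep))


def keep_only(bag: EmbeddingBag, indices) -> EmbeddingBag:
    """Bag restricted to the given rows, original order preserved."""
    idx = sorted({int(i) for i in indices})
    if not idx:
        raise ValueError("cannot keep an empty patch set")
    return bag.subset(np.array(idx))


def append_patches(bag: EmbeddingBag, features: np.ndarray) -> EmbeddingBag:
    """Append foreign patch embeddings to a bag.

    New patches get coordinates on a synthetic grid appended below the
    slide (the geometry is extended accordingly); the model is
    permutation-invariant, so placement does not affect predictions.
    """
    feats = np.atleast_2d(np.asarray(features, dtype=np.float32))
    if feats.shape[0] == 0:
        return bag
    if feats.shape[1] != bag.dim:
        raise ValueError("appended features must match the bag's embedding dim")
    g = bag.geometry
    side = g.side_px
    nx = max(1, g.width_px // side)
    row0 = math.ceil(g.height_px / side)
    m = feats.shape[0]
    rows = math.ceil(m / nx)
    new_geom = SlideGeometry(
        width_px=g.width_px, height_px=(row0 + rows) * side, mpp=g.mpp, patch_um=g.patch_um
    )
    new_coords = np.array(
        [[(k % nx) * side, (row0 + k // nx) * side] for k in range(m)], dtype=np.int64
    )
    return EmbeddingBag(
        slide_id=bag.slide_id,
        encoder_id=bag.encoder_id,
        features=np.vstack([bag.features, feats]),
        coords=np.vstack([bag.coords, new_coords]),
        geometry=new_geom,
    )


def cohens_d_paired(deltas) -> float:
    """Paired Cohen's d: mean(delta) / sd(delta), sample (n-1) sd.

    Returns NaN (flagged by callers) when the deltas have zero variance.
    """
    d = np.asarray(deltas, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        logger.warning("zero-variance deltas: Cohen's d undefined")
        return float("nan")
    return float(d.mean() / sd)


def _paired_result(rows: list[dict]) -> PerturbationResult:
    table = pd.DataFrame(rows)
    deltas = table["delta"].to_numpy()
    if np.std(deltas, ddof=1) == 0:
        return PerturbationResult(
            table=table, t_statistic=float("nan"), p_value=float("nan"),
            cohens_d=float("nan"), n=len(table), degenerate=True,
        )
    t, p = stats.ttest_rel(table["perturbed"], table["original"])
    return PerturbationResult(
        table=table, t_statistic=float(t), p_value=float(p),
        cohens_d=cohens_d_paired(deltas), n=len(table),
    )


def _resolve_mask(bag: EmbeddingBag, mask: RegionMask | Sequence[int]) -> frozenset[int]:
    if isinstance(mask, RegionMask):
        return patches_intersecting_mask(bag, mask)
    return frozenset(int(i) for i in mask)


def necessity_test(
    score_fn: ScoreFn,
    bags: Sequence[EmbeddingBag],
    masks: dict[str, RegionMask],
    inclusion_threshold: float = 0.5,
) -> PerturbationResult:
    """Is the masked region necessary?  Remove it and measure the drop.

    Only slides the model originally calls positive (score strictly above
    ``inclusion_threshold``) are included.  A negative mean delta means the
    region was necessary for the positive prediction.
    """
    rows = []
    for bag in bags:
        original = float(score_fn(bag))
        if original <= inclusion_threshold:
            continue
        idx = _resolve_mask(bag, masks[bag.slide_id])
        perturbed = original if not idx else float(score_fn(remove_patches(bag, idx)))
        rows.append(
            {"slide_id": bag.slide_id, "original": original, "perturbed": perturbed,
             "delta": perturbed - original}
        )
    if len(rows) < 2:
        raise ValueError(f"necessity test needs >= 2 eligible slides, got {len(rows)}")
    return _paired_result(rows)


def sufficiency_test(
    score_fn: ScoreFn,
    bags: Sequence[EmbeddingBag],
    masks: dict[str, RegionMask],
    inclusion_threshold: float = 0.5,
) -> PerturbationResult:
    """Is the masked region sufficient?  Keep only it and compare.

    Slides with an empty mask cannot be reduced to the region and are
    excluded (the count is logged).  A near-zero or positive mean delta
    means the region alone reproduces the prediction.
    """
    rows = []
    skipped = 0
    for bag in bags:
        original = float(score_fn(bag))
        if original <= inclusion_threshold:
            continue
        idx = _resolve_mask(bag, masks[bag.slide_id])
        if not idx:
            skipped += 1
            continue
        perturbed = float(score_fn(keep_only(bag, idx)))
        rows.append(
            {"slide_id": bag.slide_id, "original": original, "perturbed": perturbed,
             "delta": perturbed - original}
        )
    if skipped:
        logger.info("sufficiency test: %d slides skipped for empty masks", skipped)
    if len(rows) < 2:
        raise ValueError(f"sufficiency test needs >= 2 eligible slides, got {len(rows)}")
    return _paired_result(rows)


def greedy_sufficiency_search(
    score_fn: ScoreFn,
    donor_bag: EmbeddingBag,
    recipient_bag: EmbeddingBag,
    high_threshold: float = MEDIUM_HIGH_CUT,
    stop_on_no_improvement: bool = True,
) -> SearchTrace:
    """Greedy search for a minimal donor patch set that flips the recipient.

    At each step every unused donor patch is provisionally inserted into
    the recipient (plus previously selected patches) and the patch giving
    the highest prediction is kept (ties to the lowest donor index).  The
    search stops when the prediction reaches ``high_threshold``, when a
    quarter of the donor's patches have been used (at least one), or — if
    ``stop_on_no_improvement`` — when the best candidate no longer raises
    the prediction.
    """
    budget = max(1, donor_bag.n_patches // 4)
    current = recipient_bag
    pred = float(score_fn(current))
    trace = SearchTrace(
        selected=[], predictions=[], initial_prediction=pred, stop_reason="", budget=budget
    )
    if pred >= high_threshold:
        trace.stop_reason = "reached_threshold"
        return trace

    unused = list(range(donor_bag.n_patches))
    while True:
        best_idx, best_pred = None, -np.inf
        for j in unused:
            cand = append_patches(current, donor_bag.features[j])
            s = float(score_fn(cand))
            if s > best_pred:  # ties keep the earliest (lowest) donor index
                best_idx, best_pred = j, s
        if stop_on_no_improvement and best_pred <= pred:
            trace.stop_reason = "no_improvement"
            return trace
        unused.remove(best_idx)
        current = append_patches(current, donor_bag.features[best_idx])
        pred = best_pred
        trace.selected.append(best_idx)
        trace.predictions.append(pred)
        if pred >= high_threshold:
            trace.stop_reason = "reached_threshold"
            return trace
        if len(trace.selected) >= budget:
            trace.stop_reason = "exhausted_budget"
            return trace


def transfer_test(
    score_fn: ScoreFn,
    patch_features: np.ndarray,
    recipient_bags: Sequence[EmbeddingBag],
) -> pd.DataFrame:
    """Insert a fixed patch set into each recipient and report paired scores.

    Returns one row per recipient with the original prediction, the
    prediction after insertion, and their difference — the transferability
    check for a discovered high-risk patch set.
    """
    feats = np.atleast_2d(np.asarray(patch_features))
    if feats.shape[0] == 0:
        raise ValueError("patch set must be non-empty")
    rows = []
    for bag in recipient_bags:
        original = float(score_fn(bag))
        augmented = float(score_fn(append_patches(bag, feats)))
        rows.append(
            {"slide_id": bag.slide_id, "original": original, "augmented": augmented,
             "delta": augmented - original}
        )
    return pd.DataFrame(rows, columns=["slide_id", "original", "augmented", "delta"])
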