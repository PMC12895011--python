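"""Participant-stratified 10-fold cross-validation and ensemble inference.

Folds are assigned at the participant level (a participant's slides always
share a role, so multi-slide participants can never leak between train and
test) and stratified so the three risk groups are similarly distributed
across folds.  In each iteration one fold is the test set, one of the
remaining nine is the validation set used for early stopping and threshold
selection, and the rest train the model.  Pooling the test predictions over
iterations yields exactly one out-of-sample prediction per slide.

External cohorts are scored with the ensemble of the 10 fold models:
softmax probabilities are averaged for classification, raw continuous
outputs for regression.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .bag import EmbeddingBag
from .cohort import CohortRecord
from .mil import ABMILConfig, ABMILModel, ABMILResults
from .risk import binarize_group

__all__ = ["assign_folds", "crossvalidate", "ensemble_predict", "restrict_eligible"]

logger = logging.getLogger(__name__)


def assign_folds(records: list[CohortRecord], k: int = 10, seed: int = 0) -> dict[str, int]:
    """Stratified participant -> fold index map (folds near-equal in size)."""
    if k > len(records):
        raise ValueError(f"cannot make {k} folds from {len(records)} participants")
    pids = [r.participant_id for r in records]
    groups = [r.rorp_group for r in records]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(pids, groups)):
        for i in test_idx:
            assignment[pids[i]] = fold
    return assignment


def _targets(records: list[CohortRecord], task: str) -> dict[str, float]:
    if task == "classification":
        return {r.participant_id: float(binarize_group(r.rorp_group)) for r in records}
    return {r.participant_id: r.rorp_score for r in records}


def crossvalidate(
    records: list[CohortRecord],
    bags: list[EmbeddingBag],
    config: ABMILConfig,
    k: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[ABMILResults], dict[str, int]]:
    """K-fold CV over a cohort; returns (prediction table, fold models, folds).

    The prediction table has one ``split == "test"`` row per slide (the
    pooled out-of-sample predictions) and ``split == "val"`` rows from each
    iteration's validation fold (pooled for threshold selection).
    Deterministic given ``seed`` (defaults to ``config.seed``).
    """
    seed = config.seed if seed is None else seed
    by_pid = {r.participant_id: r for r in records}
    slide_owner: dict[str, str] = {}
    for r in records:
        for sid in r.slide_ids:
            slide_owner[sid] = r.participant_id
    bag_ids = {b.slide_id for b in bags}
    missing = [sid for sid in slide_owner if sid not in bag_ids]
    if missing:
        raise ValueError(f"no bag for slides: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    folds = assign_folds(records, k=k, seed=seed)
    targets = _targets(records, config.task)
    bag_pid = [slide_owner[b.slide_id] for b in bags]
    y = np.array([targets[p] for p in bag_pid])
    bag_fold = np.array([folds[p] for p in bag_pid])

    rows = []
    models: list[ABMILResults] = []
    for f in range(k):
        val_fold = (f + 1) % k
        test_idx = np.flatnonzero(bag_fold == f)
        val_idx = np.flatnonzero(bag_fold == val_fold)
        train_idx = np.flatnonzero((bag_fold != f) & (bag_fold != val_fold))
        fold_cfg = ABMILConfig(**{**config.__dict__, "seed": int(np.random.SeedSequence([seed, f]).generate_state(1)[0] % 2**31)})
        res = ABMILModel(bags, y, fold_cfg).fit(train_idx, val_idx)
        models.append(res)
        for split, idx in (("val", val_idx), ("test", test_idx)):
            for i in idx:
                b = bags[i]
                pid = bag_pid[i]
                row = {
                    "slide_id": b.slide_id,
                    "participant_id": pid,
                    "fold": f,
                    "split": split,
                    "er_her2_eligible": by_pid[pid].er_her2_eligible,
                    "target": y[i],
                }
                logits = res.logits(b)
                if config.task == "classification":
                    probs = np.exp(logits - logits.max())
                    probs /= probs.sum()
                    row.update(logit_0=logits[0], logit_1=logits[1], prob_high=probs[1])
                else:
                    row.update(score=res.predict_score(b))
                rows.append(row)

    table = pd.DataFrame(rows)
    test = table[table["split"] == "test"]
    assert sorted(test["slide_id"]) == sorted(slide_owner), "test predictions must cover every slide once"
    return table, models, folds


def ensemble_predict(
    bags: list[EmbeddingBag], models: list[ABMILResults]
) -> pd.DataFrame:
    """Score bags with a model ensemble (e.g. the 10 CV fold models).

    Classification: the per-model softmax probabilities are averaged.
    Regression: the raw continuous outputs are averaged.
    """
    if not models:
        raise ValueError("ensemble needs at least one model")
    task = models[0].config.task
    for m in models[1:]:
        if m.config.task != task:
            raise ValueError("ensemble models must share a task")
        m.params.validate_like(models[0].params)
    rows = []
    for b in bags:
        if task == "classification":
            probs = np.mean([m.predict_proba(b) for m in models], axis=0)
            rows.append({"slide_id": b.slide_id, "prob_low_medium": probs[0], "prob_high": probs[1]})
        else:
            rows.append({"slide_id": b.slide_id, "score": float(np.mean([m.predict_score(b) for m in models]))})
    return pd.DataFrame(rows)


def restrict_eligible(table: pd.DataFrame, records: list[CohortRecord] | None = None) -> pd.DataFrame:
    """Filter a prediction table to the ER+/HER2- eligible subset.

    Training always uses the full cohort; only evaluation is restricted to
    the clinically relevant subset.
    """
    if "er_her2_eligible" not in table.columns:
        if records is None:
            raise ValueError("need cohort records to resolve eligibility")
        flags = {r.participant_id: r.er_her2_eligible for r in records}
        table = table.assign(er_her2_eligible=table["participant_id"].map(flags))
    out = table[table["er_her2_eligible"].astype(bool)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no eligible rows remain after ER/HER2 restriction")
    return out
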