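"""End-to-end benchmarking orchestration.

Runs the full evaluation stack over several encoders' embedding sets of
one cohort: cross-validated classification and regression heads, AUC and
Pearson comparisons against a named baseline encoder (DeLong and Meng's z,
BH-adjusted within each task/metric family), Youden threshold selection on
pooled validation predictions, and the survival stack (C-index for the
categorical, continuous, and thresholded-continuous predictors; Cox Wald
and log-rank tests; cumulative-recurrence curves).

Everything is deterministic under the master seed, which fans out to named
substreams (simulation, folds, initialisation, data order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bag import EmbeddingBag
from .cohort import CohortRecord
from .crossval import crossvalidate, ensemble_predict, restrict_eligible
from .metrics import bh_adjust, delong_test, meng_z_from_scores, pearson_r, roc_auc, youden_threshold
from .mil import ABMILConfig, ABMILResults
from .risk import MEDIUM_HIGH_CUT, binarize_group
from .survival import (
    SurvivalData,
    censor_at,
    compare_correlated_cindex,
    concordance_index,
    cox_univariable,
    logrank_test,
    threshold_continuous_predictions,
)

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark", "run_external_eval"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Benchmark run settings."""

    baseline: str
    encoders: list[str]
    tasks: tuple[str, ...] = ("classification", "regression", "survival")
    k_folds: int = 10
    seed: int = 0
    embed_dim: int = 64
    attention_dim: int = 32
    max_epochs: int = 40

    def __post_init__(self) -> None:
        if self.baseline not in self.encoders:
            raise ValueError(f"baseline {self.baseline!r} must be among encoders {self.encoders}")


@dataclass
class BenchmarkReport:
    """Tidy benchmark table plus per-fold detail sidecar."""

    table: pd.DataFrame  # encoder, task, metric, value, p, p_adj
    detail: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "benchmark_table.csv", index=False)
        (out / "benchmark_detail.json").write_text(json.dumps(self.detail, default=float, indent=1))


def _participant_predictions(test_table: pd.DataFrame, value_col: str) -> pd.Series:
    """Mean prediction per participant (multi-slide participants averaged)."""
    return test_table.groupby("participant_id")[value_col].mean()


def _survival_frame(records: list[CohortRecord], eligible_only: bool = True) -> pd.DataFrame:
    rows = [
        {
            "participant_id": r.participant_id,
            "time": r.recurrence_time_years,
            "event": r.recurrence_event,
            "rorp_score": r.rorp_score,
            "high": binarize_group(r.rorp_group),
        }
        for r in records
        if r.er_her2_eligible or not eligible_only
    ]
    return pd.DataFrame(rows).set_index("participant_id")


def _survival_data(surv: pd.DataFrame, predictor: pd.Series) -> SurvivalData:
    joined = surv.join(predictor.rename("pred"), how="inner")
    data = SurvivalData(joined["time"], joined["event"], joined["pred"])
    return censor_at(data)


def run_benchmark(
    config: RunConfig,
    encoder_bags: dict[str, list[EmbeddingBag]],
    records: list[CohortRecord],
) -> BenchmarkReport:
    """Cross-validate both heads for every encoder and build the report.

    ``encoder_bags`` maps each encoder id to that encoder's embedding bags
    of the *same* cohort.  All metrics are computed on the pooled
    out-of-fold test predictions of the ER+/HER2- eligible subset;
    comparison tests are against the baseline encoder and BH-adjusted
    within each (task, metric) family.
    """
    missing = set(config.encoders) - set(encoder_bags)
    if missing:
        raise ValueError(f"no bags supplied for encoders: {sorted(missing)}")
    dim = encoder_bags[config.baseline][0].dim
    truth_score = {r.participant_id: r.rorp_score for r in records}
    truth_high = {r.participant_id: binarize_group(r.rorp_group) for r in records}
    surv = _survival_frame(records)

    per_encoder: dict[str, dict] = {}
    detail: dict[str, dict] = {}
    for enc in config.encoders:
        logger.info("benchmark: cross-validating encoder %s", enc)
        out: dict = {}
        for task in ("classification", "regression"):
            cfg = ABMILConfig(
                input_dim=encoder_bags[enc][0].dim,
                embed_dim=config.embed_dim,
                attention_dim=config.attention_dim,
                task=task,
                max_epochs=config.max_epochs,
                seed=int(np.random.SeedSequence([config.seed, hash(enc) % 2**31, 0 if task == "classification" else 1]).generate_state(1)[0] % 2**31),
            )
            table, models, _ = crossvalidate(records, encoder_bags[enc], cfg, k=config.k_folds, seed=config.seed)
            test = restrict_eligible(table[table["split"] == "test"], records)
            val = restrict_eligible(table[table["split"] == "val"], records)
            out[task] = {"test": test, "val": val, "models": models}
        per_encoder[enc] = out
        logger.info("benchmark: %s eligible test slides = %d", enc, len(out["classification"]["test"]))

    rows = []
    base = per_encoder[config.baseline]
    base_cls = base["classification"]["test"].set_index("slide_id").sort_index()
    base_reg = base["regression"]["test"].set_index("slide_id").sort_index()

    for enc in config.encoders:
        cls = per_encoder[enc]["classification"]["test"].set_index("slide_id").sort_index()
        reg = per_encoder[enc]["regression"]["test"].set_index("slide_id").sort_index()
        labels = cls["target"].to_numpy().astype(int)
        auc = roc_auc(cls["prob_high"].to_numpy(), labels)
        if enc == config.baseline:
            p_auc = np.nan
        else:
            p_auc = delong_test(labels, cls["prob_high"].to_numpy(), base_cls["prob_high"].to_numpy()).p_value
        rows.append({"encoder": enc, "task": "classification", "metric": "roc_auc", "value": auc, "p": p_auc})

        true_scores = reg["target"].to_numpy()
        r = pearson_r(reg["score"].to_numpy(), true_scores)
        if enc == config.baseline:
            p_r = np.nan
        else:
            p_r = meng_z_from_scores(true_scores, reg["score"].to_numpy(), base_reg["score"].to_numpy()).p_value
        rows.append({"encoder": enc, "task": "regression", "metric": "pearson_r", "value": r, "p": p_r})

        if "survival" in config.tasks:
            val = per_encoder[enc]["classification"]["val"]
            thr = youden_threshold(val["prob_high"].to_numpy(), val["target"].to_numpy().astype(int))
            cls_binary = (_participant_predictions(cls.reset_index(), "prob_high") >= thr).astype(float)
            cont_score = _participant_predictions(reg.reset_index(), "score")
            thr_cont = pd.Series(
                threshold_continuous_predictions(cont_score.to_numpy()), index=cont_score.index, dtype=float
            )
            assay = _survival_data(surv, surv["rorp_score"])

            for metric, predictor in (
                ("cindex_categorical", cls_binary),
                ("cindex_continuous", cont_score),
                ("cindex_thresholded", thr_cont),
            ):
                data = _survival_data(surv, predictor)
                # tiny cohorts can lack the comparable pairs these estimators
                # need; report what is computable and mark the rest NaN
                try:
                    c = concordance_index(data)
                except ValueError as exc:
                    logger.warning("%s %s undefined: %s", enc, metric, exc)
                    rows.append({"encoder": enc, "task": "survival", "metric": metric, "value": np.nan, "p": np.nan})
                    continue
                try:
                    p_c = compare_correlated_cindex(data, assay).p_value
                except ValueError as exc:
                    logger.warning("%s %s comparison degenerate: %s", enc, metric, exc)
                    p_c = np.nan
                rows.append({"encoder": enc, "task": "survival", "metric": metric, "value": c, "p": p_c})

            cont_data = _survival_data(surv, cont_score)
            cox = cox_univariable(cont_data)
            rows.append({"encoder": enc, "task": "survival", "metric": "cox_hr_continuous", "value": cox.hazard_ratio, "p": cox.p_value})
            bin_data = _survival_data(surv, cls_binary)
            if bin_data.predictor.std() > 0:
                lr = logrank_test(bin_data, bin_data.predictor)
                rows.append({"encoder": enc, "task": "survival", "metric": "logrank_chi2", "value": lr.statistic, "p": lr.p_value})
            detail[enc] = {"youden_threshold": float(thr)}

    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for (task, metric), idx in table.groupby(["task", "metric"]).groups.items():
        sub = table.loc[idx]
        usable = sub["p"].notna()
        if usable.any():
            table.loc[sub.index[usable], "p_adj"] = bh_adjust(sub.loc[usable, "p"].to_numpy())
    return BenchmarkReport(table=table, detail=detail)


def run_external_eval(
    models_by_encoder: dict[str, list[ABMILResults]],
    encoder_bags: dict[str, list[EmbeddingBag]],
    records: list[CohortRecord],
    baseline: str,
) -> BenchmarkReport:
    """Score a held-out cohort with the fold-model ensembles (no training).

    For each encoder the k CV models are ensembled (mean softmax
    probability / mean raw score) and the same metric stack is computed on
    the eligible subset.
    """
    surv = _survival_frame(records)
    owner = {sid: r.participant_id for r in records for sid in r.slide_ids}
    eligible_pids = {r.participant_id for r in records if r.er_her2_eligible}
    truth_high = {r.participant_id: binarize_group(r.rorp_group) for r in records}
    truth_score = {r.participant_id: r.rorp_score for r in records}

    preds: dict[str, dict[str, pd.DataFrame]] = {}
    for enc, models in models_by_encoder.items():
        by_task: dict[str, list[ABMILResults]] = {"classification": [], "regression": []}
        for m in models:
            by_task[m.config.task].append(m)
        preds[enc] = {}
        for task, task_models in by_task.items():
            if not task_models:
                continue
            tab = ensemble_predict(encoder_bags[enc], task_models)
            tab["participant_id"] = tab["slide_id"].map(owner)
            tab = tab[tab["participant_id"].isin(eligible_pids)].reset_index(drop=True)
            preds[enc][task] = tab

    rows = []
    for enc in models_by_encoder:
        cls = preds[enc].get("classification")
        if cls is not None:
            labels = cls["participant_id"].map(truth_high).to_numpy().astype(int)
            auc = roc_auc(cls["prob_high"].to_numpy(), labels)
            if enc == baseline:
                p = np.nan
            else:
                b = preds[baseline]["classification"].set_index("slide_id")
                a = cls.set_index("slide_id").loc[b.index]
                p = delong_test(
                    a["participant_id"].map(truth_high).to_numpy().astype(int),
                    a["prob_high"].to_numpy(), b["prob_high"].to_numpy(),
                ).p_value
            rows.append({"encoder": enc, "task": "classification", "metric": "roc_auc", "value": auc, "p": p})
        reg = preds[enc].get("regression")
        if reg is not None:
            y = reg["participant_id"].map(truth_score).to_numpy()
            r = pearson_r(reg["score"].to_numpy(), y)
            if enc == baseline:
                p = np.nan
            else:
                b = preds[baseline]["regression"].set_index("slide_id")
                a = reg.set_index("slide_id").loc[b.index]
                p = meng_z_from_scores(
                    a["participant_id"].map(truth_score).to_numpy(),
                    a["score"].to_numpy(), b["score"].to_numpy(),
                ).p_value
            rows.append({"encoder": enc, "task": "regression", "metric": "pearson_r", "value": r, "p": p})
            cont = pd.Series(reg["score"].to_numpy(), index=reg["participant_id"]).groupby(level=0).mean()
            data = _survival_data(surv, cont)
            rows.append({
                "encoder": enc, "task": "survival", "metric": "cindex_continuous",
                "value": concordance_index(data),
                "p": compare_correlated_cindex(data, _survival_data(surv, surv["rorp_score"])).p_value,
            })

    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for (_, _), idx in table.groupby(["task", "metric"]).groups.items():
        sub = table.loc[idx]
        usable = sub["p"].notna()
        if usable.any():
            table.loc[sub.index[usable], "p_adj"] = bh_adjust(sub.loc[usable, "p"].to_numpy())
    return BenchmarkReport(table=table)
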