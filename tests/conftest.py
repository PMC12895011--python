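"""Shared fixtures.

The expensive planted-cohort cross-validations are session-scoped so the
recovery, perturbation and acceptance tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

import histomil as hm

PLANTED_SEED = 11
CV_SEED = 5


@pytest.fixture(scope="session")
def planted_cohort():
    """Strongly planted synthetic cohort (n=200, d=32) with ground truth."""
    cfg = hm.GeneratorConfig.strong_signal(n_participants=200, seed=PLANTED_SEED)
    bags, masks, records, truth = hm.generate_cohort(cfg)
    return {"config": cfg, "bags": bags, "masks": masks, "records": records, "truth": truth}


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-signal cohort for cheap structural tests."""
    cfg = hm.GeneratorConfig(n_participants=40, seed=2)
    bags, masks, records, truth = hm.generate_cohort(cfg)
    return {"config": cfg, "bags": bags, "masks": masks, "records": records, "truth": truth}


def _head_config(task: str) -> hm.ABMILConfig:
    return hm.ABMILConfig(
        input_dim=32, embed_dim=128, attention_dim=64, task=task, seed=CV_SEED
    )


@pytest.fixture(scope="session")
def classification_cv(planted_cohort):
    """10-fold CV of the classification head on the planted cohort."""
    table, models, folds = hm.crossvalidate(
        planted_cohort["records"], planted_cohort["bags"], _head_config("classification"),
        k=10, seed=CV_SEED,
    )
    return {"table": table, "models": models, "folds": folds}


@pytest.fixture(scope="session")
def regression_cv(planted_cohort):
    """10-fold CV of the regression head on the planted cohort."""
    table, models, folds = hm.crossvalidate(
        planted_cohort["records"], planted_cohort["bags"], _head_config("regression"),
        k=10, seed=CV_SEED,
    )
    return {"table": table, "models": models, "folds": folds}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
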