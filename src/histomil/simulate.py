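"""Synthetic embedding cohorts with planted, recoverable structure.

Real development data for this pipeline (slide scans, access-controlled
clinical follow-up, proprietary encoder weights) cannot ship with the
package, so every downstream stage is exercised on synthetic cohorts that
reproduce the *statistical* structure the pipeline assumes:

* each participant has a latent continuous risk score ``r`` drawn from a
  truncated normal whose mass in the three assay risk bins matches the
  development cohort's printed proportions (~18% low / 49% medium / 33%
  high);
* each slide is a bag of d-dimensional patch embeddings; patches inside
  the slide's tumor mask carry a mean shift ``beta * r * u`` along a single
  cohort-level unit direction ``u`` (mu0 = 0), all patches carry isotropic
  Gaussian noise — so brute-force recovery oracles are trivial;
* time to recurrence is exponential with log-hazard linear in ``r``
  (proportional hazards holds by construction), administratively censored
  at 10 years; hazard parameters default to ~13% 10-year event fraction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .bag import EmbeddingBag
from .cohort import CohortRecord
from .geometry import SlideGeometry, compute_patch_grid
from .masks import RegionMask
from .risk import categorize_rorp

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_cohort", "generate_null_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Defaults emulate the study conditions of the emulated pipeline: risk
    scores spanning all three assay bins in the printed proportions,
    ~13% 10-year recurrence among participants, ~65% ER+/HER2- eligible,
    128-um patches at 0.5 um/px.
    """

    n_participants: int = 200
    embedding_dim: int = 32
    patches_per_slide: tuple[int, int] = (32, 64)
    tumor_fraction: tuple[float, float] = (0.2, 0.6)
    score_loc: float = 40.0
    score_scale: float = 30.0
    score_support: tuple[float, float] = (-20.0, 90.0)
    signal_strength: float = 0.05  # beta: tumor-patch mean shift per score unit
    noise_sd: float = 1.0
    baseline_hazard: float = 0.0025  # lambda0, events per year at r = 0
    log_hazard_per_unit: float = 0.03  # gamma, log-hazard slope per score unit
    censor_horizon: float = 10.0
    eligible_fraction: float = 0.65
    multi_slide_fraction: float = 0.0  # fraction of participants owning 2 slides
    mpp: float = 0.5
    patch_um: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patches_per_slide[0] < 2:
            raise ValueError("patches_per_slide minimum must be >= 2")
        if not (0 < self.tumor_fraction[0] <= self.tumor_fraction[1] < 1):
            raise ValueError("tumor_fraction range must lie in (0, 1)")
        for name in ("score_scale", "noise_sd", "baseline_hazard", "censor_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")

    @classmethod
    def strong_signal(cls, **overrides) -> "GeneratorConfig":
        """Strongly planted conditions used by the recovery checks."""
        overrides.setdefault("signal_strength", 0.2)
        return cls(**overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    direction: np.ndarray  # cohort-level unit vector u in R^d
    latent_scores: dict[str, float]  # participant_id -> r
    signal_indices: dict[str, frozenset[int]]  # slide_id -> planted patch rows
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        doc = {
            "direction": self.direction.tolist(),
            "latent_scores": self.latent_scores,
            "signal_indices": {k: sorted(v) for k, v in self.signal_indices.items()},
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        cfg = doc["config"]
        for key in ("patches_per_slide", "tumor_fraction", "score_support"):
            cfg[key] = tuple(cfg[key])
        return cls(
            direction=np.asarray(doc["direction"]),
            latent_scores=doc["latent_scores"],
            signal_indices={k: frozenset(v) for k, v in doc["signal_indices"].items()},
            config=GeneratorConfig(**cfg),
        )


def _draw_scores(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.score_support
    a = (lo - cfg.score_loc) / cfg.score_scale
    b = (hi - cfg.score_loc) / cfg.score_scale
    return stats.truncnorm.rvs(
        a, b, loc=cfg.score_loc, scale=cfg.score_scale, size=cfg.n_participants, random_state=rng
    )


def _slide_geometry(cfg: GeneratorConfig, n_patches: int) -> SlideGeometry:
    side = int(round(cfg.patch_um / cfg.mpp))
    cols = int(np.ceil(np.sqrt(n_patches)))
    rows = int(np.ceil(n_patches / cols))
    return SlideGeometry(width_px=cols * side, height_px=rows * side, mpp=cfg.mpp, patch_um=cfg.patch_um)


def generate_cohort(
    config: GeneratorConfig,
    direction: np.ndarray | None = None,
) -> tuple[list[EmbeddingBag], dict[str, RegionMask], list[CohortRecord], SyntheticTruth]:
    """Generate bags, tumor masks, clinical records and ground truth.

    Tumor-mask patches are exactly the rows carrying the planted mean shift
    ``beta * r * u``; non-tumor patches are pure noise.  Recurrence time is
    ``T ~ Exp(rate = lambda0 * exp(gamma * r))`` with administrative
    censoring at the horizon (events exactly at the horizon are kept).

    Passing ``direction`` reuses another cohort's signal direction ``u`` —
    i.e. the two cohorts share one encoder geometry, as an external
    validation cohort embedded with the same encoder would.
    """
    cfg = config
    if cfg.signal_strength == 0:
        logger.warning("signal_strength is 0: bags carry no signal; recovery tests will fail by design")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.embedding_dim

    u = rng.normal(size=d)
    u /= np.linalg.norm(u)
    if direction is not None:
        u = np.asarray(direction, dtype=float)
        if u.shape != (d,) or not np.isclose(np.linalg.norm(u), 1.0):
            raise ValueError("direction must be a unit vector of the embedding dimension")

    scores = _draw_scores(cfg, rng)
    eligible = rng.random(cfg.n_participants) < cfg.eligible_fraction
    two_slides = rng.random(cfg.n_participants) < cfg.multi_slide_fraction

    bags: list[EmbeddingBag] = []
    masks: dict[str, RegionMask] = {}
    records: list[CohortRecord] = []
    latent: dict[str, float] = {}
    signal: dict[str, frozenset[int]] = {}

    for i in range(cfg.n_participants):
        pid = f"P{i:04d}"
        r = float(scores[i])
        latent[pid] = r
        n_slides = 2 if two_slides[i] else 1
        slide_ids = []
        for s in range(n_slides):
            sid = f"{pid}-S{s}"
            slide_ids.append(sid)
            n = int(rng.integers(cfg.patches_per_slide[0], cfg.patches_per_slide[1] + 1))
            geom = _slide_geometry(cfg, n)
            grid = compute_patch_grid(geom)
            cells = rng.choice(len(grid), size=n, replace=False)
            coords = np.array([[grid[c].x, grid[c].y] for c in cells], dtype=np.int64)

            frac = rng.uniform(*cfg.tumor_fraction)
            n_tumor = max(1, int(round(frac * n)))
            tumor_idx = rng.choice(n, size=n_tumor, replace=False)

            feats = rng.normal(scale=cfg.noise_sd, size=(n, d))
            feats[tumor_idx] += cfg.signal_strength * r * u

            bags.append(
                EmbeddingBag(
                    slide_id=sid, encoder_id="synthetic", features=feats, coords=coords, geometry=geom
                )
            )
            masks[sid] = RegionMask(slide_id=sid, patch_indices=frozenset(int(t) for t in tumor_idx))
            signal[sid] = frozenset(int(t) for t in tumor_idx)

        rate = cfg.baseline_hazard * np.exp(cfg.log_hazard_per_unit * r)
        t = float(rng.exponential(1.0 / rate))
        event = t <= cfg.censor_horizon
        time = min(t, cfg.censor_horizon)
        records.append(
            CohortRecord(
                participant_id=pid,
                slide_ids=tuple(slide_ids),
                rorp_score=r,
                rorp_group=categorize_rorp(r),
                er_her2_eligible=bool(eligible[i]),
                recurrence_time_years=time,
                recurrence_event=bool(event),
            )
        )

    truth = SyntheticTruth(direction=u, latent_scores=latent, signal_indices=signal, config=cfg)
    return bags, masks, records, truth


def generate_null_cohort(
    config: GeneratorConfig,
) -> tuple[list[EmbeddingBag], dict[str, RegionMask], list[CohortRecord], SyntheticTruth]:
    """Cohort with labels permuted against bags (marginals preserved).

    Two independent permutations are applied: the (score, group) block is
    permuted against the bags, and the survival outcome is permuted against
    the scores.  Every bag-label and score-outcome association is therefore
    destroyed while all marginal distributions are kept — the calibration
    fixture for type-I-error testing of the comparison tests.
    """
    bags, masks, records, truth = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0])
    n = len(records)
    perm_score = rng.permutation(n)
    perm_surv = rng.permutation(n)
    shuffled = []
    for i, rec in enumerate(records):
        src = records[perm_score[i]]
        surv = records[perm_surv[i]]
        shuffled.append(
            replace_record(
                rec,
                rorp_score=src.rorp_score,
                rorp_group=src.rorp_group,
                recurrence_time_years=surv.recurrence_time_years,
                recurrence_event=surv.recurrence_event,
            )
        )
    latent = {rec.participant_id: rec.rorp_score for rec in shuffled}
    truth = SyntheticTruth(
        direction=truth.direction, latent_scores=latent, signal_indices=truth.signal_indices, config=config
    )
    return bags, masks, shuffled, truth


def replace_record(rec: CohortRecord, **kwargs) -> CohortRecord:
    fields = dict(
        participant_id=rec.participant_id,
        slide_ids=rec.slide_ids,
        rorp_score=rec.rorp_score,
        rorp_group=rec.rorp_group,
        er_her2_eligible=rec.er_her2_eligible,
        recurrence_time_years=rec.recurrence_time_years,
        recurrence_event=rec.recurrence_event,
    )
    fields.update(kwargs)
    return CohortRecord(**fields)
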