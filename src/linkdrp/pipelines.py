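"""End-to-end prediction pipelines.

Three algorithms share one contract — raw training/test expression matrices
in, one predicted IC50-scale score per tumor out:

- B (baseline): fit the final learner directly on (D, y), predict on T.
- A1: build paired features for both sets, filter the training rows by the
  distance-weighted relaxed QBC loop, fit on the filtered subset, predict on
  the paired test set.
- A2: as A1, plus leverage-score selection of the top-k feature columns
  (scored on the filtered training subset, applied identically to both sets)
  before the final fit.

Neither A1 nor A2 ever sees test responses or clinical labels; the test set
enters training only through the unlabeled feature geometry of the
distance weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gene_selection, learners, link_filtering, pairing
from .data_io import ExpressionMatrix, ResponseVector, align, check_same_genes
from .learners import LearnerSpec
from .link_filtering import CommitteeSpec, LabeledPool

logger = logging.getLogger(__name__)

ALGORITHMS = ("A1", "A2", "B")


@dataclass
class PipelineConfig:
    """All tunables of the three pipelines, defaulting to the study constants
    (lambda=0.3, k'=1, k''=5, t=3 equal-weight SVR committee, ridge seed)."""

    algorithm: str = "A1"
    final_learner: LearnerSpec = field(default_factory=lambda: LearnerSpec("rr"))
    lam: float = pairing.DEFAULT_LAMBDA
    k_prime: int = pairing.DEFAULT_K_PRIME
    k_doubleprime: int = link_filtering.DEFAULT_K_DOUBLEPRIME
    committee: CommitteeSpec | None = None
    seed_learner: LearnerSpec = field(default_factory=lambda: LearnerSpec("rr"))
    seed_rule: str = "as-written"
    top_k_genes: int | None = None
    cur_rank: int | None = None
    rng_seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; use one of {ALGORITHMS}")
        if self.algorithm == "A2" and self.top_k_genes is None:
            raise ValueError("A2 requires top_k_genes (no silent default)")


def _maybe_standardize(
    train_feat: np.ndarray, test_feat: np.ndarray, enabled: bool
) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return train_feat, test_feat
    mu = train_feat.mean(axis=0)
    sd = train_feat.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (train_feat - mu) / sd, (test_feat - mu) / sd


def _fit_predict(
    spec: LearnerSpec,
    train_feat: np.ndarray,
    train_resp: np.ndarray,
    test_feat: np.ndarray,
    standardize: bool,
) -> np.ndarray:
    train_feat, test_feat = _maybe_standardize(train_feat, test_feat, standardize)
    model = learners.fit(spec, train_feat, train_resp)
    return learners.predict(model, test_feat)


def run_baseline(
    D: ExpressionMatrix, y: ResponseVector, T: ExpressionMatrix, cfg: PipelineConfig
) -> np.ndarray:
    """Direct fit on the raw expression matrix; one prediction per tumor."""
    T = check_same_genes(D, T)
    y = align(D, y)
    return _fit_predict(cfg.final_learner, D.values, y.values, T.values, cfg.standardize)


def _filtered_training(
    D: ExpressionMatrix, y: ResponseVector, T: ExpressionMatrix, cfg: PipelineConfig
) -> tuple[LabeledPool, pairing.PairedSet]:
    """Shared A1/A2 front end: pairing plus link filtering."""
    T = check_same_genes(D, T)
    y = align(D, y)
    rng = np.random.default_rng(cfg.rng_seed)
    G = pairing.build_paired_training(D, y, lam=cfg.lam, k_prime=cfg.k_prime, rng=rng)
    G_prime = pairing.build_paired_test(T, lam=cfg.lam, k_prime=cfg.k_prime, rng=rng)
    S = link_filtering.link_filter(
        G,
        G_prime,
        seed_learner=cfg.seed_learner,
        committee=cfg.committee,
        k_doubleprime=cfg.k_doubleprime,
        seed_rule=cfg.seed_rule,
    )
    logger.info(
        "filtered training set: %d of %d rows, %d paired features",
        len(S), D.n_samples, S.features.shape[1],
    )
    return S, G_prime


def run_a1(
    D: ExpressionMatrix, y: ResponseVector, T: ExpressionMatrix, cfg: PipelineConfig
) -> np.ndarray:
    """Paired features + link filtering, then fit/predict on all 2n columns."""
    S, G_prime = _filtered_training(D, y, T, cfg)
    return _fit_predict(
        cfg.final_learner, S.features, S.responses, G_prime.features, cfg.standardize
    )


def run_a2(
    D: ExpressionMatrix, y: ResponseVector, T: ExpressionMatrix, cfg: PipelineConfig
) -> np.ndarray:
    """A1 plus leverage-score selection of the top-k columns before the fit.

    Scores are computed on the filtered training subset (filtering precedes
    feature selection) and the same column positions are applied to the test
    set.
    """
    if cfg.top_k_genes is None:
        raise ValueError("A2 requires top_k_genes")
    S, G_prime = _filtered_training(D, y, T, cfg)
    if cfg.top_k_genes > S.features.shape[1]:
        raise ValueError(
            f"top_k_genes={cfg.top_k_genes} exceeds the {S.features.shape[1]} "
            "paired feature columns"
        )
    l = cfg.cur_rank or min(S.features.shape[0], S.features.shape[1], 100)
    result = gene_selection.rank_columns(S.features, l=l, k=cfg.top_k_genes)
    S_red, G_red = gene_selection.select_columns(S, G_prime, result.selected)
    logger.info(
        "leverage selection: kept %d of %d columns at rank l=%d",
        len(result.selected), S.features.shape[1], l,
    )
    return _fit_predict(
        cfg.final_learner, S_red.features, S.responses, G_red.features, cfg.standardize
    )


def run(
    D: ExpressionMatrix, y: ResponseVector, T: ExpressionMatrix, cfg: PipelineConfig
) -> np.ndarray:
    """Dispatch on ``cfg.algorithm``."""
    fn = {"A1": run_a1, "A2": run_a2, "B": run_baseline}[cfg.algorithm]
    return fn(D, y, T, cfg)
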