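"""Transductive selection of a better-quality training subset.

Each training cell line (in its paired 2n-dimensional representation) is
weighted by its minimum Euclidean distance to the paired test tumors, so
small weights mean test-proximal cell lines. The weight median splits the
training set into a near half X and a far half Z (median ties land in both).
A ridge seed model trained on each half is scored by its mean squared error
on the opposite half; the half whose model incurred the larger error becomes
the labeled pool S and the other becomes the query pool U. A committee of
three SVRs (linear, degree-5 polynomial, sigmoid; equal weights) then runs a
relaxed query-by-committee loop: k'' times, the U row with the largest
weighted prediction variance across the committee moves — with its known
response — into S. The returned S is the filtered training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import learners
from .learners import LearnerSpec
from .pairing import PairedSet

logger = logging.getLogger(__name__)

DEFAULT_K_DOUBLEPRIME = 5
DEFAULT_SEED_LEARNER = LearnerSpec("rr")


def default_committee() -> "CommitteeSpec":
    return CommitteeSpec(
        members=[
            LearnerSpec("svr-linear"),
            LearnerSpec("svr-poly5"),
            LearnerSpec("svr-sigmoid"),
        ]
    )


@dataclass
class LabeledPool:
    """Paired feature rows with their (known) responses."""

    sample_ids: list[str]
    features: np.ndarray
    responses: np.ndarray

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class Partition:
    """Median split of the weighted training set.

    Rows with weight exactly equal to the median appear in both halves.
    """

    med: float
    x: LabeledPool  # w_i <= med (test-proximal)
    z: LabeledPool  # w_i >= med (test-distal)
    x_indices: np.ndarray
    z_indices: np.ndarray


@dataclass
class SeedAssignment:
    """Outcome of the committee-error seed step: labeled pool S, query pool U."""

    S: LabeledPool
    U: LabeledPool
    j_star: int  # 1 = X-trained side had larger MSE (S = X); 2 = Z side (S = Z)
    per_side_mse: tuple[float, float]


@dataclass
class CommitteeSpec:
    """The QBC committee: member learners and normalized voting weights."""

    members: list[LearnerSpec]
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("committee must have at least one member")
        if self.weights is None:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per committee member required")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"committee weights must sum to 1, got {self.weights.sum()}")


def compute_weights(train_features: np.ndarray, test_features: np.ndarray) -> np.ndarray:
    """Per-training-row minimum Euclidean distance to any test row."""
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if test_features.shape[0] == 0:
        raise ValueError("test set is empty; weights are undefined")
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError(
            f"column mismatch: train has {train_features.shape[1]}, "
            f"test has {test_features.shape[1]}"
        )
    return cdist(train_features, test_features).min(axis=1)


def median_partition(G: PairedSet, w: np.ndarray) -> Partition:
    """Split ``G`` at the median weight (X: w <= med, Z: w >= med)."""
    w = np.asarray(w, dtype=float).ravel()
    if len(w) != G.features.shape[0]:
        raise ValueError("one weight per training row required")
    if G.responses is None:
        raise ValueError("partition requires a training PairedSet with responses")
    med = float(np.median(w))
    x_idx = np.flatnonzero(w <= med)
    z_idx = np.flatnonzero(w >= med)
    ids = np.asarray(G.sample_ids, dtype=object)

    def pool(idx: np.ndarray) -> LabeledPool:
        return LabeledPool(
            sample_ids=list(ids[idx]),
            features=G.features[idx],
            responses=G.responses[idx],
        )

    return Partition(med=med, x=pool(x_idx), z=pool(z_idx), x_indices=x_idx, z_indices=z_idx)


def _check_nondegenerate(pool: LabeledPool, side: str) -> None:
    if pool.features.shape[0] == 0:
        raise ValueError(f"{side} partition is empty")
    if np.ptp(pool.features, axis=0).max(initial=0.0) == 0.0:
        raise ValueError(f"{side} partition has constant features; seed fit is degenerate")


def assign_seed_set(
    part: Partition,
    seed_learner: LearnerSpec = DEFAULT_SEED_LEARNER,
    rule: str = "as-written",
) -> SeedAssignment:
    """Pick S and U by cross-partition seed-model error.

    A seed model (ridge by default) trained on X predicts Z's responses and
    vice versa; each side is scored by its mean squared error over its own
    prediction set. The side with the LARGER error becomes S (ties go to the
    X side). ``rule="inverted"`` flips the assignment so that the
    smaller-error side becomes S.
    """
    if rule not in ("as-written", "inverted"):
        raise ValueError(f"unknown seed rule {rule!r}")
    _check_nondegenerate(part.x, "X")
    _check_nondegenerate(part.z, "Z")
    model_x = learners.fit(seed_learner, part.x.features, part.x.responses)
    v = learners.predict(model_x, part.z.features)  # X-trained, scored on Z
    model_z = learners.fit(seed_learner, part.z.features, part.z.responses)
    b = learners.predict(model_z, part.x.features)  # Z-trained, scored on X
    mse_x_side = float(np.mean((v - part.z.responses) ** 2))
    mse_z_side = float(np.mean((b - part.x.responses) ** 2))
    j_star = 1 if mse_x_side >= mse_z_side else 2
    if rule == "inverted":
        j_star = 3 - j_star
    S, U = (part.x, part.z) if j_star == 1 else (part.z, part.x)
    logger.info(
        "seed assignment: per-side MSE (X-trained=%.4g, Z-trained=%.4g) -> S = %s (|S|=%d)",
        mse_x_side, mse_z_side, "X" if j_star == 1 else "Z", len(S),
    )
    return SeedAssignment(S=S, U=U, j_star=j_star, per_side_mse=(mse_x_side, mse_z_side))


def disagreement_scores(member_predictions: np.ndarray, w_prime: np.ndarray) -> np.ndarray:
    """Weighted prediction variance of the committee, per candidate column.

    ``member_predictions`` is t x m (members x candidates); the score of
    candidate j is sum_i w'_i (pred_ij - f'_j)^2 with f'_j the w'-weighted
    ensemble mean.
    """
    P = np.asarray(member_predictions, dtype=float)
    w = np.asarray(w_prime, dtype=float).ravel()
    if P.ndim != 2 or P.shape[0] != len(w):
        raise ValueError("member_predictions must be t x m with one weight per member")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"committee weights must sum to 1, got {w.sum()}")
    f_prime = w @ P
    return w @ (P - f_prime) ** 2


def qbc_select(
    seed: SeedAssignment,
    committee: CommitteeSpec | None = None,
    k_doubleprime: int = DEFAULT_K_DOUBLEPRIME,
) -> LabeledPool:
    """Relaxed query-by-committee transfer loop.

    k'' times: fit every committee member on the current S, score every row
    of U by the weighted committee disagreement, and move the argmax row
    (ties to lowest index) with its stored response from U to S. Returns the
    grown S; |S_final| = |S_initial| + k''.
    """
    if committee is None:
        committee = default_committee()
    if k_doubleprime < 0:
        raise ValueError("k'' must be nonnegative")
    if k_doubleprime > len(seed.U):
        raise ValueError(
            f"k''={k_doubleprime} exceeds the {len(seed.U)} available query rows"
        )
    s_feat, s_resp = seed.S.features.copy(), seed.S.responses.copy()
    s_ids = list(seed.S.sample_ids)
    u_feat, u_resp = seed.U.features.copy(), seed.U.responses.copy()
    u_ids = list(seed.U.sample_ids)

    for _ in range(k_doubleprime):
        preds = np.vstack(
            [
                learners.predict(learners.fit(m, s_feat, s_resp), u_feat)
                for m in committee.members
            ]
        )
        scores = disagreement_scores(preds, committee.weights)
        j = int(np.argmax(scores))  # ties -> lowest index
        s_feat = np.vstack([s_feat, u_feat[j]])
        s_resp = np.append(s_resp, u_resp[j])
        s_ids.append(u_ids[j])
        u_feat = np.delete(u_feat, j, axis=0)
        u_resp = np.delete(u_resp, j)
        del u_ids[j]

    logger.info("QBC selected %d training rows (%d transferred)", len(s_ids), k_doubleprime)
    return LabeledPool(sample_ids=s_ids, features=s_feat, responses=s_resp)


def link_filter(
    G: PairedSet,
    G_prime: PairedSet,
    seed_learner: LearnerSpec = DEFAULT_SEED_LEARNER,
    committee: CommitteeSpec | None = None,
    k_doubleprime: int = DEFAULT_K_DOUBLEPRIME,
    seed_rule: str = "as-written",
) -> LabeledPool:
    """Full filtering pipeline: weights -> median split -> seed -> QBC loop."""
    w = compute_weights(G.features, G_prime.features)
    part = median_partition(G, w)
    seed = assign_seed_set(part, seed_learner=seed_learner, rule=seed_rule)
    return qbc_select(seed, committee=committee, k_doubleprime=k_doubleprime)
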