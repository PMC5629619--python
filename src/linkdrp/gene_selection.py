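"""Column ranking by CUR-style normalized statistical leverage scores.

The leverage score of column j is the mean of the squared j-th entries of
the top-l right singular vectors of the (filtered, paired) training matrix:
pi_j = (1/l) * sum_{xi<=l} (v_j^xi)^2. Because the right singular vectors
are orthonormal, the scores are nonnegative and sum to one; a high score
marks an influential column. Only the scores and the top-k index set are
computed — the explicit C, U, R factors of a CUR approximation are never
materialized, since column selection consumes only the ranking. The SVD is
the deterministic full decomposition (no randomized sketching), so results
are seed-free.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np


@dataclass
class LeverageResult:
    """Leverage scores over all feature columns plus the selected top-k set."""

    scores: np.ndarray
    rank_l: int
    selected: np.ndarray  # k column indices, descending score, ties to lowest index

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.selected = np.asarray(self.selected, dtype=int).ravel()
        if (self.scores < -1e-12).any():
            raise ValueError("leverage scores must be nonnegative")
        if abs(self.scores.sum() - 1.0) > 1e-9:
            raise ValueError(f"leverage scores must sum to 1, got {self.scores.sum()}")
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def leverage_scores(M: np.ndarray, l: int) -> np.ndarray:
    """Normalized statistical leverage of each column of ``M`` at rank ``l``."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    max_l = min(M.shape)
    if not 1 <= l <= max_l:
        raise ValueError(f"rank l must be in [1, {max_l}], got {l}")
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    numerical_rank = int((s > tol).sum())
    if l > numerical_rank:
        raise ValueError(
            f"l={l} exceeds the numerical rank {numerical_rank} of M; "
            f"use l <= {numerical_rank}"
        )
    return (vt[:l] ** 2).sum(axis=0) / l


def top_k_indexes(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending, ties broken by lowest index."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not 1 <= k <= len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}], got {k}")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:k]


def rank_columns(M: np.ndarray, l: int, k: int) -> LeverageResult:
    """Convenience: leverage scores plus the top-k index set in one call."""
    scores = leverage_scores(M, l)
    return LeverageResult(scores=scores, rank_l=l, selected=top_k_indexes(scores, k))


def select_columns(train, test, I: np.ndarray):
    """Restrict train and test to columns ``I`` in the same order.

    Accepts any pair of feature containers (:class:`~linkdrp.pairing.PairedSet`
    or the filtered training pool) exposing ``features``. Column identity is
    preserved pairwise: position r of both outputs comes from the same source
    column I[r]. Responses are untouched. The outputs are no longer 2n-wide
    paired representations.
    """
    if train.features.shape[1] != test.features.shape[1]:
        raise ValueError(
            f"column-count mismatch: train {train.features.shape[1]}, "
            f"test {test.features.shape[1]}"
        )
    I = np.asarray(I, dtype=int).ravel()
    if I.size and (I.min() < 0 or I.max() >= train.features.shape[1]):
        raise ValueError("column index out of range")

    def cut(ps):
        out = copy.copy(ps)
        out.features = ps.features[:, I].copy()
        return out

    return cut(train), cut(test)
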