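"""Paired (original, synthetic) feature construction.

Each sample is re-represented as the concatenation of its own expression
profile with a synthetic profile interpolated a fraction ``lam`` of the way
toward one of its k' nearest neighbors (Euclidean metric) within the same
set. This doubles the feature dimensionality — from n to 2n — rather than
the sample count as SMOTE-style oversampling would. Training rows keep their
response value; the synthetic partner shares it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import ExpressionMatrix, ResponseVector

DEFAULT_LAMBDA = 0.3
DEFAULT_K_PRIME = 1


@dataclass
class PairedSet:
    """Doubled-feature representation of a training or test set.

    ``features`` has 2n columns: the first n are the original profile, the
    last n the synthetic interpolated partner. ``responses`` is present only
    when built from a training set.
    """

    sample_ids: list[str]
    features: np.ndarray
    responses: np.ndarray | None
    lambda_used: float
    k_prime_used: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.responses is not None:
            self.responses = np.asarray(self.responses, dtype=float).ravel()
            if len(self.responses) != self.features.shape[0]:
                raise ValueError("responses length does not match feature rows")
        if self.features.shape[0] != len(self.sample_ids):
            raise ValueError("feature rows do not match sample_ids")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def nearest_neighbor_index(M: np.ndarray, row: int, k_prime: int = 1) -> list[int]:
    """Indices of the k' Euclidean nearest neighbors of ``M[row]`` in ``M``.

    The query row itself is excluded; distance ties break toward the lowest
    index, making the search fully deterministic.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < k_prime + 1:
        raise ValueError(
            f"need at least {k_prime + 1} rows for {k_prime} neighbors, got {M.shape[0]}"
        )
    d = np.linalg.norm(M - M[row], axis=1)
    order = np.lexsort((np.arange(len(d)), d))  # by distance, then index
    order = order[order != row]
    return order[:k_prime].tolist()


def interpolate(g_i: np.ndarray, g_star: np.ndarray, lam: float) -> np.ndarray:
    """Point a fraction ``lam`` along the segment from ``g_i`` to ``g_star``."""
    g_i = np.asarray(g_i, dtype=float)
    g_star = np.asarray(g_star, dtype=float)
    if g_i.shape != g_star.shape:
        raise ValueError(f"length mismatch: {g_i.shape} vs {g_star.shape}")
    return g_i + (g_star - g_i) * lam


def _neighbor_table(M: np.ndarray, k_prime: int) -> np.ndarray:
    """All-rows k'-NN indices (self excluded, ties to lowest index); (p, k')."""
    p = M.shape[0]
    if p < k_prime + 1:
        raise ValueError(f"need at least {k_prime + 1} rows, got {p}")
    d = cdist(M, M)
    np.fill_diagonal(d, np.inf)
    # lexsort per row: distance ascending, index ascending on ties
    idx = np.arange(p)
    out = np.empty((p, k_prime), dtype=int)
    for i in range(p):
        order = np.lexsort((idx, d[i]))
        out[i] = order[:k_prime]
    return out


def _synthetic_partners(
    M: np.ndarray, lam: float, k_prime: int, rng: np.random.Generator | None
) -> np.ndarray:
    nn = _neighbor_table(M, k_prime)
    if k_prime == 1:
        partner = nn[:, 0]
    else:
        # one partner per row, drawn uniformly from its k' nearest neighbors
        if rng is None:
            rng = np.random.default_rng(0)
        partner = nn[np.arange(M.shape[0]), rng.integers(0, k_prime, M.shape[0])]
    return interpolate(M, M[partner], lam)


def build_paired_training(
    D: ExpressionMatrix,
    y: ResponseVector,
    lam: float = DEFAULT_LAMBDA,
    k_prime: int = DEFAULT_K_PRIME,
    rng: np.random.Generator | None = None,
) -> PairedSet:
    """Paired training representation: p rows, 2n feature columns, responses kept.

    ``y`` must already be row-aligned with ``D``. With the default k'=1 the
    construction is deterministic; for k'>1 the partner is drawn uniformly
    from the k' nearest neighbors under ``rng``.
    """
    if D.sample_ids != y.sample_ids:
        raise ValueError("D and y are not aligned; call data_io.align first")
    synth = _synthetic_partners(D.values, lam, k_prime, rng)
    return PairedSet(
        sample_ids=list(D.sample_ids),
        features=np.hstack([D.values, synth]),
        responses=y.values.copy(),
        lambda_used=lam,
        k_prime_used=k_prime,
    )


def build_paired_test(
    T: ExpressionMatrix,
    lam: float = DEFAULT_LAMBDA,
    k_prime: int = DEFAULT_K_PRIME,
    rng: np.random.Generator | None = None,
) -> PairedSet:
    """Paired test representation: q rows, 2n columns, no responses.

    Neighbors are searched within the test set itself, so tumors pair with
    tumors.
    """
    synth = _synthetic_partners(T.values, lam, k_prime, rng)
    return PairedSet(
        sample_ids=list(T.sample_ids),
        features=np.hstack([T.values, synth]),
        responses=None,
        lambda_used=lam,
        k_prime_used=k_prime,
    )
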