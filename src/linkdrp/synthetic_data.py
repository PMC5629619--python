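"""Seeded synthetic cell-line / tumor datasets with the structure the method assumes.

Expression features are i.i.d. standard normal (continuous features make the
minimum-distance weights pairwise distinct almost surely); the continuous
response is a sparse linear function of a few informative genes plus
Gaussian noise; test tumors are drawn from the same generative model and
their binary clinical label thresholds the same latent response at a chosen
quantile. Defaults mirror a breast-cancer-trial-sized cohort (482 cell
lines, 24 tumors) at desk scale (50 genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ClinicalLabels, ExpressionMatrix, ResponseVector


@dataclass
class SyntheticSpec:
    """Generator settings.

    ``effect_sizes`` is either a scalar scale for Normal(0, scale) coefficient
    draws or an explicit vector of length ``n_informative``.
    ``label_threshold`` is the quantile of the tumors' latent response above
    which a tumor is labeled resistant (1).
    """

    p: int = 482
    q: int = 24
    n: int = 50
    n_informative: int = 10
    effect_sizes: float | np.ndarray = 1.0
    noise_sd: float = 1.0
    label_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2 or self.q < 2:
            raise ValueError("p and q must each be >= 2")
        if not 0 < self.n_informative <= self.n:
            raise ValueError("need 0 < n_informative <= n")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.label_threshold < 1:
            raise ValueError("label_threshold must be a quantile in (0, 1)")


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ResponseVector, ExpressionMatrix, ClinicalLabels, dict]:
    """Draw (D, y, T, labels, truth) under ``spec``.

    ``truth`` records the informative gene indices, the full coefficient
    vector and the tumors' latent responses, for recovery tests and oracle
    scoring.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"g{j}" for j in range(spec.n)]
    train_ids = [f"cell{i}" for i in range(spec.p)]
    test_ids = [f"tumor{i}" for i in range(spec.q)]

    X = rng.standard_normal((spec.p, spec.n))
    informative = np.sort(rng.choice(spec.n, size=spec.n_informative, replace=False))
    beta = np.zeros(spec.n)
    if np.isscalar(spec.effect_sizes):
        coefs = rng.normal(0.0, float(spec.effect_sizes), size=spec.n_informative)
    else:
        coefs = np.asarray(spec.effect_sizes, dtype=float).ravel()
        if len(coefs) != spec.n_informative:
            raise ValueError("effect_sizes vector must have length n_informative")
    beta[informative] = coefs
    y = X @ beta + rng.normal(0.0, spec.noise_sd, size=spec.p)

    Xt = rng.standard_normal((spec.q, spec.n))
    latent = Xt @ beta + rng.normal(0.0, spec.noise_sd, size=spec.q)
    labels = (latent > np.quantile(latent, spec.label_threshold)).astype(int)

    D = ExpressionMatrix(train_ids, genes, X)
    T = ExpressionMatrix(test_ids, genes, Xt)
    truth = {"informative": informative, "beta": beta, "latent": latent}
    return (
        D,
        ResponseVector(train_ids, y),
        T,
        ClinicalLabels(test_ids, labels),
        truth,
    )


def make_fixture(name: str):
    """Deterministic tiny datasets for unit tests.

    - ``"tiny-linear"``: 8 train / 4 test rows, 4 genes, response exactly
      linear in gene 0 (no noise).
    - ``"tied-weights"``: training rows duplicated pairwise so the
      minimum-distance weights tie, exercising the median-partition overlap.
    - ``"planted-columns"``: 40 samples, 20 high-variance signal genes
      followed by 80 near-null genes, for leverage-recovery tests.
    """
    if name == "tiny-linear":
        rng = np.random.default_rng(11)
        X = rng.standard_normal((8, 4))
        Xt = rng.standard_normal((4, 4))
        genes = [f"g{j}" for j in range(4)]
        D = ExpressionMatrix([f"c{i}" for i in range(8)], genes, X)
        T = ExpressionMatrix([f"t{i}" for i in range(4)], genes, Xt)
        y = ResponseVector(D.sample_ids, 2.0 * X[:, 0])
        labels = ClinicalLabels(T.sample_ids, (Xt[:, 0] > np.median(Xt[:, 0])).astype(int))
        return {"D": D, "y": y, "T": T, "labels": labels, "beta": np.array([2.0, 0, 0, 0])}
    if name == "tied-weights":
        rng = np.random.default_rng(23)
        base = rng.standard_normal((3, 3))
        X = np.repeat(base, 2, axis=0)  # each row appears twice -> tied weights
        Xt = rng.standard_normal((3, 3))
        genes = [f"g{j}" for j in range(3)]
        D = ExpressionMatrix([f"c{i}" for i in range(6)], genes, X)
        T = ExpressionMatrix([f"t{i}" for i in range(3)], genes, Xt)
        y = ResponseVector(D.sample_ids, rng.standard_normal(6))
        return {"D": D, "y": y, "T": T}
    if name == "planted-columns":
        rng = np.random.default_rng(37)
        signal = rng.normal(0.0, 3.0, size=(40, 20))
        null = rng.normal(0.0, 0.1, size=(40, 80))
        X = np.hstack([signal, null])
        genes = [f"g{j}" for j in range(100)]
        D = ExpressionMatrix([f"c{i}" for i in range(40)], genes, X)
        return {"D": D, "signal_columns": np.arange(20)}
    raise ValueError(f"unknown fixture {name!r}")
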