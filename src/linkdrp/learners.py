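"""Uniform fit/predict contract over the regression families used throughout.

Four families: ridge regression ("rr") and epsilon-SVR with linear, sigmoid
and degree-5 polynomial kernels ("svr-linear", "svr-sigmoid", "svr-poly5"),
backed by scikit-learn (libsvm for the SVRs). Hyperparameter defaults follow
libsvm conventions: C=1, epsilon=0.1, gamma = 1/n_features, coef0=0; ridge
penalizes coefficients only (unpenalized intercept) with alpha=1. No internal
tuning or cross-validation is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

FAMILIES = ("rr", "svr-linear", "svr-sigmoid", "svr-poly5")

_SVR_KERNEL = {"svr-linear": "linear", "svr-sigmoid": "sigmoid", "svr-poly5": "poly"}


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus hyperparameter overrides.

    Ridge accepts ``alpha``; the SVRs accept ``C``, ``epsilon``, ``gamma``
    and ``coef0`` (degree is fixed at 5 for the polynomial kernel).
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; use one of {FAMILIES}")
        object.__setattr__(self, "params", MappingProxyType(dict(self.params)))
        if self.family == "rr":
            if self.params.get("alpha", 1.0) <= 0:
                raise ValueError("ridge alpha must be > 0")
        else:
            if self.params.get("C", 1.0) <= 0:
                raise ValueError("SVR cost C must be > 0")
            if self.params.get("epsilon", 0.1) < 0:
                raise ValueError("SVR epsilon must be >= 0")


def parse_spec(text: str) -> LearnerSpec:
    """Parse a CLI spec string like ``"rr"`` or ``"rr:alpha=0.5"``.

    Multiple overrides are comma-separated: ``"svr-linear:C=2,epsilon=0.05"``.
    """
    family, _, tail = text.partition(":")
    params: dict[str, float] = {}
    if tail:
        for item in tail.split(","):
            key, _, value = item.partition("=")
            if not value:
                raise ValueError(f"malformed hyperparameter override {item!r}")
            params[key.strip()] = float(value)
    return LearnerSpec(family=family.strip(), params=params)


@dataclass
class FittedModel:
    """A trained learner; ``predict`` only accepts ``n_features``-wide input."""

    spec: LearnerSpec
    estimator: object
    n_features: int


def _build_estimator(spec: LearnerSpec, n_features: int):
    p = dict(spec.params)
    if spec.family == "rr":
        return Ridge(alpha=p.get("alpha", 1.0), fit_intercept=True)
    gamma = p.get("gamma", 1.0 / n_features)
    return SVR(
        kernel=_SVR_KERNEL[spec.family],
        C=p.get("C", 1.0),
        epsilon=p.get("epsilon", 0.1),
        gamma=gamma,
        coef0=p.get("coef0", 0.0),
        degree=5,
        tol=p.get("tol", 1e-3),
        cache_size=200,
    )


def fit(spec: LearnerSpec, features: np.ndarray, targets: np.ndarray) -> FittedModel:
    """Train ``spec`` on (features, targets). Deterministic for fixed input."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if X.shape[0] != len(y):
        raise ValueError(f"{X.shape[0]} feature rows but {len(y)} targets")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    est = _build_estimator(spec, X.shape[1])
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1])


def predict(model: FittedModel, features: np.ndarray) -> np.ndarray:
    """One finite prediction per input row."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected matrix with {model.n_features} columns, got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    return np.asarray(model.estimator.predict(X), dtype=float)
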