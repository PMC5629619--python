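"""Evaluation protocol: AUC/MAUC, training-size reduction runs, paired tests.

Predicted scores are on the IC50 scale, so the resistant/non-responder class
(label 1) is expected to score higher; AUC is the Mann-Whitney probability
that a random positive outranks a random negative, with half credit for
ties. MAUC averages AUCs over a schedule of nested, randomly reduced
training sets. Algorithms are compared pairwise by a two-tailed Wilcoxon
signed-rank test on their per-run AUCs, and predicted scores of the two
clinical groups by a two-sample t-test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy import stats

from .data_io import ClinicalLabels, ExpressionMatrix, ResponseVector


@dataclass
class ReductionSchedule:
    """Strictly decreasing training-set sizes; first entry is the full size."""

    sizes: tuple[int, ...]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if not self.sizes:
            raise ValueError("schedule must contain at least one size")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if any(b >= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError(f"sizes must be strictly decreasing, got {self.sizes}")


@dataclass
class EvalReport:
    """Per-run AUCs plus summary statistics, one report per benchmark."""

    per_run: list[tuple[int, float]]
    mauc: float
    group_ttest_p: float | None = None
    pairwise_wilcoxon: dict[str, float] | None = field(default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_run": [{"training_size": m, "auc": a} for m, a in self.per_run],
            "mauc": self.mauc,
            "group_ttest_p": self.group_ttest_p,
            "pairwise_wilcoxon": self.pairwise_wilcoxon,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def mauc(aucs) -> float:
    """Arithmetic mean of per-run AUC values."""
    aucs = np.asarray(aucs, dtype=float).ravel()
    if aucs.size == 0:
        raise ValueError("cannot average an empty AUC vector")
    return float(aucs.mean())


def reduction_runs(
    D: ExpressionMatrix, y: ResponseVector, schedule: ReductionSchedule
) -> list[tuple[ExpressionMatrix, ResponseVector]]:
    """Nested random training subsets at the scheduled sizes.

    Each run's samples are a subset of the previous run's; removal is uniform
    at random under the schedule's seed; the first run is the full set.
    """
    p = D.n_samples
    if schedule.sizes[0] != p:
        raise ValueError(
            f"first schedule size {schedule.sizes[0]} must equal the full training size {p}"
        )
    rng = np.random.default_rng(schedule.rng_seed)
    ids = np.asarray(D.sample_ids, dtype=object)
    keep = np.arange(p)
    runs = []
    for size in schedule.sizes:
        if size < len(keep):
            drop = rng.choice(len(keep), size=len(keep) - size, replace=False)
            keep = np.delete(keep, drop)
        runs.append(
            (
                ExpressionMatrix(list(ids[keep]), list(D.gene_ids), D.values[keep]),
                ResponseVector(list(ids[keep]), y.values[keep]),
            )
        )
    return runs


def wilcoxon_signed_rank(a, b, method: str = "approx") -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples a, b.

    Zero differences are dropped; absolute differences get midranks. Methods:

    - ``"approx"`` (default): plain normal approximation of the positive-rank
      sum — no continuity correction and no tie variance adjustment.
    - ``"approx-cc"``: normal approximation with a 0.5 continuity correction.
    - ``"exact"``: full enumeration of all sign patterns (n <= ~20).

    If every difference is zero the pairing is degenerate; p = 1 is returned
    with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p set to 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 pairs")
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p = 2.0 * min((sums >= w_plus).mean(), (sums <= w_plus).mean())
        return float(min(p, 1.0))
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    delta = abs(w_plus - mu)
    if method == "approx-cc":
        delta = max(delta - 0.5, 0.0)
    elif method != "approx":
        raise ValueError(f"unknown method {method!r}")
    z = delta / sigma
    return float(min(2.0 * stats.norm.sf(z), 1.0))


def group_ttest(predictions, labels, equal_var: bool = False) -> float:
    """Two-tailed two-sample t-test between the two clinical groups' scores.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance Student's test.
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    g0 = predictions[labels == 0]
    g1 = predictions[labels == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each clinical group needs at least 2 members")
    return float(stats.ttest_ind(g1, g0, equal_var=equal_var).pvalue)


def pairwise_wilcoxon(
    per_algorithm_aucs: dict[str, np.ndarray], method: str = "approx"
) -> dict[tuple[str, str], float]:
    """All-pairs signed-rank p-values over pooled per-run AUC vectors."""
    names = list(per_algorithm_aucs)
    out: dict[tuple[str, str], float] = {}
    for i, j in product(range(len(names)), repeat=2):
        if i < j:
            out[(names[i], names[j])] = wilcoxon_signed_rank(
                per_algorithm_aucs[names[i]], per_algorithm_aucs[names[j]], method=method
            )
    return out
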