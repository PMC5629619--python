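"""Benchmark harness: algorithms x learners x reduction runs -> AUC tables.

Reproduces the shape of the study's result tables: for each training-size
run, every (algorithm, final learner) combination is trained and scored on
the fixed test cohort; per-run AUCs, their mean (MAUC) and all-pairs
two-tailed Wilcoxon signed-rank p-values over the pooled runs are reported.
Pairing and link filtering are computed once per run and shared across the
final learners, which does not change any result (the filter ignores the
final learner) but avoids redundant QBC loops.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import evaluation, gene_selection, pipelines
from .data_io import ClinicalLabels, ExpressionMatrix, ResponseVector, align
from .learners import LearnerSpec
from .pipelines import PipelineConfig, _filtered_training, _fit_predict

_ABBREV = {"rr": "RR", "svr-linear": "SVR+L", "svr-sigmoid": "SVR+S", "svr-poly5": "SVR+P5"}


def combo_name(algorithm: str, learner: LearnerSpec) -> str:
    return f"{algorithm}+{_ABBREV.get(learner.family, learner.family)}"


@dataclass
class BenchmarkResult:
    """Per-run AUC table plus MAUCs and pairwise Wilcoxon p-values."""

    auc_table: pd.DataFrame  # rows = combos, columns = training sizes, + MAUC
    pairwise_p: pd.DataFrame  # symmetric matrix of two-tailed p-values
    training_sizes: tuple[int, ...]

    def write(self, table_path, pairwise_path, delimiter: str = "\t") -> None:
        self.auc_table.to_csv(table_path, sep=delimiter, float_format="%.4f")
        self.pairwise_p.to_csv(pairwise_path, sep=delimiter, float_format="%.4g")


def run_benchmark(
    D: ExpressionMatrix,
    y: ResponseVector,
    T: ExpressionMatrix,
    labels: ClinicalLabels,
    schedule: evaluation.ReductionSchedule,
    algorithms: tuple[str, ...] = ("A1", "A2", "B"),
    learners_specs: tuple[LearnerSpec, ...] = (
        LearnerSpec("svr-linear"),
        LearnerSpec("svr-sigmoid"),
        LearnerSpec("rr"),
    ),
    cfg: PipelineConfig | None = None,
    wilcoxon_method: str = "approx",
) -> BenchmarkResult:
    """Evaluate every (algorithm, learner) combo over the reduction schedule."""
    if cfg is None:
        cfg = PipelineConfig(algorithm="A1", top_k_genes=None)
    if "A2" in algorithms and cfg.top_k_genes is None:
        raise ValueError("benchmark with A2 requires cfg.top_k_genes")
    labels = align(T, labels)
    runs = evaluation.reduction_runs(D, y, schedule)
    combos = [(a, ls) for a in algorithms for ls in learners_specs]
    aucs: dict[str, list[float]] = {combo_name(a, ls): [] for a, ls in combos}

    for D_run, y_run in runs:
        filtered = None
        if "A1" in algorithms or "A2" in algorithms:
            filtered = _filtered_training(D_run, y_run, T, cfg)
        for a, ls in combos:
            if a == "B":
                preds = pipelines.run_baseline(
                    D_run, y_run, T, replace(cfg, algorithm="B", final_learner=ls)
                )
            else:
                S, G_prime = filtered
                if a == "A2":
                    l = cfg.cur_rank or min(S.features.shape[0], S.features.shape[1], 100)
                    res = gene_selection.rank_columns(S.features, l=l, k=cfg.top_k_genes)
                    S_fit, G_fit = gene_selection.select_columns(S, G_prime, res.selected)
                else:
                    S_fit, G_fit = S, G_prime
                preds = _fit_predict(
                    ls, S_fit.features, S.responses, G_fit.features, cfg.standardize
                )
            aucs[combo_name(a, ls)].append(evaluation.auc(preds, labels.labels))

    names = list(aucs)
    table = pd.DataFrame(
        {str(m): [aucs[nm][i] for nm in names] for i, m in enumerate(schedule.sizes)},
        index=names,
    )
    table["MAUC"] = [evaluation.mauc(aucs[nm]) for nm in names]
    pair = evaluation.pairwise_wilcoxon(
        {nm: np.asarray(aucs[nm]) for nm in names}, method=wilcoxon_method
    )
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for (i, j), p in pair.items():
        pmat.loc[i, j] = p
        pmat.loc[j, i] = p
    return BenchmarkResult(auc_table=table, pairwise_p=pmat, training_sizes=schedule.sizes)
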