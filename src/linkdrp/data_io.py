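"""Reading, writing and alignment of expression matrices, drug responses and labels.

The on-disk format is a delimited text table (TSV by default, CSV by flag):
expression matrices carry a header row of gene identifiers and a first column
of sample identifiers; response vectors and clinical labels are two-column
files (sample id, value). Matrices must be complete — missing values are
rejected rather than imputed, since the method assumes fully homogenized
expression data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, duplicates)."""


class AlignmentError(ValueError):
    """Sample or gene identifier sets do not match between companion inputs."""


@dataclass
class ExpressionMatrix:
    """Samples x genes real matrix on a log-intensity-like scale.

    Rows are cell lines (training) or tumors (test); columns are genes.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseVector:
    """Continuous drug responses (IC50 scale), one per training sample."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.sample_ids):
            raise ValueError("response length does not match sample_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("response vector contains non-finite values")


@dataclass
class ClinicalLabels:
    """Binary clinical outcome per tumor: 1 = resistant/non-responder, 0 = sensitive.

    ``categories`` optionally keeps a fine-grained response class per sample
    (e.g. CR/PR/MR/NC/PD for bortezomib trials).
    """

    sample_ids: list[str]
    labels: np.ndarray
    categories: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match sample_ids")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        if self.categories is not None and len(self.categories) != len(self.labels):
            raise ValueError("categories length does not match labels")


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, keep_default_na=False, dtype=str
        )
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    return df


def _to_float(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    try:
        # numpy's parser is correctly rounded, so written files round-trip
        return df.to_numpy(dtype=str).astype(float)
    except ValueError:
        bad = df.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"sample {df.index[i]!r}, column {df.columns[j]!r}"
        ) from None


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Parse a delimited samples x genes table.

    First row holds gene identifiers, first column sample identifiers.
    Ragged rows and non-numeric cells (including literal ``NA``) raise
    :class:`ParseError` naming the offending line or cell.
    """
    df = _read_table(path, delimiter)
    values = _to_float(df, path)
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=values,
    )


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    # default str() formatting is the shortest round-tripping repr
    df.to_csv(path, sep=delimiter)


def read_response_vector(path: str | Path, delimiter: str = "\t") -> ResponseVector:
    """Parse a two-column (sample id, IC50) file. Duplicate ids are rejected."""
    df = _read_table(path, delimiter)
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected exactly 2 columns, got {df.shape[1] + 1}")
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    values = _to_float(df, path).ravel()
    return ResponseVector(sample_ids=ids, values=values)


def write_predictions(
    sample_ids: Sequence[str],
    predictions: np.ndarray,
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write per-tumor predicted responses as a two-column table."""
    pd.Series(np.asarray(predictions, dtype=float), index=list(sample_ids)).to_csv(
        path, sep=delimiter, header=["prediction"], index_label="sample"
    )


def read_clinical_labels(path: str | Path, delimiter: str = "\t") -> ClinicalLabels:
    """Parse a two- or three-column (sample id, binary label[, category]) file."""
    df = _read_table(path, delimiter)
    if df.shape[1] not in (1, 2):
        raise ParseError(f"{path}: expected 2 or 3 columns, got {df.shape[1] + 1}")
    ids = [str(s) for s in df.index]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    labels = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if labels.isna().any():
        bad = df.index[labels.isna()][0]
        raise ParseError(f"{path}: non-numeric label for sample {bad!r}")
    categories = [str(c) for c in df.iloc[:, 1]] if df.shape[1] == 2 else None
    return ClinicalLabels(sample_ids=ids, labels=labels.to_numpy(), categories=categories)


def align(
    expr: ExpressionMatrix, aux: ResponseVector | ClinicalLabels
) -> ResponseVector | ClinicalLabels:
    """Reorder ``aux`` to the row order of ``expr``.

    The two sample-id sets must coincide exactly; anything missing on either
    side raises :class:`AlignmentError` listing the offending identifiers.
    Idempotent: aligning an already-aligned companion returns an equal object.
    """
    expr_ids, aux_ids = set(expr.sample_ids), set(aux.sample_ids)
    if expr_ids != aux_ids:
        missing = sorted(expr_ids - aux_ids)
        extra = sorted(aux_ids - expr_ids)
        parts = []
        if missing:
            parts.append(f"missing from companion: {missing}")
        if extra:
            parts.append(f"unknown to expression matrix: {extra}")
        raise AlignmentError("sample id mismatch — " + "; ".join(parts))
    pos = {s: i for i, s in enumerate(aux.sample_ids)}
    order = [pos[s] for s in expr.sample_ids]
    if isinstance(aux, ResponseVector):
        return ResponseVector(list(expr.sample_ids), aux.values[order])
    return ClinicalLabels(
        list(expr.sample_ids),
        aux.labels[order],
        None if aux.categories is None else [aux.categories[i] for i in order],
    )


def check_same_genes(
    train: ExpressionMatrix, test: ExpressionMatrix, reorder: bool = False
) -> ExpressionMatrix:
    """Require identical gene sets between train and test.

    By default the gene *order* must also match and mismatches raise; with
    ``reorder=True`` the test matrix is reordered to the training gene order.
    """
    if train.gene_ids == test.gene_ids:
        return test
    if set(train.gene_ids) != set(test.gene_ids):
        missing = sorted(set(train.gene_ids) ^ set(test.gene_ids))
        raise AlignmentError(f"gene sets differ between train and test: {missing[:10]}")
    if not reorder:
        raise AlignmentError(
            "gene order differs between train and test; pass reorder=True to permute"
        )
    pos = {g: j for j, g in enumerate(test.gene_ids)}
    order = [pos[g] for g in train.gene_ids]
    return ExpressionMatrix(
        list(test.sample_ids), list(train.gene_ids), test.values[:, order]
    )
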