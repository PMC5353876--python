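"""Expression-matrix preprocessing: quantile normalization and collapsing of
duplicate gene rows."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

COLLAPSE_METHODS = ("mean", "max")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to share one reference value distribution.

    The reference distribution is the per-rank mean of the column-sorted
    matrix.  Within each column, values keep their ranks; tied values receive
    the mean of the reference values at their tied ranks ("average ties"),
    which makes the transform deterministic and idempotent.
    """
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference values across tied input positions
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return ExpressionMatrix(
        matrix.gene_ids,
        matrix.time_labels,
        out,
        allow_duplicate_genes=matrix.allow_duplicate_genes,
    )


def collapse_duplicate_genes(matrix: ExpressionMatrix, method: str = "mean") -> ExpressionMatrix:
    """Combine repeated gene rows column-wise; output gene order is
    first-occurrence order."""
    if method not in COLLAPSE_METHODS:
        raise ValueError(f"unknown collapse method {method!r}; expected one of {COLLAPSE_METHODS}")
    seen: dict[str, list[int]] = {}
    for i, g in enumerate(matrix.gene_ids):
        seen.setdefault(g, []).append(i)
    reducer = np.mean if method == "mean" else np.max
    gene_ids = tuple(seen)
    values = np.vstack([reducer(matrix.values[rows, :], axis=0) for rows in seen.values()])
    return ExpressionMatrix(gene_ids, matrix.time_labels, values)
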