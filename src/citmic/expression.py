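"""Cohort expression-matrix I/O and gene filtering.

Matrices are genes x samples (rows = gene symbols, columns = sample ids)
on a non-negative log-like scale such as log2(TPM+1) or log2(FPKM+1);
normalisation itself is upstream of this package. The in-memory container
is a plain :class:`pandas.DataFrame` validated by :func:`validate_expression`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "validate_expression",
    "filter_genes_by_prevalence",
]


class ExpressionValidationError(ValueError):
    pass


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract.

    Requires: at least one gene and one sample, unique gene symbols and
    sample ids, all values finite and >= 0. Returns the frame unchanged.
    """
    if expr.shape[0] < 1 or expr.shape[1] < 1:
        raise ExpressionValidationError("expression matrix must be non-empty")
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicate gene symbols: {dups[:5]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ExpressionValidationError("expression values must be numeric")
    if not np.isfinite(values).all():
        raise ExpressionValidationError("expression contains NaN/inf values")
    if (values < 0).any():
        raise ExpressionValidationError(
            "negative expression values found; supply log-normalized "
            "non-negative values such as log2(TPM+1)"
        )
    return expr


def read_expression(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a dense genes x samples expression table (TSV/CSV, gzip ok).

    First column holds gene symbols, the header row sample ids. Duplicate
    gene rows are collapsed deterministically by keeping the row with the
    highest mean expression. Non-numeric cells raise a parse error naming
    the offending gene and sample; negative values raise a validation error.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.name.rstrip(".gz").endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False)
    raw = raw.replace("", np.nan)
    if raw.shape[1] == 0:
        raise ExpressionValidationError(f"{path}: no sample columns found")
    expr = raw.apply(pd.to_numeric, errors="coerce")
    bad = expr.isna() & raw.notna()
    allna = raw.isna()
    if bad.to_numpy().any() or allna.to_numpy().any():
        mask = (bad | allna).to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ExpressionValidationError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    expr = expr.astype(float)
    if expr.index.duplicated().any():
        # keep, per duplicated symbol, the row with the highest mean
        means = expr.mean(axis=1).to_numpy()
        order = np.lexsort((-means, expr.index.to_numpy()))
        keep = np.zeros(len(expr), dtype=bool)
        seen: set = set()
        for pos in order:
            g = expr.index[pos]
            if g not in seen:
                seen.add(g)
                keep[pos] = True
        expr = expr.loc[keep]
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a genes x samples table mirroring :func:`read_expression`'s dialect."""
    expr.to_csv(path, sep=delimiter, index_label="gene")


def filter_genes_by_prevalence(expr: pd.DataFrame,
                               min_fraction: float = 0.5,
                               expressed_threshold: float = 0.0) -> pd.DataFrame:
    """Keep genes expressed (value > threshold) in at least ``min_fraction``
    of samples.

    Defaults retain genes expressed in at least 50% of samples with
    "expressed" meaning strictly positive on the provided log scale. With a
    single sample the filter degenerates to ``gene > threshold``, which is
    allowed (the per-sample network needs no cohort). Idempotent and
    order-preserving; never alters the sample set.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    validate_expression(expr)
    frac = (expr.to_numpy() > expressed_threshold).mean(axis=1)
    out = expr.loc[frac >= min_fraction]
    if out.shape[0] == 0:
        raise ExpressionValidationError(
            f"no gene is expressed (> {expressed_threshold}) in at least "
            f"{min_fraction:.0%} of samples"
        )
    return out
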