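"""Column normalization of expression matrices.

Two modes are supported, mirroring the choices the deconvolution
algorithm exposes:

* quantile normalization — every column is forced onto the common
  distribution given by the across-column mean of the per-rank order
  statistics; robust against single outlier measurements shifting a
  whole profile;
* global-mean normalization — every column is rescaled so its mean
  equals the grand mean of the matrix (multiplicative on the linear
  intensity scale, additive on the log scale).
"""

from __future__ import annotations

import numpy as np

from .matrices import ExpressionMatrix, ValidationError

__all__ = [
    "quantile_normalize",
    "global_mean_normalize",
    "quantile_normalize_values",
    "global_mean_normalize_values",
]


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D array.

    After the call every column holds the same multiset of values (the
    mean of the sorted columns), placed according to the original
    within-column ranks.  Ties are broken by (stable) original position.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValidationError("quantile normalization expects a 2-D matrix")
    if V.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 columns")
    order = np.argsort(V, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(V, order, axis=0)
    mean_stats = sorted_vals.mean(axis=1)
    out = np.empty_like(V)
    np.put_along_axis(out, order, mean_stats[:, None], axis=0)
    return out


def global_mean_normalize_values(values: np.ndarray, additive: bool = False) -> np.ndarray:
    """Rescale every column so its mean equals the grand mean.

    ``additive=False`` multiplies each column by grand_mean/column_mean
    (linear intensities); ``additive=True`` shifts each column by
    grand_mean - column_mean (log intensities).
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValidationError("global-mean normalization expects a 2-D matrix")
    grand = V.mean()
    col_means = V.mean(axis=0)
    if additive:
        return V + (grand - col_means)[None, :]
    if np.any(col_means == 0):
        j = int(np.flatnonzero(col_means == 0)[0])
        raise ValidationError(f"column {j} has zero mean; cannot rescale on the linear scale")
    return V * (grand / col_means)[None, :]


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an :class:`ExpressionMatrix` across samples."""
    return ExpressionMatrix(
        quantile_normalize_values(X.values), list(X.gene_ids), list(X.sample_ids)
    )


def global_mean_normalize(X: ExpressionMatrix, additive: bool = False) -> ExpressionMatrix:
    """Global-mean normalize an :class:`ExpressionMatrix` across samples."""
    return ExpressionMatrix(
        global_mean_normalize_values(X.values, additive=additive),
        list(X.gene_ids),
        list(X.sample_ids),
    )
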