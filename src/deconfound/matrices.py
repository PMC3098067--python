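"""Core matrix containers for mixed-tissue expression deconvolution.

The data model is the factorization ``X ~ S @ C`` where

* ``X`` (genes x samples) holds measured expression intensities of a
  heterogeneous tissue (e.g. whole blood),
* ``S`` (genes x cell types) holds cell-type-specific expression
  signatures, and
* ``C`` (cell types x samples) holds per-sample cell-type proportions
  whose columns sum to one.

The containers are thin, validated wrappers around ``numpy`` arrays with
ordered identifier lists; heavier frame-based I/O lives in
:mod:`deconfound.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DeconfoundError",
    "ValidationError",
    "ExpressionMatrix",
    "SignatureMatrix",
    "ConcentrationMatrix",
    "COLUMN_SUM_TOL",
]

#: tolerance on concentration-matrix column sums (proportions sum to 100%)
COLUMN_SUM_TOL = 1e-8


class DeconfoundError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DeconfoundError, ValueError):
    """Invalid input data or configuration."""


def _check_ids(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


def _as_2d_float(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite entries")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression intensities."""

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "expression matrix")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression intensities must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not found") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class SignatureMatrix:
    """Genes x cell-types matrix of cell-type-specific expression profiles.

    Cell-type labels may be placeholders (``celltype_1`` ...) until marker
    based assignment relabels the columns.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_type_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "signature matrix")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_type_labels = _check_ids(self.cell_type_labels, "cell type")
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_labels)):
            raise ValidationError(
                f"signature matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_type_labels)} cell types"
            )
        if np.any(self.values < 0):
            raise ValidationError("signature matrix must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.cell_type_labels.index(label)
        except ValueError:
            raise KeyError(f"cell type {label!r} not found") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_type_labels)


@dataclass
class ConcentrationMatrix:
    """Cell-types x samples matrix of proportions; columns sum to one."""

    values: np.ndarray
    cell_type_labels: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "concentration matrix")
        self.cell_type_labels = _check_ids(self.cell_type_labels, "cell type")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.cell_type_labels), len(self.sample_ids)):
            raise ValidationError(
                f"concentration matrix shape {self.values.shape} does not match "
                f"{len(self.cell_type_labels)} cell types x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < -COLUMN_SUM_TOL) or np.any(self.values > 1 + COLUMN_SUM_TOL):
            raise ValidationError("concentrations must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > COLUMN_SUM_TOL):
            worst = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValidationError(
                f"concentration columns must sum to 1 (sample {worst!r} sums to "
                f"{sums[np.argmax(np.abs(sums - 1.0))]:.10g})"
            )

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, label: str) -> np.ndarray:
        try:
            i = self.cell_type_labels.index(label)
        except ValueError:
            raise KeyError(f"cell type {label!r} not found") from None
        return self.values[i, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_type_labels, columns=self.sample_ids)
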