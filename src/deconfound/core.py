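"""Constrained alternating-NNLS factorization of mixed-tissue expression.

The estimator decomposes a heterogeneous-tissue expression matrix as
``X ~ S @ C`` under three constraints:

1. ``S`` non-negative and column-normalized (quantile or global-mean);
2. ``0 <= C[i, j] <= 1`` for every entry;
3. every column of ``C`` sums to one (proportions sum to 100%).

Starting from random factors, the algorithm alternates exact NNLS
updates — fix ``S`` and solve for every sample column of ``C``, fix
``C`` and solve for every gene row of ``S``.  The concentration
constraints (2-3) are enforced right after every C-update: this keeps
the proportions on the simplex throughout and pins the scale split
between the two factors.  The S column normalization of constraint 1
is applied once at exit by default ("deferred"): enforcing it inside
the loop either has no effect on the iterates or slows convergence of
the factor estimates markedly, while non-negativity of ``S`` is
inherent to the NNLS update ("post_update" mode, which renormalizes
``S`` after every update, is available for comparison).

Iteration stops when the Frobenius residual ``||X - S C||_F`` drops
below ``residual_tol``, when its relative change between iterations
falls below ``rel_tol`` (disabled by default), or after
``max_iterations`` full sweeps.  Because alternating NNLS is a local
optimizer with random starts, ``n_restarts`` independent runs are
performed and the factorization with the smallest final residual is
reported (ties go to the lowest restart index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import (
    ConcentrationMatrix,
    ExpressionMatrix,
    SignatureMatrix,
    ValidationError,
)
from .nnls import nnls_shared
from .normalize import global_mean_normalize_values, quantile_normalize_values

__all__ = [
    "DeconfoundingConfig",
    "DeconfoundingResult",
    "deconfound",
    "residual_norm",
    "project_concentration_constraints",
    "preprocess_expression_values",
]

NORMALIZATIONS = ("quantile", "global_mean")
SCALES = ("linear", "log2")


@dataclass
class DeconfoundingConfig:
    """Settings of the alternating-NNLS deconvolution.

    Parameters
    ----------
    n_cell_types : number of signature columns to estimate (>= 2).
    normalization : "quantile" or "global_mean"; applied to the columns
        of ``X`` once up front and to the columns of ``S`` at every
        constraint step.
    scale : "linear" runs on intensities as given; "log2" transforms the
        input as ``log2(x + 1)`` first and reports signatures on the
        log2 scale.
    residual_tol : absolute Frobenius-residual exit threshold (criterion
        ``a``); reachable only on (near) noise-free instances.
    max_iterations : iteration cap (criterion ``b``), the practical exit
        on noisy data.
    rel_tol : optional additional exit when the relative residual change
        between successive iterations falls below this value; disabled
        (0) by default because the factor estimates keep improving long
        after the residual has plateaued.
    random_seed, n_restarts : random restarts of the local optimizer;
        the best final residual wins.
    """

    n_cell_types: int = 2
    normalization: str = "quantile"
    scale: str = "linear"
    residual_tol: float = 0.1
    max_iterations: int = 100
    random_seed: int = 0
    n_restarts: int = 3
    rel_tol: float = 0.0
    constraint_order: str = "deferred"

    def __post_init__(self):
        if self.n_cell_types < 2:
            raise ValidationError("n_cell_types must be >= 2")
        if self.normalization not in NORMALIZATIONS:
            raise ValidationError(f"normalization must be one of {NORMALIZATIONS}")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        if self.residual_tol <= 0:
            raise ValidationError("residual_tol must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")
        if self.rel_tol < 0:
            raise ValidationError("rel_tol must be >= 0")
        if self.constraint_order not in ("deferred", "post_update"):
            raise ValidationError("constraint_order must be 'deferred' or 'post_update'")


@dataclass
class DeconfoundingResult:
    """Estimated factorization together with its convergence trace."""

    S_hat: SignatureMatrix
    C_hat: ConcentrationMatrix
    residual_trace: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    stop_reason: str = ""
    restart_index: int = 0

    @property
    def final_residual(self) -> float:
        return float(self.residual_trace[-1]) if self.residual_trace else float("nan")


def residual_norm(X: ExpressionMatrix, S: SignatureMatrix, C: ConcentrationMatrix) -> float:
    """Frobenius norm of ``X - S @ C``."""
    if S.values.shape != (X.n_genes, C.n_cell_types) or C.n_samples != X.n_samples:
        raise ValidationError(
            f"non-conformable shapes: X {X.values.shape}, "
            f"S {S.values.shape}, C {C.values.shape}"
        )
    return float(np.linalg.norm(X.values - S.values @ C.values))


def project_concentration_constraints(C, cell_type_labels=None, sample_ids=None) -> ConcentrationMatrix:
    """Project a raw matrix onto the concentration constraints.

    Entries are clipped to [0, 1] and every column is rescaled to sum to
    one; a column that is all zero after clipping is replaced by the
    uniform composition ``1 / n_cell_types``.
    """
    V = np.asarray(C, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1:
        raise ValidationError("concentration matrix must be 2-D with >= 1 row")
    V = _project_concentration_values(V)
    k, n = V.shape
    if cell_type_labels is None:
        cell_type_labels = [f"celltype_{i + 1}" for i in range(k)]
    if sample_ids is None:
        sample_ids = [f"sample_{j + 1}" for j in range(n)]
    return ConcentrationMatrix(V, list(cell_type_labels), list(sample_ids))


def _project_concentration_values(V: np.ndarray) -> np.ndarray:
    V = np.clip(V, 0.0, 1.0)
    sums = V.sum(axis=0)
    dead = sums <= 0
    if np.any(dead):
        V[:, dead] = 1.0 / V.shape[0]
        sums = V.sum(axis=0)
    return V / sums[None, :]


def _apply_signature_constraints(S: np.ndarray, config: DeconfoundingConfig) -> np.ndarray:
    """Constraint 1: S non-negative and column-normalized."""
    S = np.clip(S, 0.0, None)
    if config.normalization == "quantile":
        S = quantile_normalize_values(S)
    else:
        grand = S.mean()
        col_means = S.mean(axis=0)
        if config.scale == "log2":
            S = S + (grand - col_means)[None, :]
        else:
            ok = col_means > 0
            scale = np.ones_like(col_means)
            scale[ok] = grand / col_means[ok]  # all-zero columns left alone
            S = S * scale[None, :]
    return np.clip(S, 0.0, None)


def preprocess_expression_values(values: np.ndarray, config: DeconfoundingConfig) -> np.ndarray:
    """Scale transform and column normalization applied to X up front."""
    V = np.asarray(values, dtype=float)
    if config.scale == "log2":
        V = np.log2(V + 1.0)
    if config.normalization == "quantile":
        V = quantile_normalize_values(V)
    else:
        V = global_mean_normalize_values(V, additive=(config.scale == "log2"))
    return V


def deconfound(X: ExpressionMatrix, config: DeconfoundingConfig | None = None) -> DeconfoundingResult:
    """Estimate signatures and proportions from mixed-tissue expression.

    Parameters
    ----------
    X : expression matrix (genes x samples, non-negative intensities).
    config : algorithm settings; defaults to :class:`DeconfoundingConfig`.

    Returns
    -------
    DeconfoundingResult with ``S_hat`` (placeholder cell-type labels
    ``celltype_1`` ...), ``C_hat`` (columns summing to one), the
    per-iteration Frobenius residual trace of the winning restart, and
    convergence information.
    """
    if config is None:
        config = DeconfoundingConfig()
    k = config.n_cell_types
    if k > X.n_samples:
        raise ValidationError(
            f"n_cell_types={k} exceeds the number of samples ({X.n_samples})"
        )
    if not np.any(X.values > 0):
        raise ValidationError("expression matrix is all zero; nothing to factorize")

    V = preprocess_expression_values(X.values, config)
    m, n = V.shape
    vmax = float(V.max())

    seeds = np.random.SeedSequence(config.random_seed).spawn(config.n_restarts)
    best = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(seeds[r])
        # start values: S resampled from the empirical intensity
        # distribution (scale-matched on any scale), C uniform projected
        S = rng.choice(V.ravel(), size=(m, k), replace=True)
        C = _project_concentration_values(rng.uniform(0.0, 1.0, size=(k, n)))
        if config.constraint_order == "post_update":
            S = _apply_signature_constraints(S, config)

        trace: list[float] = []
        prev = np.inf
        stop = "max_iterations"
        for _ in range(config.max_iterations):
            C = nnls_shared(S, V)  # fix S, solve every sample column
            C = _project_concentration_values(C)
            S = nnls_shared(C.T, V.T).T  # fix C, solve every gene row
            if config.constraint_order == "post_update":
                S = _apply_signature_constraints(S, config)
            res = float(np.linalg.norm(V - S @ C))
            trace.append(res)
            if res < config.residual_tol:
                stop = "residual_tol"
                break
            if config.rel_tol > 0 and np.isfinite(prev) and abs(prev - res) <= config.rel_tol * max(prev, 1e-300):
                stop = "rel_tol"
                break
            prev = res
        candidate = (trace[-1], r, S, C, trace, stop)
        if best is None or candidate[0] < best[0]:
            best = candidate

    final_res, r_idx, S, C, trace, stop = best
    if config.constraint_order == "deferred":
        # constraint 1 (column normalization of S) applied at exit; the
        # residual trace refers to the pre-normalization fit
        S = _apply_signature_constraints(S, config)
    gene_ids = list(X.gene_ids)
    sample_ids = list(X.sample_ids)
    labels = [f"celltype_{i + 1}" for i in range(k)]
    return DeconfoundingResult(
        S_hat=SignatureMatrix(S, gene_ids, labels),
        C_hat=ConcentrationMatrix(C, labels, sample_ids),
        residual_trace=trace,
        n_iterations=len(trace),
        converged=final_res < config.residual_tol,
        stop_reason=stop,
        restart_index=r_idx,
    )
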