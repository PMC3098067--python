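"""Non-negative least squares solvers.

``nnls_solve`` wraps the Lawson-Hanson active-set solver from scipy for a
single right-hand side.  ``nnls_shared`` solves many NNLS problems that
share one (skinny) design matrix ``A`` with a small number of columns, as
arise in alternating non-negative factorization: every column of ``C`` is
an NNLS problem against ``S``, every row of ``S`` an NNLS problem against
``C.T``.  For k unknowns the optimum is the best feasible least-squares
solution over the 2^k possible active sets, so with k equal to a handful
of cell types the exact solution for *all* right-hand sides can be
computed with a few vectorized ``lstsq`` calls instead of thousands of
per-column active-set iterations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.optimize

from .matrices import ValidationError

__all__ = ["nnls_solve", "nnls_shared"]

# negative slack tolerated when deciding feasibility of a candidate solution
_FEAS_TOL = 1e-10


def nnls_solve(A, b) -> np.ndarray:
    """Minimize ``||A x - b||_2`` subject to ``x >= 0``.

    Parameters
    ----------
    A : (m, k) array_like
    b : (m,) array_like

    Returns
    -------
    x : (k,) ndarray satisfying the KKT conditions of the NNLS problem.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.shape[0]:
        raise ValidationError(f"incompatible NNLS shapes {A.shape} and {b.shape}")
    if A.shape[1] < 1:
        raise ValidationError("design matrix needs at least one column")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValidationError("NNLS input contains non-finite values")
    x, _ = scipy.optimize.nnls(A, b)
    return x


def nnls_shared(A, B) -> np.ndarray:
    """Exact NNLS for every column of ``B`` against a shared design ``A``.

    Enumerates all active sets: for each non-empty subset F of columns the
    unconstrained least-squares solution restricted to F is computed for
    all right-hand sides at once; a candidate is feasible if it is
    non-negative, and the optimum for each column is the feasible
    candidate with the smallest residual (the all-zero solution is always
    feasible).  Exact because the restricted solution on the optimal
    support equals the NNLS optimum.  Cost grows as ``2^k`` in the number
    of unknowns, intended for small k (few cell types).

    Parameters
    ----------
    A : (m, k) array_like
    B : (m, p) array_like

    Returns
    -------
    X : (k, p) ndarray, column j minimizing ``||A x - B[:, j]||`` s.t. x >= 0.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValidationError(f"incompatible NNLS shapes {A.shape} and {B.shape}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValidationError("NNLS input contains non-finite values")
    m, k = A.shape
    p = B.shape[1]
    if k > 12:
        raise ValidationError("nnls_shared enumerates 2^k active sets; k too large")

    best_x = np.zeros((k, p))
    best_rn = np.einsum("ij,ij->j", B, B)  # residual of the all-zero solution

    # subsets ordered by size then lexicographically: deterministic tie-break
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            AF = A[:, support]
            XF, *_ = np.linalg.lstsq(AF, B, rcond=None)
            feas = np.all(XF >= -_FEAS_TOL, axis=0)
            if not np.any(feas):
                continue
            R = AF @ XF - B
            rn = np.einsum("ij,ij->j", R, R)
            upd = feas & (rn < best_rn - 1e-12 * (1.0 + best_rn))
            if np.any(upd):
                best_rn[upd] = rn[upd]
                best_x[:, upd] = 0.0
                best_x[np.ix_(list(support), np.flatnonzero(upd))] = np.clip(
                    XF[:, upd], 0.0, None
                )
    return best_x
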