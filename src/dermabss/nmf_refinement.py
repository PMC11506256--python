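"""Step 4: ALS non-negative matrix factorization warm-started from Step 3.

The first three steps can leave small negative values in the estimated maps,
which is not physically acceptable for concentrations.  Factorizing the full
4 x N mixture matrix as ``X ~= N @ H`` with both factors non-negative, and
initializing ``H`` with the Step-3 source matrix, restricts the NMF solution
set to the neighborhood of the true factors (up to per-source positive
scaling) and enforces non-negativity.  The solver alternates unconstrained
least-squares solves for ``N`` and ``H`` with projection of negative entries
to zero, minimizing the squared Euclidean distance ``0.5 * ||X - N H||^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class NMFResult:
    """Warm-started ALS-NMF factorization of the mixture matrix.

    ``N`` approximates the mixing matrix up to per-column positive scaling
    and ``H`` the source matrix up to the inverse per-row scaling.
    ``residual_history`` records ``0.5 * ||X - N H||_F^2`` per iteration.
    """

    N: np.ndarray
    H: np.ndarray
    residual_history: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _solve_gram(G: np.ndarray, B: np.ndarray, ridge: float = 1e-10):
    """Solve ``G Z = B`` with a logged ridge fallback for singular Gram."""
    try:
        return np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        logger.warning("singular Gram matrix; adding ridge jitter %.1e", ridge)
        G = G + ridge * np.eye(G.shape[0])
        try:
            return np.linalg.solve(G, B)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "persistent singular Gram matrix in ALS-NMF") from err


def als_nmf(X: np.ndarray, H_init: np.ndarray, eps: float = 1e-6,
            max_iter: int = 500) -> NMFResult:
    """Alternating least squares NMF with non-negativity projection.

    Parameters
    ----------
    X
        Non-negative mixture matrix, shape ``(4, N_pixels)`` (guaranteed by
        the zero-minimum absorbance construction).
    H_init
        Warm start for the source matrix, same shape as ``H``.  Negative
        entries are clamped to zero and each row is scaled to unit maximum
        (Step-3 outputs carry arbitrary scales).
    eps
        Relative change of the residual below which the iteration stops.
    max_iter
        Iteration budget.

    Returns
    -------
    NMFResult
        The best (lowest-residual) iterate; its residual never exceeds the
        first one.
    """
    X = np.asarray(X, dtype=float)
    H_init = np.asarray(H_init, dtype=float)
    if X.ndim != 2 or H_init.shape[1] != X.shape[1]:
        raise ValueError("X and H_init must be 2-D with matching column count")
    if X.min() < 0:
        raise ValueError("X must be non-negative")

    H = np.maximum(H_init, 0.0)
    H = _reseed_zero_rows(H, None)
    H = H / H.max(axis=1, keepdims=True)
    H0 = H.copy()
    # exact-fit floor: below this the relative-change test is float noise
    floor = 1e-15 * float(np.sum(X * X))

    history: list = []
    best = None
    converged = False
    for _ in range(max_iter):
        # N <- X H^T (H H^T)^-1, then clamp
        N = _solve_gram(H @ H.T, H @ X.T).T
        np.maximum(N, 0.0, out=N)
        if not N.any():
            raise np.linalg.LinAlgError("ALS-NMF collapsed: N is all zero")
        # H <- (N^T N)^-1 N^T X, then clamp
        H = _solve_gram(N.T @ N, N.T @ X)
        np.maximum(H, 0.0, out=H)
        H = _reseed_zero_rows(H, H0)
        d = 0.5 * float(np.sum((X - N @ H) ** 2))
        history.append(d)
        if best is None or d < best[0]:
            best = (d, N.copy(), H.copy())
        if d <= floor:
            converged = True
            break
        if len(history) >= 2:
            prev = history[-2]
            if abs(prev - d) <= eps * max(prev, 1e-300):
                converged = True
                break
    d_best, N_best, H_best = best
    logger.debug("als_nmf: %d iterations, residual %.3e -> %.3e, converged=%s",
                 len(history), history[0], d_best, converged)
    return NMFResult(N=N_best, H=H_best, residual_history=history,
                     iterations=len(history), converged=converged)


def _reseed_zero_rows(H: np.ndarray, H0: np.ndarray | None) -> np.ndarray:
    """Re-seed all-zero rows (logged): restart from the warm start when
    available, otherwise from tiny deterministic positive noise."""
    dead = ~H.any(axis=1)
    if dead.any():
        logger.warning("als_nmf: re-seeding %d zero row(s)", int(dead.sum()))
        H = H.copy()
        if H0 is not None:
            H[dead] = H0[dead]
        else:
            rng = np.random.default_rng(12345)
            H[dead] = 1e-8 * (1.0 + rng.random((int(dead.sum()), H.shape[1])))
    return H


def source_contributions(N: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-source contribution maps ``(sum_i N_ij) * H_j(u)``.

    The per-source positive scale indeterminacy of the factorization cancels
    in this product, which equals ``(sum_i m_ij) * S_j(u)`` for an exact
    factorization — the scale-free quantity worth reporting.
    """
    N = np.asarray(N, dtype=float)
    H = np.asarray(H, dtype=float)
    return N.sum(axis=0)[:, None] * H
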