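"""L1-penalized sparse inverse covariance (graphical lasso) estimation.

Solves

    minimize_{Theta > 0}  -log det(Theta) + tr(S Theta) + lam * ||Theta||_1,off

over symmetric positive definite matrices, where ``S`` is a sample covariance
and the L1 penalty is applied to the off-diagonal entries (the diagonal can
optionally be penalized too). Zero off-diagonal entries of the estimate encode
conditional independence, so the support of the solution is read as an
undirected association graph.

The solver is an ADMM splitting: the smooth log-det subproblem has a closed
form via one eigendecomposition per iteration, and the L1 subproblem is an
elementwise soft-threshold, which makes the returned support exactly sparse.
Convergence is declared on the duality gap, using the dual feasible point
obtained by projecting the primal inverse onto the box ``|W - S| <= lam``.
Warm starts across a decreasing lambda path are supported and used by the
stability-selection driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GlassoResult", "PrecisionPath", "glasso_fit", "lambda_max", "lambda_grid"]


class GlassoConvergenceError(RuntimeError):
    """Raised when ADMM fails to reach the duality-gap tolerance."""

    def __init__(self, msg: str, last_objective: float):
        super().__init__(f"{msg} (last objective {last_objective:.6g})")
        self.last_objective = last_objective


@dataclass
class GlassoResult:
    """One penalized precision estimate.

    ``precision`` is the positive-definite iterate; ``support`` is the exact
    off-diagonal sparsity pattern from the soft-threshold step (boolean,
    symmetric, False on the diagonal). ``sparse_precision`` carries the
    soft-thresholded values (exact zeros off the support) with the positive
    diagonal of ``precision``.
    """

    precision: np.ndarray
    sparse_precision: np.ndarray
    support: np.ndarray
    lam: float
    objective: float
    dual_gap: float
    n_iter: int

    @property
    def n_edges(self) -> int:
        return int(self.support.sum() // 2)


@dataclass
class PrecisionPath:
    """Penalized precision estimates along a decreasing lambda grid."""

    lambdas: np.ndarray
    results: list[GlassoResult] = field(default_factory=list)

    def supports(self) -> list[np.ndarray]:
        return [r.support for r in self.results]

    def n_edges(self) -> list[int]:
        return [r.n_edges for r in self.results]


def _objective(theta: np.ndarray, s: np.ndarray, lam: float, penalize_diagonal: bool) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return float(-logdet + np.sum(s * theta) + lam * l1)


def _dual_gap(theta: np.ndarray, s: np.ndarray, lam: float, penalize_diagonal: bool) -> float:
    """Duality gap at ``theta`` via box projection of its inverse.

    The dual is max log det(W) + p over |W - S|_inf <= lam (off-diagonal;
    the diagonal constraint is W_ii = S_ii when the diagonal is unpenalized).
    Returns +inf while the projected point is not positive definite.
    """
    p = s.shape[0]
    w = np.linalg.inv(theta)
    w = 0.5 * (w + w.T)
    lo, hi = s - lam, s + lam
    w_proj = np.clip(w, lo, hi)
    if not penalize_diagonal:
        np.fill_diagonal(w_proj, np.diag(s))
    sign, logdet_w = np.linalg.slogdet(w_proj)
    if sign <= 0:
        return np.inf
    primal = _objective(theta, s, lam, penalize_diagonal)
    dual = logdet_w + p
    return float(primal - dual)


def _soft_threshold(x: np.ndarray, thresh: float, penalize_diagonal: bool) -> np.ndarray:
    out = np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)
    if not penalize_diagonal:
        idx = np.arange(x.shape[0])
        out[idx, idx] = x[idx, idx]
    return out


def glasso_fit(
    cov: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 2000,
    penalize_diagonal: bool = False,
    rho: float = 1.0,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> GlassoResult:
    """Fit the graphical lasso at a single penalty level.

    Parameters
    ----------
    cov
        Symmetric sample covariance matrix.
    lam
        L1 penalty level, > 0.
    tol
        Duality-gap tolerance, scaled by the dimension.
    max_iter
        Maximum ADMM iterations; exceeding it raises
        :class:`GlassoConvergenceError` with the last objective value.
    penalize_diagonal
        Whether the L1 penalty covers the diagonal (off by default; keeps the
        estimator full rank and matches the common glasso convention).
    rho
        Initial ADMM penalty parameter (adapted by residual balancing).
    warm_start
        Optional ``(Z, U)`` pair from a previous fit at a nearby lambda.
    """
    s = np.asarray(cov, float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if lam <= 0:
        raise ValueError("lam must be positive")
    s = 0.5 * (s + s.T)
    p = s.shape[0]

    if warm_start is not None:
        z = warm_start[0].copy()
        u = warm_start[1].copy()
    else:
        z = np.diag(1.0 / np.maximum(np.diag(s) + lam, 1e-12))
        u = np.zeros_like(s)

    theta = z.copy()
    gap_scale = max(1.0, p)
    last_gap = np.inf
    for it in range(1, max_iter + 1):
        # Theta-step: closed-form solution of rho/2||Theta - (Z-U)||^2 part
        a = rho * (z - u) - s
        a = 0.5 * (a + a.T)
        evals, evecs = np.linalg.eigh(a)
        theta_evals = (evals + np.sqrt(evals**2 + 4.0 * rho)) / (2.0 * rho)
        theta = (evecs * theta_evals) @ evecs.T
        theta = 0.5 * (theta + theta.T)

        z_old = z
        z = _soft_threshold(theta + u, lam / rho, penalize_diagonal)
        u = u + theta - z

        if it % 5 == 0 or it == max_iter:
            r_norm = np.linalg.norm(theta - z)
            s_norm = rho * np.linalg.norm(z - z_old)
            scale = max(np.linalg.norm(theta), np.linalg.norm(z), 1e-12)
            if r_norm / scale < 0.1 * tol and s_norm / scale < 0.1 * tol:
                last_gap = _dual_gap(theta, s, lam, penalize_diagonal)
                if last_gap < tol * gap_scale:
                    break
            # residual balancing keeps the two ADMM residuals comparable
            if r_norm > 10.0 * s_norm:
                rho *= 2.0
                u /= 2.0
            elif s_norm > 10.0 * r_norm:
                rho /= 2.0
                u *= 2.0
    else:
        raise GlassoConvergenceError(
            f"glasso ADMM did not converge in {max_iter} iterations at lam={lam:.4g}",
            _objective(theta, s, lam, penalize_diagonal),
        )

    support = np.abs(z) > 0
    np.fill_diagonal(support, False)
    sparse = 0.5 * (z + z.T)
    np.fill_diagonal(sparse, np.diag(theta))
    sparse[~(support | np.eye(p, dtype=bool))] = 0.0
    result = GlassoResult(
        precision=theta,
        sparse_precision=sparse,
        support=support,
        lam=float(lam),
        objective=_objective(theta, s, lam, penalize_diagonal),
        dual_gap=float(last_gap),
        n_iter=it,
    )
    result._warm = (z, u)  # type: ignore[attr-defined]  # path reuse
    return result


def lambda_max(cov: np.ndarray) -> float:
    """Smallest penalty yielding an empty graph: max off-diagonal |cov|."""
    s = np.asarray(cov, float)
    off = np.abs(s - np.diag(np.diag(s)))
    return float(off.max()) if s.shape[0] > 1 else 1.0


def lambda_grid(cov: np.ndarray, n_lambda: int = 20, lambda_min_ratio: float = 1e-2) -> np.ndarray:
    """Log-spaced decreasing penalty grid from lambda_max down."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < lambda_min_ratio < 1:
        raise ValueError("lambda_min_ratio must be in (0, 1)")
    lmax = lambda_max(cov)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def fit_path(
    cov: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 2000,
    penalize_diagonal: bool = False,
) -> PrecisionPath:
    """Fit the penalty path from sparse to dense with warm starts."""
    lambdas = np.sort(np.asarray(lambdas, float))[::-1]
    path = PrecisionPath(lambdas=lambdas)
    warm = None
    for lam in lambdas:
        res = glasso_fit(
            cov, lam, tol=tol, max_iter=max_iter,
            penalize_diagonal=penalize_diagonal, warm_start=warm,
        )
        warm = res._warm  # type: ignore[attr-defined]
        path.results.append(res)
    return path
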