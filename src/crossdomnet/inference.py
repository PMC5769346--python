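"""Sparse association-network inference from (cross-domain) CLR data.

The community is modeled as a Gaussian graphical model on the latent log
absolute abundances: the sample covariance of the concatenated per-domain CLR
matrix approximates the covariance of the log basis (exactly so as the number
of taxa per domain grows), so an L1-penalized maximum-likelihood precision
estimate of the CLR data recovers the sparse conditional-dependence graph of
the underlying community. The penalty level is chosen by StARS (Stability
Approach to Regularization Selection): the graph is re-estimated over random
subsamples of the data along the whole penalty path, and the densest model
whose edge set is stable (subsampling instability below a threshold,
conventionally 0.1) is selected. Nonzero off-diagonal entries of the selected
precision matrix become signed, weighted edges (partial correlations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import (
    GlassoResult,
    PrecisionPath,
    fit_path,
    glasso_fit,
    lambda_grid,
)
from .preprocess import ClrMatrix, CrossDomainMatrix
from .taxonomy import UNCLASSIFIED, phylum_of

__all__ = [
    "CovarianceEstimate",
    "StarsResult",
    "AssociationNetwork",
    "EdgeTally",
    "empirical_covariance",
    "lambda_path",
    "stars_select",
    "precision_to_network",
    "classify_edges",
]


def _as_matrix(z) -> tuple[np.ndarray, list[str]]:
    if isinstance(z, CrossDomainMatrix) or isinstance(z, ClrMatrix):
        df = z.values
        return df.to_numpy(float), [str(c) for c in df.columns]
    if isinstance(z, pd.DataFrame):
        return z.to_numpy(float), [str(c) for c in z.columns]
    arr = np.asarray(z, float)
    return arr, [f"v{i}" for i in range(arr.shape[1])]


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    n_samples: int
    column_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance estimate must be symmetric")
        if (np.diag(m) < -1e-12).any():
            raise ValueError("covariance diagonal must be non-negative")
        self.matrix = 0.5 * (m + m.T)


def empirical_covariance(z) -> CovarianceEstimate:
    """Unbiased (n-1 denominator) sample covariance of the columns."""
    arr, cols = _as_matrix(z)
    if arr.shape[0] < 2:
        raise ValueError("covariance needs at least 2 samples")
    cov = np.cov(arr, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return CovarianceEstimate(matrix=cov, n_samples=arr.shape[0], column_ids=cols)


def _maybe_correlation(s: np.ndarray, use_correlation: bool) -> np.ndarray:
    if not use_correlation:
        return s
    d = np.sqrt(np.diag(s))
    d[d == 0] = 1.0
    return s / np.outer(d, d)


def lambda_path(
    cov: CovarianceEstimate | np.ndarray,
    n_lambda: int = 20,
    lambda_min_ratio: float = 1e-2,
    tol: float = 1e-4,
    max_iter: int = 2000,
    use_correlation: bool = True,
) -> PrecisionPath:
    """Fit the glasso penalty path, warm-started from the sparse end.

    The grid runs log-spaced from the smallest penalty giving an empty graph
    (the largest off-diagonal |covariance|) down by ``lambda_min_ratio``.
    With ``use_correlation`` (default) the covariance is rescaled to a
    correlation matrix first, so the uniform L1 penalty treats taxa with
    unequal CLR variances evenhandedly; partial correlations are invariant to
    this rescaling.
    """
    s = cov.matrix if isinstance(cov, CovarianceEstimate) else np.asarray(cov, float)
    s = _maybe_correlation(s, use_correlation)
    grid = lambda_grid(s, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    return fit_path(s, grid, tol=tol, max_iter=max_iter)


@dataclass
class StarsResult:
    """StARS stability-selection output.

    ``edge_selection_frequencies`` holds, per penalty level, the fraction of
    subsamples in which each edge was selected; ``instability_curve`` is the
    mean over node pairs of ``2 * theta * (1 - theta)`` (maximal, 0.5, when an
    edge appears in exactly half the subsamples). ``converged`` is False when
    no penalty met the threshold and the sparsest model was returned instead.
    """

    selected_lambda: float
    selected_index: int
    lambdas: np.ndarray
    edge_selection_frequencies: list[np.ndarray]
    instability_curve: np.ndarray
    monotonized_instability: np.ndarray
    refit: GlassoResult
    beta: float
    n_subsamples: int
    subsample_size: int
    seed: int
    converged: bool = True

    @property
    def selected_frequencies(self) -> np.ndarray:
        return self.edge_selection_frequencies[self.selected_index]


def stars_select(
    z,
    beta: float = 0.1,
    n_lambda: int = 20,
    lambda_min_ratio: float = 1e-2,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    seed: int = 0,
    tol: float = 1e-3,
    refit_tol: float = 1e-5,
    max_iter: int = 2000,
    use_correlation: bool = True,
) -> StarsResult:
    """Select the penalty by edge-set stability under subsampling.

    For each of ``n_subsamples`` random subsamples (without replacement, of
    size ``floor(10*sqrt(n))`` capped at ``n - 1`` unless given) the full
    penalty path is refit and per-edge selection frequencies are accumulated.
    Per-penalty instability is monotonized by a running maximum from the
    sparse end, and the densest model whose monotonized instability stays at
    or below ``beta`` is selected, then refit on the full data.
    """
    if not 0 < beta < 0.5:
        raise ValueError("beta must be in (0, 0.5)")
    arr, cols = _as_matrix(z)
    n, p = arr.shape
    if subsample_size is None:
        # floor(10*sqrt(n)) per the StARS reference, capped at 80% of n so
        # subsamples stay distinct on small cohorts
        subsample_size = min(int(np.floor(10.0 * np.sqrt(n))), int(0.8 * n), n - 1)
    if not 1 < subsample_size < n:
        raise ValueError("subsample_size must be in (1, n_samples)")

    full_cov = _maybe_correlation(np.cov(arr, rowvar=False, ddof=1), use_correlation)
    grid = lambda_grid(full_cov, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)

    rng = np.random.default_rng(seed)
    counts = [np.zeros((p, p)) for _ in grid]
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub_cov = _maybe_correlation(
            np.cov(arr[idx], rowvar=False, ddof=1), use_correlation
        )
        path = fit_path(sub_cov, grid, tol=tol, max_iter=max_iter)
        for k, res in enumerate(path.results):
            counts[k] += res.support

    freqs = [c / n_subsamples for c in counts]
    offdiag = ~np.eye(p, dtype=bool)
    n_pairs = p * (p - 1) / 2.0
    instability = np.array(
        [float((2.0 * f * (1.0 - f))[offdiag].sum() / 2.0 / n_pairs) for f in freqs]
    )
    monotonized = np.maximum.accumulate(instability)  # grid is sparse -> dense

    ok = np.flatnonzero(monotonized <= beta)
    if ok.size:
        selected_index = int(ok[-1])  # densest stable model
        converged = True
    else:
        selected_index = 0
        converged = False
        warnings.warn(
            f"StARS instability never fell below beta={beta}; "
            "returning the sparsest model on the path",
            UserWarning,
            stacklevel=2,
        )
    selected_lambda = float(grid[selected_index])
    refit = glasso_fit(full_cov, selected_lambda, tol=refit_tol, max_iter=max_iter)
    return StarsResult(
        selected_lambda=selected_lambda,
        selected_index=selected_index,
        lambdas=grid,
        edge_selection_frequencies=freqs,
        instability_curve=instability,
        monotonized_instability=monotonized,
        refit=refit,
        beta=beta,
        n_subsamples=n_subsamples,
        subsample_size=subsample_size,
        seed=seed,
        converged=converged,
    )


@dataclass
class AssociationNetwork:
    """Undirected signed association graph over OTUs.

    Thin wrapper around a :class:`networkx.Graph`; node attributes are
    ``otu_id`` (un-namespaced), ``domain``, ``phylum`` and ``lineage``, edge
    attributes ``partial_correlation`` and ``sign``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (u, v): d["partial_correlation"]
            for u, v, d in self.graph.edges(data=True)
        }

    def domains(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="domain", default=""))


def precision_to_network(
    precision: np.ndarray,
    node_ids: list[str] | None = None,
    domains: list[str] | dict[str, str] | None = None,
    taxonomy: dict[str, str] | None = None,
    threshold: float = 1e-10,
    support: np.ndarray | None = None,
) -> AssociationNetwork:
    """Turn a sparse precision matrix into a signed association network.

    Edge weights are partial correlations
    ``rho_ij = -prec_ij / sqrt(prec_ii * prec_jj)`` (the sign flip relative to
    the raw precision entry is the standard Gaussian graphical model
    convention). An edge exists wherever the off-diagonal entry exceeds
    ``threshold`` in magnitude, or wherever ``support`` is True if an explicit
    support mask (e.g. from the penalized fit) is supplied.

    Node ids may be domain-namespaced as ``"<domain>:<otu>"``; the domain is
    recovered from the prefix when ``domains`` is not given. ``taxonomy``
    maps base OTU ids (or namespaced ids) to lineage strings.
    """
    prec = np.asarray(precision, float)
    if not np.isfinite(prec).all():
        raise ValueError("precision matrix contains non-finite entries")
    if not np.allclose(prec, prec.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    if (np.diag(prec) <= 0).any():
        raise ValueError("precision diagonal must be positive")
    p = prec.shape[0]
    if node_ids is None:
        node_ids = [f"v{i}" for i in range(p)]
    taxonomy = taxonomy or {}

    def _node_meta(k: int) -> dict[str, str]:
        nid = node_ids[k]
        if isinstance(domains, dict):
            dom = domains.get(nid, "")
        elif domains is not None:
            dom = domains[k]
        else:
            dom = nid.split(":", 1)[0] if ":" in nid else ""
        base = nid.split(":", 1)[1] if ":" in nid else nid
        lineage = taxonomy.get(nid, taxonomy.get(base, ""))
        return {
            "otu_id": base,
            "domain": dom,
            "phylum": phylum_of(lineage) if lineage else UNCLASSIFIED,
            "lineage": lineage,
        }

    g = nx.Graph()
    for k in range(p):
        g.add_node(node_ids[k], **_node_meta(k))
    d = np.sqrt(np.diag(prec))
    for i in range(p):
        for j in range(i + 1, p):
            present = support[i, j] if support is not None else abs(prec[i, j]) > threshold
            if present:
                rho = float(-prec[i, j] / (d[i] * d[j]))
                g.add_edge(
                    node_ids[i],
                    node_ids[j],
                    partial_correlation=rho,
                    weight=rho,
                    sign=1 if rho > 0 else -1,
                )
    return AssociationNetwork(graph=g)


@dataclass
class EdgeTally:
    """Edge counts split by endpoint domains."""

    within: dict[str, int]
    cross: dict[tuple[str, str], int]
    total: int

    @property
    def n_cross(self) -> int:
        return sum(self.cross.values())

    @property
    def cross_fraction(self) -> float:
        return self.n_cross / self.total if self.total else 0.0

    def fractions(self) -> dict[str, float]:
        out = {f"within:{d}": c / self.total for d, c in self.within.items()}
        for (a, b), c in self.cross.items():
            out[f"cross:{a}-{b}"] = c / self.total
        return out


def classify_edges(net: AssociationNetwork) -> EdgeTally:
    """Tally edges as within-domain (per domain) or cross-domain."""
    within: dict[str, int] = {}
    cross: dict[tuple[str, str], int] = {}
    g = net.graph
    for u, v in g.edges:
        du = g.nodes[u].get("domain", "")
        dv = g.nodes[v].get("domain", "")
        if du == dv:
            within[du] = within.get(du, 0) + 1
        else:
            key = tuple(sorted((du, dv)))
            cross[key] = cross.get(key, 0) + 1
    return EdgeTally(within=within, cross=cross, total=g.number_of_edges())
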