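"""Sparse Gaussian graphical model estimation.

The latent correlation matrix is fed to the graphical lasso over a
descending penalty path; the extended BIC (EBIC) selects the penalty; the
selected precision matrix Theta is reported as partial-correlation edge
weights w_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj).

The L1-penalized fit itself delegates to scikit-learn's ``graphical_lasso``
(off-diagonal penalty only, matching the objective
log det Theta - tr(S Theta) - lam * sum_{i != j} |Theta_ij|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "GlassoPath",
    "RegularizedNetwork",
    "glasso_fit",
    "ebic",
    "estimate_network",
    "partial_correlations",
]

_EDGE_EPS = 1e-8  # |Theta_ij| below this counts as an exact zero


def glasso_fit(S: np.ndarray, lam: float, max_iter: int = 500) -> np.ndarray:
    """Graphical lasso precision estimate at penalty ``lam``.

    Maximizes log det Theta - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|
    (diagonal unpenalized). ``lam = 0`` returns the unpenalized MLE S^-1.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    w = np.linalg.eigvalsh((S + S.T) / 2.0)
    if w.min() <= 0:
        raise ValueError("input matrix must be positive definite")
    if lam == 0.0:
        return np.linalg.inv(S)
    try:
        with warnings.catch_warnings():
            # near-converged fits (dual gap ~ tol) are fine for selection
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            _, precision = graphical_lasso(
                S, alpha=float(lam), max_iter=max_iter, tol=1e-6, enet_tol=1e-8
            )
    except FloatingPointError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    return (precision + precision.T) / 2.0


def _edge_count(Theta: np.ndarray) -> int:
    iu = np.triu_indices_from(Theta, k=1)
    return int(np.sum(np.abs(Theta[iu]) > _EDGE_EPS))


def ebic(Theta: np.ndarray, S: np.ndarray, n: int, gamma_ebic: float = 0.5) -> float:
    """Extended BIC of a precision estimate:
    -2 * (n/2) * (log det Theta - tr(S Theta)) + E log n + 4 gamma E log p,
    with E the number of nonzero off-diagonal upper-triangle entries. The
    additive Gaussian constant is omitted (selection is invariant to it)."""
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise ValueError("precision estimate must be positive definite")
    loglik = (n / 2.0) * (logdet - np.trace(S @ Theta))
    E = _edge_count(Theta)
    p = Theta.shape[0]
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma_ebic * E * np.log(p))


def partial_correlations(Theta: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a precision matrix; zero diagonal."""
    d = np.sqrt(np.diag(Theta))
    W = -Theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < _EDGE_EPS] = 0.0
    return (W + W.T) / 2.0


@dataclass(frozen=True)
class GlassoPath:
    """Penalty path with per-lambda precision fits and EBIC values."""

    lambdas: np.ndarray
    precisions: tuple[np.ndarray, ...]
    logliks: np.ndarray  # (n/2)(log det - trace) part only
    edge_counts: np.ndarray
    ebics: np.ndarray

    def argmin_ebic(self) -> int:
        """Index of the minimal EBIC; ties go to the larger penalty
        (sparser model). The path is stored with lambdas descending, so the
        first minimizer wins."""
        return int(np.argmin(self.ebics))


@dataclass(frozen=True)
class RegularizedNetwork:
    """Partial-correlation network selected by EBIC."""

    weights: np.ndarray
    item_codes: tuple[str, ...]
    lam: float
    gamma_ebic: float
    n: int
    path: GlassoPath | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(W)) > 0):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(W) >= 1):
            raise ValueError("partial correlations must lie in (-1, 1)")
        object.__setattr__(self, "weights", W)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.sum(self.weights[iu] != 0))

    @property
    def edge_fraction(self) -> float:
        return self.edge_count / self.possible_edges

    def edge_list(self) -> pd.DataFrame:
        """Edges sorted by |weight| descending."""
        iu, ju = np.triu_indices(self.p, k=1)
        w = self.weights[iu, ju]
        keep = w != 0
        frame = pd.DataFrame(
            {
                "node_i": [self.item_codes[i] for i in iu[keep]],
                "node_j": [self.item_codes[j] for j in ju[keep]],
                "weight": w[keep],
            }
        )
        return frame.reindex(
            frame["weight"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)

    def to_weight_tsv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=list(self.item_codes), columns=list(self.item_codes)
        ).to_csv(path, sep="\t")

    def to_edge_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def to_graph(self, absolute: bool = False):
        """networkx Graph with 'weight' attributes (optionally |weight|)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.item_codes)
        iu, ju = np.triu_indices(self.p, k=1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0:
                G.add_edge(
                    self.item_codes[i],
                    self.item_codes[j],
                    weight=abs(w) if absolute else w,
                )
        return G

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)


def estimate_network(
    S: np.ndarray,
    n: int,
    item_codes: tuple[str, ...] | None = None,
    gamma_ebic: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    keep_path_precisions: bool = False,
) -> RegularizedNetwork:
    """EBIC-tuned graphical lasso network.

    The penalty path holds ``n_lambda`` log-spaced values from
    lambda_max = max off-diagonal |S| (which yields the empty graph) down to
    lambda_max * lambda_min_ratio. EBIC ties break toward the larger penalty.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if item_codes is None:
        item_codes = tuple(f"V{j + 1}" for j in range(p))
    if n <= p:
        warnings.warn(
            f"sample count n={n} does not exceed item count p={p}; "
            "regularized estimates may be unstable",
            stacklevel=2,
        )
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.max(np.abs(S[iu])))
    if lam_max == 0.0:
        return RegularizedNetwork(
            weights=np.zeros((p, p)),
            item_codes=item_codes,
            lam=0.0,
            gamma_ebic=gamma_ebic,
            n=n,
        )
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    precisions: list[np.ndarray] = []
    logliks = np.empty(n_lambda)
    edges = np.empty(n_lambda, dtype=int)
    ebics = np.empty(n_lambda)
    for t, lam in enumerate(lambdas):
        Theta = glasso_fit(S, lam)
        precisions.append(Theta)
        sign, logdet = np.linalg.slogdet(Theta)
        logliks[t] = (n / 2.0) * (logdet - np.trace(S @ Theta))
        edges[t] = _edge_count(Theta)
        ebics[t] = ebic(Theta, S, n, gamma_ebic)

    path = GlassoPath(
        lambdas=lambdas,
        precisions=tuple(precisions) if keep_path_precisions else tuple(),
        logliks=logliks,
        edge_counts=edges,
        ebics=ebics,
    )
    best = int(np.argmin(ebics))
    W = partial_correlations(precisions[best])
    return RegularizedNetwork(
        weights=W,
        item_codes=item_codes,
        lam=float(lambdas[best]),
        gamma_ebic=gamma_ebic,
        n=n,
        path=path,
    )
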