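"""Stability and inference by resampling.

Three procedures, all re-running the full estimation pipeline
(polychoric -> EBIC-glasso -> centrality) on resampled data:

* case-dropping bootstrap with the correlation-stability (CS) coefficient —
  the largest proportion of subjects that can be dropped while the
  correlation between subsample and full-sample centrality stays >= 0.7 in
  at least 95% of draws (> 0.25 interpretable, > 0.5 preferred);
* nonparametric case bootstrap with 95% percentile intervals for every edge
  weight and centrality, and for pairwise differences between them;
* a permutation test comparing mean centrality between two node groups
  (e.g. DSM vs non-DSM symptoms), exact by enumeration of all group
  assignments when that is cheaper than Monte-Carlo sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .centrality import CENTRALITY_INDICES, CentralityTable, centrality_table
from .data import ItemCatalog, OrdinalResponseMatrix
from .network import RegularizedNetwork, estimate_network
from .polychoric import polychoric_matrix

__all__ = [
    "FitConfig",
    "StabilityResult",
    "BootstrapResult",
    "PermutationTestResult",
    "fit_network",
    "fit_centrality",
    "case_drop_stability",
    "nonparametric_bootstrap",
    "group_centrality_permutation",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))


@dataclass(frozen=True)
class FitConfig:
    """Tunables of one pipeline fit, shared by all resampling loops."""

    gamma_ebic: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    closeness_variant: str = "reciprocal-total"


def fit_network(data: OrdinalResponseMatrix, config: FitConfig | None = None) -> RegularizedNetwork:
    config = config or FitConfig()
    poly = polychoric_matrix(data)
    return estimate_network(
        poly.correlation,
        n=data.n,
        item_codes=data.item_codes,
        gamma_ebic=config.gamma_ebic,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )


def fit_centrality(
    data: OrdinalResponseMatrix, config: FitConfig | None = None
) -> tuple[RegularizedNetwork, CentralityTable]:
    config = config or FitConfig()
    net = fit_network(data, config)
    return net, centrality_table(net, config.closeness_variant)


def _vector_correlation(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method '{method}'")


@dataclass(frozen=True)
class StabilityResult:
    """Case-dropping bootstrap output.

    ``correlations[index]`` is a (len(grid), B_per) array of subsample-vs-full
    centrality correlations (NaN where a draw failed or was degenerate).
    """

    grid: tuple[float, ...]
    correlations: dict[str, np.ndarray]
    cs: dict[str, float]
    cor_threshold: float
    prob: float
    cor_method: str
    seed: int | None
    n_failed: int

    def interpretability(self, index: str) -> str:
        value = self.cs[index]
        if value > 0.5:
            return "preferred"
        if value > 0.25:
            return "interpretable"
        return "low"

    def retained_fraction(self, index: str) -> np.ndarray:
        """Per grid point, the fraction of draws with correlation >= threshold."""
        cors = self.correlations[index]
        ok = np.where(np.isnan(cors), False, cors >= self.cor_threshold)
        return ok.mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "grid": list(self.grid),
            "cs": {k: float(v) for k, v in self.cs.items()},
            "interpretability": {
                k: self.interpretability(k) for k in self.cs
            },
            "retained_fraction": {
                k: self.retained_fraction(k).tolist() for k in self.correlations
            },
            "cor_threshold": self.cor_threshold,
            "prob": self.prob,
            "cor_method": self.cor_method,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def compute_cs(
    correlations: np.ndarray,
    grid: tuple[float, ...],
    cor_threshold: float = 0.7,
    prob: float = 0.95,
) -> float:
    """CS = max drop proportion whose draws stay correlated >= threshold with
    probability >= prob; 0 if no grid point qualifies."""
    ok = np.where(np.isnan(correlations), False, correlations >= cor_threshold)
    frac = ok.mean(axis=1)
    qualifying = [q for q, f in zip(grid, frac) if f >= prob]
    return max(qualifying) if qualifying else 0.0


def case_drop_stability(
    data: OrdinalResponseMatrix,
    config: FitConfig | None = None,
    grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B_per: int = 100,
    seed: int | None = None,
    cor_threshold: float = 0.7,
    prob: float = 0.95,
    cor_method: str = "pearson",
) -> StabilityResult:
    """Case-dropping bootstrap of centrality stability."""
    config = config or FitConfig()
    largest_drop = max(grid)
    if round((1 - largest_drop) * data.n) < data.p + 1:
        raise ValueError("largest drop proportion leaves too few cases")

    _, full = fit_centrality(data, config)
    full_vectors = {idx: full.raw(idx) for idx in CENTRALITY_INDICES}

    rng = np.random.default_rng(seed)
    cors = {idx: np.full((len(grid), B_per), np.nan) for idx in CENTRALITY_INDICES}
    n_failed = 0
    for qi, q in enumerate(grid):
        size = int(round((1 - q) * data.n))
        for b in range(B_per):
            idx_rows = rng.choice(data.n, size=size, replace=False)
            try:
                _, sub = fit_centrality(data.subset_rows(idx_rows), config)
            except Exception:
                n_failed += 1
                continue
            for index in CENTRALITY_INDICES:
                cors[index][qi, b] = _vector_correlation(
                    full_vectors[index], sub.raw(index), cor_method
                )

    cs = {
        index: compute_cs(cors[index], grid, cor_threshold, prob)
        for index in CENTRALITY_INDICES
    }
    return StabilityResult(
        grid=tuple(grid),
        correlations=cors,
        cs=cs,
        cor_threshold=cor_threshold,
        prob=prob,
        cor_method=cor_method,
        seed=seed,
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Nonparametric case-bootstrap draws and 95% percentile intervals."""

    item_codes: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    edge_point: np.ndarray  # all upper-triangle weights (zeros included)
    centrality_point: dict[str, np.ndarray]
    edge_draws: np.ndarray  # B x n_pairs
    centrality_draws: dict[str, np.ndarray]  # index -> B x p
    B: int
    seed: int | None
    n_failed: int

    def edge_interval(self, a: int, b: int) -> tuple[float, float]:
        k = self.pairs.index((min(a, b), max(a, b)))
        lo, hi = np.quantile(self.edge_draws[:, k], [0.025, 0.975])
        return float(lo), float(hi)

    def centrality_interval(self, index: str, node: int) -> tuple[float, float]:
        lo, hi = np.quantile(self.centrality_draws[index][:, node], [0.025, 0.975])
        return float(lo), float(hi)

    def edge_difference_interval(self, pair_a: int, pair_b: int) -> tuple[float, float]:
        diff = self.edge_draws[:, pair_a] - self.edge_draws[:, pair_b]
        lo, hi = np.quantile(diff, [0.025, 0.975])
        return float(lo), float(hi)

    def centrality_difference_interval(
        self, index: str, node_a: int, node_b: int
    ) -> tuple[float, float]:
        draws = self.centrality_draws[index]
        diff = draws[:, node_a] - draws[:, node_b]
        lo, hi = np.quantile(diff, [0.025, 0.975])
        return float(lo), float(hi)

    def centrality_difference_significant(self, index: str) -> np.ndarray:
        """Boolean p x p matrix: interval of the pairwise centrality
        difference excludes 0."""
        draws = self.centrality_draws[index]
        p = draws.shape[1]
        sig = np.zeros((p, p), dtype=bool)
        for a in range(p):
            for b in range(a + 1, p):
                lo, hi = self.centrality_difference_interval(index, a, b)
                sig[a, b] = sig[b, a] = lo > 0 or hi < 0
        return sig


def nonparametric_bootstrap(
    data: OrdinalResponseMatrix,
    config: FitConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Case resampling with replacement; pipeline re-fit per draw."""
    config = config or FitConfig()
    net, cent = fit_centrality(data, config)
    p = data.p
    pairs = tuple((i, j) for i in range(p) for j in range(i + 1, p))
    iu = np.triu_indices(p, k=1)

    rng = np.random.default_rng(seed)
    edge_draws = np.full((B, len(pairs)), np.nan)
    cent_draws = {idx: np.full((B, p), np.nan) for idx in CENTRALITY_INDICES}
    n_failed = 0
    for b in range(B):
        rows = rng.choice(data.n, size=data.n, replace=True)
        try:
            bnet, bcent = fit_centrality(data.subset_rows(rows), config)
        except Exception:
            n_failed += 1
            continue
        edge_draws[b] = bnet.weights[iu]
        for index in CENTRALITY_INDICES:
            cent_draws[index][b] = bcent.raw(index)

    ok = ~np.isnan(edge_draws).all(axis=1)
    return BootstrapResult(
        item_codes=data.item_codes,
        pairs=pairs,
        edge_point=net.weights[iu],
        centrality_point={idx: cent.raw(idx) for idx in CENTRALITY_INDICES},
        edge_draws=edge_draws[ok],
        centrality_draws={idx: cent_draws[idx][ok] for idx in CENTRALITY_INDICES},
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class PermutationTestResult:
    """Two-sided permutation test of a group difference in node centrality."""

    observed: float
    p_value: float
    mode: str  # "exhaustive" | "monte-carlo"
    n_null: int
    seed: int | None
    null_sample: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "observed_difference": float(self.observed),
            "p_value": float(self.p_value),
            "mode": self.mode,
            "n_null": int(self.n_null),
            "seed": self.seed,
        }


def _group_mask(groups, p: int, group1: str) -> np.ndarray:
    if isinstance(groups, ItemCatalog):
        mask = groups.group_indicator(group1)
    else:
        arr = np.asarray(groups)
        mask = arr if arr.dtype == bool else arr == group1
    if mask.shape != (p,):
        raise ValueError("group labels inconsistent with the centrality vector")
    n1 = int(mask.sum())
    if n1 == 0 or n1 == p:
        raise ValueError("both groups must be nonempty")
    return mask


def group_centrality_permutation(
    values: np.ndarray,
    groups,
    group1: str = "DSM",
    R: int = 100_000,
    mode: str = "auto",
    seed: int | None = None,
    keep_null: bool = False,
) -> PermutationTestResult:
    """Test mean(group1) - mean(group2) against random node reassignment.

    ``groups`` may be an ItemCatalog (group1 selected by label), a boolean
    mask, or a label sequence. Exhaustive mode enumerates every assignment of
    the observed group sizes; Monte-Carlo draws R random assignments and uses
    the add-one estimator p = (1 + #{|null| >= |obs|}) / (1 + R). ``auto``
    enumerates whenever C(p, n1) <= R.
    """
    values = np.asarray(values, dtype=float)
    p = len(values)
    mask = _group_mask(groups, p, group1)
    n1 = int(mask.sum())
    observed = values[mask].mean() - values[~mask].mean()

    total = values.sum()
    n2 = p - n1
    n_exhaustive = math.comb(p, n1)
    if mode == "auto":
        mode = "exhaustive" if n_exhaustive <= R else "monte-carlo"

    if mode == "exhaustive":
        idx = np.fromiter(
            (i for combo in combinations(range(p), n1) for i in combo),
            dtype=np.int64,
            count=n_exhaustive * n1,
        ).reshape(n_exhaustive, n1)
        sums1 = values[idx].sum(axis=1)
        null = sums1 / n1 - (total - sums1) / n2
        exceed = int(np.sum(np.abs(null) >= np.abs(observed) - 1e-12))
        p_value = exceed / n_exhaustive
        n_null = n_exhaustive
    elif mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((R, p)), axis=1)[:, :n1]
        sums1 = values[order].sum(axis=1)
        null = sums1 / n1 - (total - sums1) / n2
        exceed = int(np.sum(np.abs(null) >= np.abs(observed) - 1e-12))
        p_value = (1 + exceed) / (1 + R)
        n_null = R
    else:
        raise ValueError(f"unknown mode '{mode}'")

    return PermutationTestResult(
        observed=float(observed),
        p_value=float(p_value),
        mode=mode,
        n_null=n_null,
        seed=seed,
        null_sample=null if keep_null else None,
    )
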