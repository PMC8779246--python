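"""Synthetic ordinal datasets with known ground truth.

The generator draws latent multivariate-normal vectors whose precision
matrix carries a planted sparse, block-structured partial-correlation
network, then discretizes each coordinate through thresholds chosen to
match target marginal category probabilities. This latent-Gaussian copula
is exactly the data-generating model that polychoric correlation assumes,
so the full pipeline (polychoric -> EBIC-glasso -> centrality ->
communities) can be validated against a recoverable truth.

Default dimensions emulate the REAP-AP schizophrenia cohort: 18 items on a
7-point scale, n = 1438 subjects, marginals taken from the cohort's
published frequency table, and three planted symptom clusters of sizes
10/3/5 with within-block partial correlations in the 0.15-0.45 range
(the magnitude range of the strongest edges reported for that cohort).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .data import OrdinalResponseMatrix, reference_item_counts
from .network import partial_correlations

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "packaged_bprs_marginals",
    "spec_from_partials",
    "make_truth_network",
    "sample_ordinal",
]

DEFAULT_BLOCKS = (10, 3, 5)


def packaged_bprs_marginals() -> tuple[np.ndarray, tuple[str, ...]]:
    """18 x 7 per-item category probabilities (published cohort counts / n)
    together with the item codes, in catalog order."""
    table = reference_item_counts()
    probs = table.counts / table.n
    return probs, table.item_codes


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for one synthetic study.

    ``partials`` holds the achieved partial correlations (after the diagonal
    loading that enforces positive definiteness) — recovery experiments must
    compare against these, not the pre-loading targets.
    """

    precision: np.ndarray
    partials: np.ndarray
    latent_corr: np.ndarray
    category_probs: np.ndarray  # p x K, rows sum to 1
    labels: np.ndarray  # planted community of each item, 1-based
    item_codes: tuple[str, ...]
    seed: int | None

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def K(self) -> int:
        return self.category_probs.shape[1]

    def true_edges(self) -> np.ndarray:
        """Boolean upper-triangle adjacency of the achieved truth."""
        iu = np.triu_indices(self.p, k=1)
        return np.abs(self.partials[iu]) > 1e-10

    def thresholds(self) -> list[np.ndarray]:
        cuts = []
        for row in self.category_probs:
            cum = np.cumsum(row[:-1])
            cum = np.clip(cum, 1e-12, 1 - 1e-12)
            cuts.append(ndtri(cum))
        return cuts

    def to_json(self, path) -> None:
        payload = {
            "partials": self.partials.tolist(),
            "labels": self.labels.tolist(),
            "item_codes": list(self.item_codes),
            "category_probs": self.category_probs.tolist(),
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class SyntheticDataset:
    data: OrdinalResponseMatrix
    spec: SyntheticSpec


def _default_marginals(p: int, item_codes=None):
    probs18, codes18 = packaged_bprs_marginals()
    if p == 18:
        return probs18, codes18 if item_codes is None else tuple(item_codes)
    # smaller/larger studies reuse the published marginals cyclically
    idx = np.arange(p) % 18
    probs = probs18[idx]
    codes = (
        tuple(item_codes)
        if item_codes is not None
        else tuple(f"{codes18[i]}{j + 1}" for j, i in enumerate(idx))
    )
    return probs, codes


def spec_from_partials(
    target: np.ndarray,
    labels: np.ndarray | None = None,
    marginals: np.ndarray | None = None,
    item_codes: tuple[str, ...] | None = None,
    min_eig: float = 0.05,
    seed: int | None = None,
) -> SyntheticSpec:
    """Turn a target partial-correlation pattern into a sampling-ready spec.

    ``target`` is symmetric with zero diagonal; it becomes the off-diagonal
    of a unit-diagonal precision matrix, diagonally loaded until the smallest
    eigenvalue reaches ``min_eig``. The achieved partial correlations (the
    targets shrunk by the loading) are stored as the recoverable truth.
    """
    target = np.asarray(target, dtype=float)
    p = target.shape[0]
    if not np.allclose(target, target.T) or np.any(np.diag(target) != 0):
        raise ValueError("target must be symmetric with zero diagonal")
    omega = np.eye(p) - target
    w_min = np.linalg.eigvalsh(omega).min()
    delta = max(0.0, min_eig - w_min)
    if delta > 25.0:
        raise ValueError("target weights cannot be made positive definite")
    omega = omega + delta * np.eye(p)

    partials = partial_correlations(omega)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    latent = sigma / np.outer(d, d)
    np.fill_diagonal(latent, 1.0)

    if marginals is None:
        marginals, item_codes = _default_marginals(p, item_codes)
    else:
        marginals = np.asarray(marginals, dtype=float)
        if item_codes is None:
            item_codes = tuple(f"V{j + 1}" for j in range(p))
    if marginals.shape[0] != p:
        raise ValueError("marginals must have one row per item")
    if labels is None:
        labels = np.ones(p, dtype=np.int64)

    return SyntheticSpec(
        precision=omega,
        partials=partials,
        latent_corr=latent,
        category_probs=marginals,
        labels=np.asarray(labels, dtype=np.int64),
        item_codes=tuple(item_codes),
        seed=seed,
    )


def make_truth_network(
    blocks: tuple[int, ...] = DEFAULT_BLOCKS,
    within_density: float = 0.5,
    within_weight_range: tuple[float, float] = (0.15, 0.45),
    bridge_count: int = 4,
    bridge_weight: float = 0.1,
    seed: int | None = None,
    marginals: np.ndarray | None = None,
    item_codes: tuple[str, ...] | None = None,
    min_eig: float = 0.05,
) -> SyntheticSpec:
    """Plant a sparse block-structured partial-correlation network.

    Each block receives a random spanning tree (so planted communities are
    connected) plus random extra within-block edges up to
    round(within_density * pairs-in-block), with weights drawn uniformly from
    ``within_weight_range``; ``bridge_count`` cross-block edges of weight
    ``bridge_weight`` tie the blocks together. The target pattern is turned
    into a precision matrix with unit diagonal and then diagonally loaded
    until the smallest eigenvalue reaches ``min_eig``; the achieved partial
    correlations (shrunk by the loading) are stored as the usable truth.
    """
    if not 0.0 <= within_density <= 1.0:
        raise ValueError("within_density must lie in [0, 1]")
    p = int(sum(blocks))
    rng = np.random.default_rng(seed)
    target = np.zeros((p, p))
    labels = np.concatenate(
        [np.full(size, b + 1, dtype=np.int64) for b, size in enumerate(blocks)]
    )

    lo, hi = within_weight_range
    start = 0
    for size in blocks:
        nodes = np.arange(start, start + size)
        start += size
        if size < 2 or within_density == 0.0:
            continue
        pairs = [(i, j) for a, i in enumerate(nodes) for j in nodes[a + 1:]]
        n_target = int(round(within_density * len(pairs)))
        chosen: set[tuple[int, int]] = set()
        # random spanning tree keeps every planted block connected
        order = rng.permutation(nodes)
        for t in range(1, size):
            u = order[t]
            v = order[rng.integers(0, t)]
            chosen.add((min(u, v), max(u, v)))
        remaining = [pr for pr in pairs if pr not in chosen]
        extra = max(0, n_target - len(chosen))
        if extra and remaining:
            picks = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
            chosen.update(remaining[i] for i in picks)
        for i, j in chosen:
            target[i, j] = target[j, i] = rng.uniform(lo, hi)

    cross = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if labels[i] != labels[j]
    ]
    if bridge_count and cross:
        picks = rng.choice(len(cross), size=min(bridge_count, len(cross)), replace=False)
        for idx in picks:
            i, j = cross[idx]
            target[i, j] = target[j, i] = bridge_weight

    return spec_from_partials(
        target,
        labels=labels,
        marginals=marginals,
        item_codes=item_codes,
        min_eig=min_eig,
        seed=seed,
    )


def sample_ordinal(
    spec: SyntheticSpec, n: int, seed: int | None = None
) -> SyntheticDataset:
    """Draw n subjects: latent Gaussian with the spec's correlation, then
    per-item discretization through the marginal-matching thresholds."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(spec.latent_corr)
    Z = rng.standard_normal((n, spec.p)) @ L.T
    X = np.empty((n, spec.p), dtype=np.int64)
    for j, cuts in enumerate(spec.thresholds()):
        X[:, j] = 1 + np.searchsorted(cuts, Z[:, j])
    data = OrdinalResponseMatrix(values=X, item_codes=spec.item_codes, K=spec.K)
    return SyntheticDataset(data=data, spec=spec)
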