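"""Spin-glass community detection by simulated annealing.

Communities are found by minimizing the configuration-null Potts Hamiltonian

    H(sigma) = -sum_{i<j} (a_ij - gamma * s_i s_j / (2m)) * delta(sigma_i, sigma_j)

on absolute edge weights a_ij = |w_ij| (s_i is node strength, m the total
edge mass). Within-community edge mass beyond its null expectation lowers H.
Optimization is single-node-update Metropolis annealing with a geometric
cooling schedule, best-visited-state tracking and multiple restarts; the
result is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import RegularizedNetwork

__all__ = ["CommunityPartition", "hamiltonian", "spinglass_partition"]


def _abs_adjacency(net: RegularizedNetwork | np.ndarray) -> np.ndarray:
    W = net.weights if isinstance(net, RegularizedNetwork) else np.asarray(net)
    return np.abs(W)


def _null_matrix(a: np.ndarray, gamma_spin: float) -> np.ndarray:
    """B_ij = a_ij - gamma * s_i s_j / (2m), the per-pair Hamiltonian gain."""
    s = a.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        raise ValueError("no community structure estimable: network has no edges")
    B = a - gamma_spin * np.outer(s, s) / two_m
    np.fill_diagonal(B, 0.0)
    return B


def hamiltonian(
    net: RegularizedNetwork | np.ndarray,
    labels: np.ndarray,
    gamma_spin: float = 0.5,
) -> float:
    """Evaluate H(sigma) for an arbitrary labeling (any integer labels)."""
    a = _abs_adjacency(net)
    labels = np.asarray(labels)
    if labels.shape != (a.shape[0],):
        raise ValueError("labels must assign one community per node")
    B = _null_matrix(a, gamma_spin)
    same = labels[:, None] == labels[None, :]
    return float(-B[same].sum() / 2.0)  # each unordered pair counted once


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..q in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass(frozen=True)
class CommunityPartition:
    """Annealed partition: contiguous labels 1..q and the final Hamiltonian."""

    labels: np.ndarray
    hamiltonian: float
    gamma_spin: float
    seed: int | None
    restarts: int
    item_codes: tuple[str, ...] | None = None
    trace: tuple[tuple[float, float], ...] = ()  # (temperature, best H)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self) -> dict[int, tuple[str, ...]]:
        codes = self.item_codes or tuple(
            f"V{i + 1}" for i in range(len(self.labels))
        )
        return {
            c: tuple(codes[i] for i in np.flatnonzero(self.labels == c))
            for c in range(1, self.n_communities + 1)
        }

    def summary(self) -> dict:
        return {
            "n_communities": self.n_communities,
            "sizes": [int((self.labels == c).sum()) for c in range(1, self.n_communities + 1)],
            "members": {str(c): list(v) for c, v in self.members().items()},
            "hamiltonian": self.hamiltonian,
            "gamma_spin": self.gamma_spin,
            "seed": self.seed,
            "restarts": self.restarts,
        }


def _anneal_once(
    B_rows: list[list[float]],
    p: int,
    spins: int,
    t_start: float,
    t_stop: float,
    cooling: float,
    rng: np.random.Generator,
    collect_trace: bool,
) -> tuple[np.ndarray, float, list[tuple[float, float]]]:
    labels = rng.integers(0, spins, size=p)
    # community_sums[c][v] = sum of B[u][v] over nodes u currently in c
    community_sums = [[0.0] * p for _ in range(spins)]
    for u in range(p):
        row = B_rows[u]
        acc = community_sums[labels[u]]
        for v in range(p):
            acc[v] += row[v]
    H = 0.0
    for i in range(p):
        acc = community_sums[labels[i]]
        H -= acc[i] - B_rows[i][i]
    H /= 2.0

    labels = labels.tolist()
    best_H = H
    best_labels = list(labels)
    trace: list[tuple[float, float]] = []

    n_temps = int(math.ceil(math.log(t_stop / t_start) / math.log(cooling)))
    proposals_per_temp = p * spins
    total = n_temps * proposals_per_temp
    nodes = rng.integers(0, p, size=total)
    targets = rng.integers(0, spins, size=total)
    uniforms = rng.random(size=total)

    T = t_start
    idx = 0
    exp = math.exp
    for _ in range(n_temps):
        for _ in range(proposals_per_temp):
            v = int(nodes[idx])
            new = int(targets[idx])
            u01 = uniforms[idx]
            idx += 1
            old = labels[v]
            if new == old:
                continue
            gain_old = community_sums[old][v]  # includes B[v][v] = 0
            gain_new = community_sums[new][v]
            dH = -(gain_new - gain_old)
            if dH <= 0.0 or u01 < exp(-dH / T):
                row = B_rows[v]
                acc_old = community_sums[old]
                acc_new = community_sums[new]
                for j in range(p):
                    acc_old[j] -= row[j]
                    acc_new[j] += row[j]
                labels[v] = new
                H += dH
                if H < best_H:
                    best_H = H
                    best_labels = list(labels)
        if collect_trace:
            trace.append((T, best_H))
        T *= cooling
    return np.array(best_labels), best_H, trace


def spinglass_partition(
    net: RegularizedNetwork | np.ndarray,
    gamma_spin: float = 0.5,
    spins: int = 17,
    t_start: float = 1.0,
    t_stop: float = 0.01,
    cooling: float = 0.99,
    seed: int | None = 2016,
    restarts: int = 10,
    item_codes: tuple[str, ...] | None = None,
    collect_trace: bool = False,
) -> CommunityPartition:
    """Anneal the Potts Hamiltonian and return the best partition found.

    At each temperature, p * spins single-node label changes are proposed and
    accepted with probability min(1, exp(-dH / T)); the temperature is
    multiplied by ``cooling`` until it falls below ``t_stop``. The best state
    ever visited is kept, over ``restarts`` independent restarts.
    """
    if not 0.0 < cooling < 1.0:
        raise ValueError("cooling factor must lie in (0, 1)")
    if not t_stop < t_start:
        raise ValueError("stop temperature must be below start temperature")
    a = _abs_adjacency(net)
    if isinstance(net, RegularizedNetwork) and item_codes is None:
        item_codes = net.item_codes
    B = _null_matrix(a, gamma_spin)
    B_rows = [row.tolist() for row in B]
    p = a.shape[0]
    spins = min(spins, p) if spins > 0 else p

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list] | None = None
    for _ in range(restarts):
        labels, H, trace = _anneal_once(
            B_rows, p, spins, t_start, t_stop, cooling, rng, collect_trace
        )
        if best is None or H < best[1]:
            best = (labels, H, trace)
    labels, H, trace = best
    return CommunityPartition(
        labels=_relabel_contiguous(labels),
        hamiltonian=H,
        gamma_spin=gamma_spin,
        seed=seed,
        restarts=restarts,
        item_codes=item_codes,
        trace=tuple(trace),
    )
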