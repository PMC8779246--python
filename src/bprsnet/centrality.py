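"""Node centrality on the weighted partial-correlation network.

Strength is the sum of absolute edge weights at a node. Closeness and
betweenness operate on shortest paths with edge length 1/|weight| (strong
associations are short); closeness is (p-1) divided by the total distance to
the other nodes of the node's connected component, and betweenness is the
unnormalized count of shortest source-target pairs routed through the node,
with ties split fractionally. Standardized (z) scores accompany the raw
metrics for scale-free reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import RegularizedNetwork

__all__ = [
    "CentralityTable",
    "strength",
    "shortest_path_metrics",
    "centrality_table",
]

CENTRALITY_INDICES = ("strength", "closeness", "betweenness")


def strength(net: RegularizedNetwork) -> np.ndarray:
    """s_i = sum_j |w_ij|."""
    return np.abs(net.weights).sum(axis=1)


def _length_graph(net: RegularizedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    iu, ju = np.triu_indices(net.p, k=1)
    for i, j in zip(iu, ju):
        w = net.weights[i, j]
        if w != 0:
            G.add_edge(int(i), int(j), length=1.0 / abs(w))
    return G


def shortest_path_metrics(
    net: RegularizedNetwork, closeness_variant: str = "reciprocal-total"
) -> tuple[np.ndarray, np.ndarray]:
    """(closeness, betweenness) under the 1/|w| distance transform.

    ``closeness_variant``: "reciprocal-total" gives (p-1)/sum of distances
    within the node's component; "harmonic" gives the mean of 1/dist over all
    other nodes (unreachable nodes contribute 0). Isolated nodes score 0 on
    both metrics either way.
    """
    G = _length_graph(net)
    p = net.p
    closeness = np.zeros(p)
    for i in range(p):
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        del dist[i]
        if not dist:
            continue
        if closeness_variant == "reciprocal-total":
            closeness[i] = (p - 1) / sum(dist.values())
        elif closeness_variant == "harmonic":
            closeness[i] = sum(1.0 / d for d in dist.values()) / (p - 1)
        else:
            raise ValueError(f"unknown closeness variant '{closeness_variant}'")
    bet = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([bet[i] for i in range(p)])
    return closeness, betweenness


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        warnings.warn(
            "metric has zero variance across nodes; z-scores set to 0",
            stacklevel=3,
        )
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class CentralityTable:
    """Raw and z-standardized strength/closeness/betweenness per node."""

    item_codes: tuple[str, ...]
    strength: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray

    def raw(self, index: str) -> np.ndarray:
        if index not in CENTRALITY_INDICES:
            raise ValueError(f"unknown centrality index '{index}'")
        return getattr(self, index)

    def z(self, index: str) -> np.ndarray:
        return _zscore(self.raw(index))

    @property
    def rank_strength(self) -> np.ndarray:
        """Rank 1 = highest strength."""
        order = np.argsort(-self.strength, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    def top_node(self, index: str = "strength") -> str:
        return self.item_codes[int(np.argmax(self.raw(index)))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.item_codes),
                "strength": self.strength,
                "closeness": self.closeness,
                "betweenness": self.betweenness,
                "z_strength": self.z("strength"),
                "z_closeness": self.z("closeness"),
                "z_betweenness": self.z("betweenness"),
                "rank_strength": self.rank_strength,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def centrality_table(
    net: RegularizedNetwork, closeness_variant: str = "reciprocal-total"
) -> CentralityTable:
    closeness, betweenness = shortest_path_metrics(net, closeness_variant)
    return CentralityTable(
        item_codes=net.item_codes,
        strength=strength(net),
        closeness=closeness,
        betweenness=betweenness,
    )
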