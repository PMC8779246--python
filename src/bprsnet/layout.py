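"""Force-directed (Fruchterman-Reingold) node placement.

Attraction is proportional to |edge weight|, so strongly associated symptoms
land close together; coordinates are rescaled into the unit square. The
iteration is networkx's spring layout, deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import RegularizedNetwork

__all__ = ["LayoutResult", "fr_layout"]


@dataclass(frozen=True)
class LayoutResult:
    coordinates: np.ndarray  # p x 2, inside [0, 1]^2
    item_codes: tuple[str, ...]
    iterations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.item_codes),
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fr_layout(
    net: RegularizedNetwork, iterations: int = 500, seed: int | None = 0
) -> LayoutResult:
    G = net.to_graph(absolute=True)
    if net.p == 1:
        coords = np.array([[0.5, 0.5]])
    else:
        pos = nx.spring_layout(
            G, weight="weight", iterations=iterations, seed=seed
        )
        coords = np.array([pos[c] for c in net.item_codes])
        span = coords.max(axis=0) - coords.min(axis=0)
        span[span == 0] = 1.0
        coords = (coords - coords.min(axis=0)) / span
    return LayoutResult(
        coordinates=coords,
        item_codes=net.item_codes,
        iterations=iterations,
        seed=seed,
    )
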