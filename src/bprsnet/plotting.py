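"""Best-effort network figure: positive edges green, negative red, width
proportional to |weight|, nodes at force-directed positions."""

from __future__ import annotations

from pathlib import Path

from .layout import fr_layout
from .network import RegularizedNetwork

__all__ = ["plot_network"]


def plot_network(
    net: RegularizedNetwork,
    path: str | Path,
    labels=None,
    seed: int | None = 0,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout = fr_layout(net, seed=seed)
    coords = layout.coordinates
    fig, ax = plt.subplots(figsize=(6, 6))
    p = net.p
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w == 0:
                continue
            ax.plot(
                [coords[i, 0], coords[j, 0]],
                [coords[i, 1], coords[j, 1]],
                color="forestgreen" if w > 0 else "firebrick",
                linewidth=6 * abs(w),
                alpha=0.7,
                zorder=1,
            )
    colors = None
    if labels is not None:
        cmap = plt.get_cmap("tab10")
        colors = [cmap((lab - 1) % 10) for lab in labels]
    ax.scatter(coords[:, 0], coords[:, 1], s=450, c=colors or "lightsteelblue",
               edgecolors="black", zorder=2)
    for code, (x, y) in zip(net.item_codes, coords):
        ax.annotate(code, (x, y), ha="center", va="center", fontsize=7, zorder=3)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
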