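"""Minimal tanglegram drawing (matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import TanglegramLayout
from .trees import Node, Tree

__all__ = ["plot_tanglegram"]

_GROUP_COLORS = {
    "mammal": "#1f3b99",
    "bird": "#7fd07f",
    "reptile": "#79c8e0",
    "amphibian": "#79c8e0",
    "fish": "#d62728",
    "invertebrate": "#e377c2",
    "plant": "#1a6b1a",
}


def _layout_coords(tree: Tree, order: tuple[str, ...], mirrored: bool):
    """x (depth level) and y (leaf rank) coordinates per node."""
    ypos = {lab: i for i, lab in enumerate(order)}
    xs: dict[int, float] = {}
    ys: dict[int, float] = {}

    def depth(nd: Node) -> int:
        if nd.is_leaf:
            return 0
        return 1 + max(depth(c) for c in nd.children)

    total = max(depth(tree.root), 1)

    def walk(nd: Node, level: int) -> float:
        if nd.is_leaf:
            xs[id(nd)] = float(total)
            ys[id(nd)] = float(ypos[nd.label])
            return ys[id(nd)]
        kid_ys = [walk(c, level + 1) for c in nd.children]
        xs[id(nd)] = float(level)
        ys[id(nd)] = sum(kid_ys) / len(kid_ys)
        return ys[id(nd)]

    walk(tree.root, 0)
    if mirrored:
        for k in xs:
            xs[k] = total - xs[k]
    return xs, ys, total


def _draw(ax, tree: Tree, order, x_offset: float, mirrored: bool, scale: float):
    xs, ys, total = _layout_coords(tree, order, mirrored)
    for nd in tree.postorder():
        if nd.is_leaf:
            continue
        for c in nd.children:
            x0 = x_offset + xs[id(nd)] / total * scale
            x1 = x_offset + xs[id(c)] / total * scale
            ax.plot([x0, x0], [ys[id(nd)], ys[id(c)]], color="0.3", lw=1)
            ax.plot([x0, x1], [ys[id(c)], ys[id(c)]], color="0.3", lw=1)
    return {lab: i for i, lab in enumerate(order)}


def plot_tanglegram(
    host: Tree,
    virus: Tree,
    layout: TanglegramLayout,
    path: str | Path,
    host_groups: dict[str, str] | None = None,
) -> None:
    """Render host (left) and virus (right) trees with association lines.

    ``host_groups`` optionally maps host tip labels to host-type names used
    to color the lines (mammal, bird, fish, ...).
    """
    n = max(len(layout.host_order), len(layout.virus_order))
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.22 * n)))
    scale = 0.35
    _draw(ax, host, layout.host_order, 0.0, False, scale)
    _draw(ax, virus, layout.virus_order, 1.0 - scale, True, scale)

    hpos = {lab: i for i, lab in enumerate(layout.host_order)}
    vpos = {lab: i for i, lab in enumerate(layout.virus_order)}
    for v, h in layout.association.items():
        color = "0.6"
        if host_groups:
            color = _GROUP_COLORS.get(host_groups.get(h, "").lower(), "0.6")
        ax.plot([scale, 1.0 - scale], [hpos[h], vpos[v]], color=color, lw=0.8)

    for lab, i in hpos.items():
        ax.text(scale + 0.005, i, lab, fontsize=6, va="center", ha="left")
    for lab, i in vpos.items():
        ax.text(1.0 - scale - 0.005, i, lab, fontsize=6, va="center", ha="right")
    ax.set_axis_off()
    ax.set_title(f"crossings = {layout.crossings}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
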