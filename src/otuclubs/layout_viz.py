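"""Fruchterman-Reingold layout and network/heat-map rendering.

The layout is the classic force-directed scheme: every node pair repels with
force k^2/d, every edge attracts with force |w| * d^2/k (attraction scales
with the magnitude of the correlation, so strongly negative pairs also
co-locate), displacements are capped by a linearly cooling temperature, and
positions stay inside a square frame.  k = C * sqrt(area / n).

Rendering follows the network conventions: green edges for positive
correlations, red for negative, thickness proportional to |r|, node radius
from mean log abundance, node color either a blue-to-red differential
abundance heat scale or club membership (leaders starred).  Edges with
|weight| below the display threshold are omitted from the drawing only —
they never affect clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .clubs import ClubPartition
from .corrnet import CorrelationResult

__all__ = [
    "LayoutPositions",
    "fruchterman_reingold",
    "render_network",
    "club_heatmap",
    "visible_edges",
    "CLUB_PALETTE",
]

DEFAULT_DISPLAY_THRESHOLD = 0.2

# deterministic palette, assigned to clubs by decreasing size
CLUB_PALETTE = [
    "#d62728", "#1f77b4", "#2ca02c", "#7f7f7f", "#bcbd22",
    "#9467bd", "#8c564b", "#e377c2", "#17becf", "#ff7f0e",
]


@dataclass
class LayoutPositions:
    """2-D coordinates per node inside a [0, side] x [0, side] frame."""

    positions: dict[str, tuple[float, float]]
    seed: int
    iterations: int
    side: float

    def __getitem__(self, node: str) -> tuple[float, float]:
        return self.positions[node]

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.positions[n] for n in nodes])


def fruchterman_reingold(
    net: nx.Graph,
    seed: int,
    iterations: int = 500,
    area: float = 1.0,
    c: float = 1.0,
) -> LayoutPositions:
    """Deterministic weighted Fruchterman-Reingold layout.

    Attraction along an edge scales with |weight|; repulsion acts between
    all pairs; the per-step displacement is capped by a temperature that
    cools linearly to zero.  Identical seed, network, and parameters give
    bitwise-identical positions.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("network has no nodes")
    side = float(np.sqrt(area))
    if n == 1:
        return LayoutPositions({nodes[0]: (side / 2, side / 2)}, seed, iterations, side)

    k = c * np.sqrt(area / n)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, side, size=(n, 2))

    index = {node: i for i, node in enumerate(nodes)}
    if net.number_of_edges() > 0:
        eu, ev, ew = zip(
            *((index[u], index[v], abs(d["weight"])) for u, v, d in net.edges(data=True))
        )
        eu = np.array(eu)
        ev = np.array(ev)
        ew = np.array(ew, dtype=float)
    else:
        eu = ev = np.array([], dtype=int)
        ew = np.array([], dtype=float)

    t0 = 0.1 * side
    eps = 1e-12
    for step in range(iterations):
        t = t0 * (1.0 - step / iterations)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=-1))
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, eps)
        # repulsion k^2/d along the unit vector away from the other node:
        # (delta/d) * k^2/d = delta * k^2/d^2
        disp = (delta * (k**2 / dist**2)[..., None]).sum(axis=1)
        if eu.size:
            dvec = pos[eu] - pos[ev]
            d = np.maximum(np.sqrt((dvec**2).sum(axis=1)), eps)
            f = ew * d**2 / k  # attraction magnitude
            pull = dvec / d[:, None] * f[:, None]
            np.add.at(disp, eu, -pull)
            np.add.at(disp, ev, pull)
        length = np.maximum(np.sqrt((disp**2).sum(axis=1)), eps)
        step_len = np.minimum(length, t)
        pos = pos + disp / length[:, None] * step_len[:, None]
        np.clip(pos, 0.0, side, out=pos)

    positions = {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}
    return LayoutPositions(positions, seed, iterations, side)


def visible_edges(
    net: nx.Graph, display_threshold: float = DEFAULT_DISPLAY_THRESHOLD
) -> list[tuple[str, str, float]]:
    """Edges that survive the display-only weak-correlation filter."""
    return [
        (u, v, d["weight"])
        for u, v, d in net.edges(data=True)
        if abs(d["weight"]) >= display_threshold
    ]


def _node_radii(net: nx.Graph, lo: float = 40.0, hi: float = 400.0) -> np.ndarray:
    """Affine rescale of mean log abundance to a legible marker-size range."""
    sizes = np.array([d.get("size", 0.0) for _, d in net.nodes(data=True)], dtype=float)
    span = sizes.max() - sizes.min()
    if span == 0:
        return np.full(len(sizes), (lo + hi) / 2)
    return lo + (sizes - sizes.min()) / span * (hi - lo)


def render_network(
    net: nx.Graph,
    pos: LayoutPositions,
    path: str | Path,
    color_mode: str = "heat",
    partition: ClubPartition | None = None,
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> Path:
    """Draw the network to an SVG/PNG file and return the path.

    ``color_mode="heat"`` colors nodes blue (no group difference) to red
    (significant difference) by the heat scalar; ``"clubs"`` colors by club
    with unassigned nodes light gray and each leader overplotted with a
    star.  Edges with |weight| < ``display_threshold`` are not drawn.
    """
    if color_mode not in ("heat", "clubs"):
        raise ValueError(f"unknown color_mode {color_mode!r}")
    if color_mode == "clubs" and partition is None:
        raise ValueError("clubs color mode requires a ClubPartition")
    nodes = list(net.nodes)
    missing = [n for n in nodes if n not in pos.positions]
    if missing:
        raise ValueError(f"positions missing for nodes: {missing[:5]}")
    xy = pos.as_array(nodes)

    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v, w in visible_edges(net, display_threshold):
        (x0, y0), (x1, y1) = pos[u], pos[v]
        ax.plot(
            [x0, x1],
            [y0, y1],
            color="#2ca02c" if w > 0 else "#d62728",
            linewidth=0.5 + 3.0 * abs(w),
            alpha=0.6,
            zorder=1,
        )
    radii = _node_radii(net)
    if color_mode == "heat":
        heat = np.array([d.get("heat", 0.0) for _, d in net.nodes(data=True)])
        sc = ax.scatter(
            xy[:, 0], xy[:, 1], s=radii, c=heat, cmap="coolwarm",
            vmin=0.0, vmax=1.0, edgecolors="black", linewidths=0.5, zorder=2,
        )
        fig.colorbar(sc, ax=ax, label="differential abundance (1 - p)", shrink=0.7)
    else:
        club_of = partition.club_of()
        colors = [
            CLUB_PALETTE[club_of[n] % len(CLUB_PALETTE)] if club_of.get(n, -1) >= 0
            else "#dddddd"
            for n in nodes
        ]
        ax.scatter(
            xy[:, 0], xy[:, 1], s=radii, c=colors,
            edgecolors="black", linewidths=0.5, zorder=2,
        )
        leaders = [c.leader for c in partition.clubs]
        if leaders:
            lxy = pos.as_array(leaders)
            ax.scatter(
                lxy[:, 0], lxy[:, 1], marker="*", s=180, c="black", zorder=3,
            )
    for n, (x, y) in zip(nodes, xy):
        ax.annotate(n, (x, y), fontsize=4, ha="center", va="bottom",
                    xytext=(0, 4), textcoords="offset points")
    ax.set_xlim(-0.05 * pos.side, 1.05 * pos.side)
    ax.set_ylim(-0.05 * pos.side, 1.05 * pos.side)
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def club_heatmap(
    c: CorrelationResult, partition: ClubPartition, path: str | Path
) -> Path:
    """Masked-correlation heat map with rows/columns grouped by club.

    Club members are contiguous (in club order), unassigned nodes last; a
    diverging scale centered at zero; tick labels tinted by club color.
    """
    order: list[str] = [m for club in partition.clubs for m in club.members]
    order += list(partition.unassigned)
    index = {otu: i for i, otu in enumerate(c.otu_ids)}
    unknown = [o for o in order if o not in index]
    if unknown:
        raise ValueError(f"partition nodes not in correlation result: {unknown[:5]}")
    perm = [index[o] for o in order]
    mat = c.masked_r[np.ix_(perm, perm)].copy()
    np.fill_diagonal(mat, 1.0)

    club_of = partition.club_of()
    fig, ax = plt.subplots(figsize=(9, 8))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-1.0, vmax=1.0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="masked Pearson r", shrink=0.8)
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=4)
    ax.set_yticklabels(order, fontsize=4)
    for tick, otu in zip(ax.get_xticklabels(), order):
        k = club_of.get(otu, -1)
        tick.set_color(CLUB_PALETTE[k % len(CLUB_PALETTE)] if k >= 0 else "#888888")
    for tick, otu in zip(ax.get_yticklabels(), order):
        k = club_of.get(otu, -1)
        tick.set_color(CLUB_PALETTE[k % len(CLUB_PALETTE)] if k >= 0 else "#888888")
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
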