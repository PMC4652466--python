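"""Bacterial clubs, club statistics, leaders, and the rival-club search.

A club is a Markov cluster of at least ``min_size`` (default 3) OTUs in the
significance-masked co-occurrence network; smaller clusters' members are
left unassigned.  Rival clubs come from a two-phase search: phase 1 clusters
the absolute-value correlation network into super-clubs, phase 2 re-clusters
each super-club with negative edges removed; sub-club pairs from one
super-club whose cross correlations are predominantly negative are reported
as rivals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .corrnet import network_weight_matrix
from .mcl import MclParams, mcl_cluster

__all__ = [
    "Club",
    "ClubPartition",
    "ClubStats",
    "RivalPair",
    "find_clubs",
    "club_stats",
    "find_rival_clubs",
    "write_clubs_tsv",
    "write_rivals_tsv",
    "write_club_summary_tsv",
]

MIN_CLUB_SIZE = 3
DEFAULT_NEG_FRACTION = 0.5
# phase 1 groups by interaction strength regardless of sign and therefore
# wants a coarser granularity than the sub-club pass
DEFAULT_SUPER_INFLATION = 1.7
DEFAULT_MIN_INTER_COVERAGE = 1.0 / 3.0


@dataclass
class Club:
    """A set of >= min_size co-occurring OTUs with its MCL leader."""

    members: list[str]
    leader: str
    color_index: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClubPartition:
    """Disjoint clubs plus the unassigned remainder of the node set."""

    clubs: list[Club]
    unassigned: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clubs:
            if seen & set(c.members):
                raise ValueError("clubs must be pairwise disjoint")
            if c.leader not in c.members:
                raise ValueError(f"leader {c.leader!r} not a member of its club")
            seen |= set(c.members)
        if seen & set(self.unassigned):
            raise ValueError("unassigned nodes overlap club members")

    def all_nodes(self) -> list[str]:
        out = [m for c in self.clubs for m in c.members]
        out.extend(self.unassigned)
        return out

    def club_of(self) -> dict[str, int]:
        """Node -> club index; unassigned nodes map to -1."""
        mapping = {m: k for k, c in enumerate(self.clubs) for m in c.members}
        mapping.update({n: -1 for n in self.unassigned})
        return mapping


@dataclass
class ClubStats:
    """Mean +/- sample SD of the nonzero (significance-retained) correlations
    within each club and between each club pair.

    ``intra[k] = (mean, sd, n_nonzero)``; ``inter[(j, k)]`` likewise for
    j < k.  Pairs with no nonzero cross correlations are (nan, nan, 0) —
    undefined, never zero.
    """

    intra: dict[int, tuple[float, float, int]]
    inter: dict[tuple[int, int], tuple[float, float, int]]


@dataclass
class RivalPair:
    """Two sub-clubs of one super-club with predominantly negative
    cross-correlations (inter mean < 0)."""

    club_a: tuple[str, ...]
    club_b: tuple[str, ...]
    super_club: int
    inter_mean: float
    inter_sd: float
    neg_fraction: float
    leader_a: str
    leader_b: str


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def _partition_from_mcl(
    nodes: list[str], weights: np.ndarray, params: MclParams, min_size: int
) -> ClubPartition:
    res = mcl_cluster(weights, params)
    clubs: list[Club] = []
    unassigned: list[str] = []
    sized = [
        (cl, res.leaders[k]) for k, cl in enumerate(res.clusters) if len(cl) >= min_size
    ]
    # colors by decreasing size; ties by smallest member index for determinism
    sized.sort(key=lambda cl_lead: (-len(cl_lead[0]), cl_lead[0][0]))
    for color, (cl, lead) in enumerate(sized):
        clubs.append(Club([nodes[i] for i in cl], nodes[lead], color))
    small = [cl for cl in res.clusters if len(cl) < min_size]
    for cl in small:
        unassigned.extend(nodes[i] for i in cl)
    unassigned.sort(key=nodes.index)
    return ClubPartition(clubs, unassigned)


def find_clubs(
    net: nx.Graph,
    params: MclParams = MclParams(),
    min_size: int = MIN_CLUB_SIZE,
    weight_mode: str = "positive",
) -> ClubPartition:
    """Markov-cluster the masked correlation network into clubs.

    ``weight_mode="positive"`` clamps negative correlations to zero before
    clustering (the default club definition: mutual positive co-occurrence);
    ``"absolute"`` uses |r| instead (the super-club weighting of the rival
    search).  Clusters of size >= ``min_size`` become clubs with their MCL
    leaders; smaller clusters' nodes are unassigned.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    nodes, w = network_weight_matrix(net)
    if net.number_of_edges() == 0:
        warnings.warn("network has no edges; all nodes unassigned", stacklevel=2)
        return ClubPartition([], list(nodes))
    if weight_mode == "positive":
        w = np.clip(w, 0.0, None)
    elif weight_mode == "absolute":
        w = np.abs(w)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return _partition_from_mcl(nodes, w, params, min_size)


def club_stats(net: nx.Graph, partition: ClubPartition) -> ClubStats:
    """Intra- and inter-club correlation summaries over nonzero entries.

    Only the significance-retained (nonzero masked) correlations enter the
    means; SD uses the n - 1 denominator.
    """
    nodes, w = network_weight_matrix(net)
    index = {n: i for i, n in enumerate(nodes)}
    for c in partition.clubs:
        for m in c.members:
            if m not in index:
                raise ValueError(f"club member {m!r} not in network")
    intra: dict[int, tuple[float, float, int]] = {}
    inter: dict[tuple[int, int], tuple[float, float, int]] = {}
    member_idx = [np.array([index[m] for m in c.members]) for c in partition.clubs]
    for k, idx in enumerate(member_idx):
        block = w[np.ix_(idx, idx)]
        vals = block[np.triu_indices(len(idx), k=1)]
        intra[k] = _mean_sd(vals[vals != 0])
    for j in range(len(member_idx)):
        for k in range(j + 1, len(member_idx)):
            cross = w[np.ix_(member_idx[j], member_idx[k])].ravel()
            inter[(j, k)] = _mean_sd(cross[cross != 0])
    return ClubStats(intra, inter)


def find_rival_clubs(
    net: nx.Graph,
    params: MclParams = MclParams(),
    min_size: int = MIN_CLUB_SIZE,
    neg_fraction: float = DEFAULT_NEG_FRACTION,
    super_inflation: float = DEFAULT_SUPER_INFLATION,
    min_inter_coverage: float = DEFAULT_MIN_INTER_COVERAGE,
) -> list[RivalPair]:
    """Two-phase rival-club detection.

    Phase 1: Markov clustering of the |r| network at ``super_inflation``
    (coarser than the sub-club pass, since sign is ignored and
    anti-correlated blocks must merge) yields super-clubs.  Phase 2: within
    each super-club, Markov clustering of the positive-only submatrix at
    ``params.inflation`` yields sub-clubs.  Every unordered pair of
    sub-clubs (each >= ``min_size``) from one super-club is reported iff

    * at least ``min_inter_coverage`` of its cross member pairs carry a
      nonzero (significance-retained) correlation — "many" cross
      correlations must actually exist,
    * the mean of the nonzero cross correlations is negative, and
    * at least ``neg_fraction`` of them are negative.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    if net.number_of_edges() == 0:
        return []
    nodes, w = network_weight_matrix(net)
    phase1 = MclParams(
        expansion=params.expansion,
        inflation=super_inflation,
        self_loop=params.self_loop,
        prune_below=params.prune_below,
        max_iter=params.max_iter,
        tol=params.tol,
    )
    super_res = mcl_cluster(np.abs(w), phase1)
    rivals: list[RivalPair] = []
    for sc_id, super_cl in enumerate(super_res.clusters):
        if len(super_cl) < 2 * min_size:
            continue  # cannot hold two sub-clubs
        idx = np.array(super_cl)
        sub_w = np.clip(w[np.ix_(idx, idx)], 0.0, None)
        sub_nodes = [nodes[i] for i in super_cl]
        sub_part = _partition_from_mcl(sub_nodes, sub_w, params, min_size)
        if len(sub_part.clubs) < 2:
            continue
        for a in range(len(sub_part.clubs)):
            for b in range(a + 1, len(sub_part.clubs)):
                ca, cb = sub_part.clubs[a], sub_part.clubs[b]
                ia = np.array([nodes.index(m) for m in ca.members])
                ib = np.array([nodes.index(m) for m in cb.members])
                cross = w[np.ix_(ia, ib)].ravel()
                nz = cross[cross != 0]
                if nz.size == 0 or nz.size / cross.size < min_inter_coverage:
                    continue
                mean, sd, _ = _mean_sd(nz)
                frac_neg = float((nz < 0).mean())
                if mean < 0 and frac_neg >= neg_fraction:
                    rivals.append(
                        RivalPair(
                            tuple(ca.members),
                            tuple(cb.members),
                            sc_id,
                            mean,
                            sd,
                            frac_neg,
                            ca.leader,
                            cb.leader,
                        )
                    )
    return rivals


def write_clubs_tsv(partition: ClubPartition, path: str | Path) -> None:
    rows = []
    for k, c in enumerate(partition.clubs):
        for m in c.members:
            rows.append(
                {"otu_id": m, "club_id": k, "is_leader": int(m == c.leader)}
            )
    for m in partition.unassigned:
        rows.append({"otu_id": m, "club_id": -1, "is_leader": 0})
    pd.DataFrame(rows, columns=["otu_id", "club_id", "is_leader"]).to_csv(
        path, sep="\t", index=False
    )


def write_rivals_tsv(rivals: list[RivalPair], path: str | Path) -> None:
    rows = [
        {
            "club_a": ",".join(r.club_a),
            "club_b": ",".join(r.club_b),
            "super_club": r.super_club,
            "inter_mean": r.inter_mean,
            "inter_sd": r.inter_sd,
            "neg_fraction": r.neg_fraction,
        }
        for r in rivals
    ]
    pd.DataFrame(
        rows,
        columns=["club_a", "club_b", "super_club", "inter_mean", "inter_sd", "neg_fraction"],
    ).to_csv(path, sep="\t", index=False)


def write_club_summary_tsv(
    net: nx.Graph,
    partition: ClubPartition,
    path: str | Path,
    top_k: int = 5,
) -> None:
    """Per-club summary: the top-k most abundant members plus intra stats."""
    stats = club_stats(net, partition)
    size_of = nx.get_node_attributes(net, "size")
    rows = []
    for k, c in enumerate(partition.clubs):
        top = sorted(c.members, key=lambda m: -size_of.get(m, 0.0))[:top_k]
        mean, sd, n = stats.intra[k]
        rows.append(
            {
                "club_id": k,
                "size": len(c.members),
                "leader": c.leader,
                "top_members": ",".join(top),
                "intra_mean": mean,
                "intra_sd": sd,
                "n_significant": n,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "club_id", "size", "leader", "top_members",
            "intra_mean", "intra_sd", "n_significant",
        ],
    ).to_csv(path, sep="\t", index=False)
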