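"""Markov clustering (MCL) on non-negative weighted graphs, from scratch.

The algorithm simulates flow on the graph: the weight matrix (plus self
loops) is column-normalized to a stochastic matrix, then alternately
expanded (matrix power) and inflated (entrywise power followed by column
renormalization) until the matrix stops changing.  Clusters are read off the
converged matrix; the nodes where flow terminates (positive diagonal) are
the attractors, and the attractor with the largest diagonal entry in each
cluster is the cluster's leader.

Everything here is deterministic: identical input and parameters produce
identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MclParams", "MclResult", "inflate", "mcl_cluster"]


@dataclass(frozen=True)
class MclParams:
    """Tuning knobs for Markov clustering.

    inflation > 1 controls granularity (larger -> finer clusters);
    expansion >= 2 is the matrix-power step; self_loop is added to every
    diagonal entry before normalization; entries below prune_below are
    dropped after each inflation.
    """

    expansion: int = 2
    inflation: float = 2.0
    self_loop: float = 1.0
    prune_below: float = 1e-6
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.self_loop < 0:
            raise ValueError("self_loop must be non-negative")
        if self.prune_below < 0:
            raise ValueError("prune_below must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class MclResult:
    """Partition of the node indices with attractors and leaders.

    ``clusters`` is a list of sorted index lists forming a partition of
    range(n).  ``attractors[k]`` are the attractor indices of cluster k
    (non-empty), ``leaders[k]`` the single leader.  ``cluster_of[i]`` maps a
    node index to its cluster index.
    """

    clusters: list[list[int]]
    attractors: list[list[int]]
    leaders: list[int]
    converged_matrix: np.ndarray
    iterations: int
    converged: bool
    cluster_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cluster_of:
            self.cluster_of = {
                i: k for k, cl in enumerate(self.clusters) for i in cl
            }


def inflate(column: np.ndarray, r: float) -> np.ndarray:
    """Entrywise power ``r`` followed by renormalization to sum 1."""
    col = np.asarray(column, dtype=float)
    if np.any(col < 0):
        raise ValueError("column must be non-negative")
    total = col.sum()
    if total <= 0:
        raise ValueError("cannot inflate an all-zero column")
    powered = col**r
    return powered / powered.sum()


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("matrix has an all-zero column; add self loops")
    return m / sums


def _inflate_matrix(m: np.ndarray, r: float) -> np.ndarray:
    powered = m**r
    return powered / powered.sum(axis=0)


def mcl_cluster(weights: np.ndarray, params: MclParams = MclParams()) -> MclResult:
    """Cluster a non-negative symmetric weight matrix with zero diagonal.

    Iterates column-normalize -> expand -> inflate -> prune until the
    maximum entry change between successive iterations falls below
    ``params.tol`` or ``params.max_iter`` is reached (in which case the
    result carries ``converged=False`` and a warning is emitted).

    Cluster readout from the converged matrix T: attractors are nodes i with
    T[i, i] > tol; node j joins the cluster of the attractor i maximizing
    T[i, j] (ties -> lowest attractor index); attractor-to-attractor
    assignments are followed to a fixed point so mutually attracting nodes
    share one cluster.  Each cluster's leader is its attractor with the
    largest diagonal entry (ties -> lowest index).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weights must be symmetric")
    n = w.shape[0]
    if n == 0:
        return MclResult([], [], [], np.zeros((0, 0)), 0, True)

    a = w.copy()
    np.fill_diagonal(a, np.diag(a) + params.self_loop)
    m = _normalize_columns(a)

    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _inflate_matrix(m, params.inflation)
        m[m < params.prune_below] = 0.0
        m = _normalize_columns(m)
        if np.max(np.abs(m - prev)) < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iter} iterations "
            f"(max change still >= {params.tol})",
            stacklevel=2,
        )

    diag = np.diag(m)
    attractor_idx = np.flatnonzero(diag > params.tol)
    if attractor_idx.size == 0:
        # pathological (e.g. pruned to a permutation); treat max-diag node
        # of each column as attractor of itself
        attractor_idx = np.array([int(np.argmax(diag))])

    # each node joins the attractor receiving its largest flow (row = target)
    flows = m[attractor_idx, :]
    best = attractor_idx[np.argmax(flows, axis=0)]  # argmax is first-max: lowest index

    # resolve attractor -> attractor chains to a fixed point
    assign = {int(i): int(best[i]) for i in range(n)}

    def root(i: int) -> int:
        seen = []
        while True:
            seen.append(i)
            j = assign[i]
            if j == i:
                break
            if j in seen:  # cycle: collapse to the smallest member
                i = min(seen[seen.index(j):])
                break
            i = j
        for s in seen:
            assign[s] = i
        return i

    cluster_map: dict[int, list[int]] = {}
    for i in range(n):
        cluster_map.setdefault(root(i), []).append(i)

    # deterministic cluster order: by smallest member index
    roots = sorted(cluster_map, key=lambda r: min(cluster_map[r]))
    clusters: list[list[int]] = []
    attractors: list[list[int]] = []
    leaders: list[int] = []
    attractor_set = set(attractor_idx.tolist())
    for r in roots:
        members = sorted(cluster_map[r])
        atts = [i for i in members if i in attractor_set]
        if not atts:
            atts = [members[int(np.argmax(diag[members]))]]
        lead = max(atts, key=lambda i: (diag[i], -i))
        clusters.append(members)
        attractors.append(atts)
        leaders.append(lead)
    return MclResult(clusters, attractors, leaders, m, it, converged)
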