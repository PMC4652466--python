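"""Significance-masked Pearson co-occurrence networks.

Pairwise Pearson correlations of log relative abundances across samples,
two-sided p-values from the t-distribution with n - 2 degrees of freedom,
Benjamini-Hochberg adjustment over all distinct OTU pairs of the network,
and zeroing of every correlation whose adjusted value exceeds ``mask_alpha``
(default 0.25).  The masked matrix becomes an undirected signed weighted
graph whose nodes carry mean-log-abundance and differential-abundance
annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

__all__ = [
    "CorrelationResult",
    "bh_adjust",
    "correlation_with_significance",
    "build_network",
    "network_weight_matrix",
    "write_edge_tsv",
    "write_node_tsv",
    "write_graphml",
]

DEFAULT_MASK_ALPHA = 0.25


@dataclass
class CorrelationResult:
    """Symmetric correlation, p-value, and BH-q matrices over the OTU set.

    ``masked_r`` equals ``r`` with every entry whose q-value exceeds
    ``mask_alpha`` set to zero (strict inequality: zeroed iff q > alpha).
    The diagonal of ``r`` is exactly 1; the diagonal of ``masked_r`` is 0
    (self-correlations are never network edges).
    """

    otu_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    masked_r: np.ndarray
    mask_alpha: float
    n_samples: int


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values for one family of tests."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def correlation_with_significance(
    x: NormalizedMatrix, mask_alpha: float = DEFAULT_MASK_ALPHA
) -> CorrelationResult:
    """Pearson correlations with BH-FDR masking over all OTU pairs.

    Requires at least 3 samples and 2 OTUs.  An OTU column with zero
    variance yields undefined correlations; these are set to r = 0, p = 1
    with a warning rather than aborting.
    """
    n, m = x.values.shape
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    if m < 2:
        raise ValueError(f"need >= 2 OTUs for correlation, got {m}")

    v = x.values
    sd = v.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance OTU(s); their correlations "
            "are set to 0 with p = 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)

    # two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n - 2
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(m, k=1)
    q = np.ones_like(p)
    q_flat = bh_adjust(p[iu])
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(q, 0.0)

    masked = np.where(q > mask_alpha, 0.0, r)
    np.fill_diagonal(masked, 0.0)
    return CorrelationResult(list(x.otu_ids), r, p, q, masked, mask_alpha, n)


def build_network(
    c: CorrelationResult,
    mean_log_abundance: np.ndarray | None = None,
    heat: np.ndarray | None = None,
) -> nx.Graph:
    """Turn a masked correlation matrix into an undirected annotated graph.

    One edge per nonzero masked correlation (stored once, i < j), carrying
    the signed weight, its magnitude, sign label, and q-value.  Nodes are the
    OTU labels annotated with ``size`` (mean log abundance) and ``heat``
    (differential-abundance scalar); both default to zeros when not given.
    """
    m = len(c.otu_ids)
    if mean_log_abundance is None:
        mean_log_abundance = np.zeros(m)
    if heat is None:
        heat = np.zeros(m)
    mean_log_abundance = np.asarray(mean_log_abundance, dtype=float)
    heat = np.asarray(heat, dtype=float)
    if mean_log_abundance.shape != (m,) or heat.shape != (m,):
        raise ValueError(
            f"node annotations must have length {m}, got "
            f"{mean_log_abundance.shape} and {heat.shape}"
        )
    g = nx.Graph(mask_alpha=c.mask_alpha, n_samples=c.n_samples)
    for j, otu in enumerate(c.otu_ids):
        g.add_node(otu, size=float(mean_log_abundance[j]), heat=float(heat[j]))
    ii, jj = np.nonzero(np.triu(c.masked_r, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = float(c.masked_r[i, j])
        g.add_edge(
            c.otu_ids[i],
            c.otu_ids[j],
            weight=w,
            magnitude=abs(w),
            sign="positive" if w > 0 else "negative",
            q=float(c.q[i, j]),
        )
    return g


def network_weight_matrix(g: nx.Graph) -> tuple[list[str], np.ndarray]:
    """Node order and the symmetric signed weight matrix of the graph."""
    nodes = list(g.nodes)
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    return nodes, w


def write_edge_tsv(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "weight": d["weight"],
            "sign": d["sign"],
            "q_value": d["q"],
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "q_value"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_tsv(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"otu_id": n, "mean_log_abundance": d["size"], "heat": d["heat"]}
        for n, d in g.nodes(data=True)
    ]
    pd.DataFrame(rows, columns=["otu_id", "mean_log_abundance", "heat"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)
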