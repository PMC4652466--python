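"""Shared helpers importable from test modules (tests/ is on sys.path via
rootdir when pytest runs with the default import mode)."""

import numpy as np

from otuclubs.corrnet import CorrelationResult, build_network


def make_network_from_masked(masked_r, otu_ids=None, n_samples=10):
    """Graph + CorrelationResult from a hand-written masked matrix."""
    c = crafted_correlation(masked_r, otu_ids, n_samples)
    return build_network(c), c


def crafted_correlation(masked_r, otu_ids=None, n_samples=10):
    """CorrelationResult built directly from a hand-written masked matrix."""
    masked_r = np.asarray(masked_r, dtype=float)
    m = masked_r.shape[0]
    if otu_ids is None:
        otu_ids = [f"otu{i}" for i in range(m)]
    r = masked_r.copy()
    np.fill_diagonal(r, 1.0)
    masked = masked_r.copy()
    np.fill_diagonal(masked, 0.0)
    q = np.where(masked != 0, 0.01, 1.0)
    np.fill_diagonal(q, 0.0)
    return CorrelationResult(
        list(otu_ids), r, q.copy(), q, masked, 0.25, n_samples
    )


def bh_oracle_stepup(pvals):
    """Brute-force Benjamini-Hochberg step-up, written independently of the
    implementation: sort ascending, scale p*m/rank, then enforce
    monotonicity with a running minimum from the largest p downwards."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, p[i] * m / rank))
        adjusted[i] = running_min
    return np.array(adjusted)


def naive_mcl(weights, inflation=2.0, self_loop=1.0, max_iter=200, tol=1e-8):
    """Deliberately plain reference MCL written with explicit loops.

    Returns the list of clusters as frozensets of node indices, read from
    the converged matrix by grouping each column with the row holding its
    maximum entry.
    """
    w = [list(map(float, row)) for row in np.asarray(weights)]
    n = len(w)
    for i in range(n):
        w[i][i] += self_loop
    # column normalize
    mat = [[0.0] * n for _ in range(n)]
    for j in range(n):
        s = sum(w[i][j] for i in range(n))
        for i in range(n):
            mat[i][j] = w[i][j] / s
    for _ in range(max_iter):
        # expansion: plain-loop matrix square
        new = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                new[i][j] = sum(mat[i][k] * mat[k][j] for k in range(n))
        # inflation: entrywise square + column renormalize
        for j in range(n):
            col = [new[i][j] ** inflation for i in range(n)]
            s = sum(col)
            for i in range(n):
                new[i][j] = col[i] / s
        diff = max(
            abs(new[i][j] - mat[i][j]) for i in range(n) for j in range(n)
        )
        mat = new
        if diff < tol:
            break
    # each column joins the row of its maximum entry
    assign = {}
    for j in range(n):
        best = max(range(n), key=lambda i: mat[i][j])
        assign[j] = best
    clusters: dict[int, set] = {}
    for j, a in sorted(assign.items()):
        clusters.setdefault(a, set()).add(j)
    # merge clusters whose key node is itself assigned elsewhere
    changed = True
    while changed:
        changed = False
        for a in list(clusters):
            target = assign[a]
            if target != a and target in clusters and a in clusters:
                clusters[target] |= clusters.pop(a)
                changed = True
    return sorted(
        (frozenset(c) for c in clusters.values()), key=lambda c: min(c)
    )
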