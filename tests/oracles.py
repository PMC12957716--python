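"""Independent brute-force oracles for the graph metrics.

Deliberately naive: exhaustive simple-path enumeration for betweenness,
library all-pairs shortest paths for closeness, a dense symmetric
eigendecomposition (with eigenspace projection) for eigenvector
centrality.  Only usable on tiny graphs; they exist so the production
algorithms can be checked against something that shares none of their
code paths.
"""

import numpy as np
from scipy.sparse.csgraph import shortest_path


def lengths_matrix(W, mode):
    B = (W != 0).astype(float)
    if mode == "binary":
        return B
    L = np.zeros_like(W, dtype=float)
    L[B > 0] = 1.0 / np.abs(W[B > 0])
    return L


def oracle_degree(W):
    """Row-wise count of nonzero off-diagonal entries."""
    W = np.asarray(W)
    n = W.shape[0]
    return np.array(
        [sum(1 for j in range(n) if j != i and W[i, j] != 0) for i in range(n)]
    )


def _all_simple_paths(L, x, y):
    """Every simple x-y path as (node tuple, total length), via plain DFS."""
    n = L.shape[0]
    out = []
    stack = [(x, (x,), 0.0)]
    while stack:
        v, path, dist = stack.pop()
        if v == y:
            out.append((path, dist))
            continue
        for w in range(n):
            if L[v, w] > 0 and w not in path:
                stack.append((w, path + (w,), dist + L[v, w]))
    return out

def oracle_betweenness(W, mode="binary", tol=1e-12):
    """Enumerate all shortest paths per pair; credit interior nodes fractionally."""
    L = lengths_matrix(np.asarray(W), mode)
    n = L.shape[0]
    bc = np.zeros(n)
    for x in range(n):
        for y in range(x + 1, n):
            paths = _all_simple_paths(L, x, y)
            if not paths:
                continue
            best = min(d for _, d in paths)
            shortest = [p for p, d in paths if d <= best + tol * (1.0 + best)]
            for p in shortest:
                for node in p[1:-1]:
                    bc[node] += 1.0 / len(shortest)
    return bc


def oracle_distances(W, mode="binary"):
    L = lengths_matrix(np.asarray(W), mode)
    graph = np.where(L > 0, L, np.inf)
    np.fill_diagonal(graph, 0.0)
    return shortest_path(graph, method="FW", directed=False)


def oracle_closeness(W, mode="binary"):
    """Wasserman-Faust closeness from library all-pairs distances."""
    d = oracle_distances(W, mode)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(d[i])
        reach = finite.sum() - 1
        if reach <= 0:
            continue
        out[i] = (reach / (n - 1)) * (reach / d[i][finite].sum())
    return out


def oracle_eigenvector(W, mode="binary", tol=1e-10):
    """Principal-eigenspace projection of the uniform start, L1-normalized.

    Uses a dense symmetric eigendecomposition; when the largest eigenvalue
    is degenerate (e.g. isomorphic disconnected components) the limit of a
    shifted power iteration from the uniform vector is the projection of
    that vector onto the top eigenspace, so that is what the oracle returns.
    """
    M = (W != 0).astype(float) if mode == "binary" else np.abs(np.asarray(W, float))
    vals, vecs = np.linalg.eigh(M)
    lam = vals[-1]
    top = vecs[:, vals > lam - tol * max(1.0, abs(lam))]
    start = np.ones(M.shape[0])
    proj = top @ (top.T @ start)
    v = np.abs(proj)
    return v / v.sum(), lam
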