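"""Graph centrality of subfields in the co-atrophy network.

Four node-level metrics on the thresholded covariance network:

* degree        D_i = number of connections of node i (binary indicator,
                regardless of stored weights);
* betweenness   B_i = sum over unordered pairs x < y (x, y != i) of
                g_xiy / g_xy, the fraction of shortest x-y paths through i,
                unnormalized; pairs with no connecting path contribute 0;
* closeness     C_i = (N - 1) / sum_j l_ij on a connected graph; on
                disconnected graphs the Wasserman-Faust form
                (R_i / (N - 1)) * (R_i / sum_{j reachable} l_ij) with R_i
                the number of nodes reachable from i; isolated nodes get 0;
* eigenvector   E = principal eigenvector of the adjacency matrix,
                L1-normalized (sum E_i = 1), with lambda the largest
                eigenvalue.

Path-based metrics run either on the binarized graph (every edge length 1,
the default) or in weighted mode where edge length is 1/|r| so stronger
co-atrophy means a shorter path.  Eigenvector centrality uses the binary
or the |r| matrix.  All shortest-path ties are counted fractionally via
path counts, never by picking one arbitrary path.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import AdjacencyMatrix

logger = logging.getLogger(__name__)

BINARY = "binary"
WEIGHTED = "weighted"

_EV_TOL = 1e-12
_EV_MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


@dataclass
class GeodesicTable:
    """All-pairs shortest-path structure of a graph.

    ``l[i, j]`` is the shortest-path distance (np.inf when disconnected),
    ``g[i, j]`` the number of distinct shortest i-j paths (0 when
    disconnected, 1 on the diagonal).
    """

    l: np.ndarray
    g: np.ndarray


@dataclass
class CentralityProfile:
    """The four centrality values per node plus the network eigen-pair."""

    labels: tuple
    degree: np.ndarray  # int
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray  # L1-normalized, non-negative
    lam: float  # largest adjacency eigenvalue
    modes: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "degree": self.degree,
                "betweenness": self.betweenness,
                "closeness": self.closeness,
                "eigenvector": self.eigenvector,
            }
        )


def _lengths(adj: AdjacencyMatrix, mode: str) -> np.ndarray:
    """Edge-length matrix: 1 per edge in binary mode, 1/|r| in weighted mode."""
    B = adj.binary()
    if mode == BINARY:
        return B
    if mode == WEIGHTED:
        L = np.zeros_like(adj.weights)
        mask = B > 0
        L[mask] = 1.0 / np.abs(adj.weights[mask])
        return L
    raise ValueError(f"unknown mode {mode!r}")


def _adjacency_lists(lengths: np.ndarray) -> list[list[tuple[int, float]]]:
    n = lengths.shape[0]
    return [
        [(j, lengths[i, j]) for j in np.nonzero(lengths[i])[0]] for i in range(n)
    ]


def _single_source(adjlist, source: int, n: int, binary: bool):
    """Shortest-path tree from one source: distances, path counts sigma,
    predecessor lists, and nodes in non-decreasing distance order."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[source] = 0.0
    sigma[source] = 1.0
    order: list[int] = []
    if binary:
        queue = deque([source])
        while queue:
            v = queue.popleft()
            order.append(v)
            dv = dist[v]
            for w, _ in adjlist[v]:
                if np.isinf(dist[w]):
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    else:
        seen: set[int] = set()
        heap = [(0.0, source)]
        while heap:
            dv, v = heapq.heappop(heap)
            if v in seen:
                continue
            seen.add(v)
            order.append(v)
            for w, length in adjlist[v]:
                alt = dv + length
                if alt < dist[w]:
                    dist[w] = alt
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (alt, w))
                elif w not in seen and alt == dist[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
    return dist, sigma, preds, order


def geodesics(adj: AdjacencyMatrix, mode: str = BINARY) -> GeodesicTable:
    """All-pairs shortest-path distances and shortest-path counts."""
    adj.validate()
    lengths = _lengths(adj, mode)
    adjlist = _adjacency_lists(lengths)
    n = adj.n_nodes
    l = np.full((n, n), np.inf)
    g = np.zeros((n, n))
    for s in range(n):
        dist, sigma, _, _ = _single_source(adjlist, s, n, binary=(mode == BINARY))
        l[s] = dist
        g[s] = sigma
    return GeodesicTable(l=l, g=g)


def degree_centrality(adj: AdjacencyMatrix) -> np.ndarray:
    """D_i: count of nonzero off-diagonal entries in row i."""
    adj.validate()
    return np.count_nonzero(adj.weights, axis=1).astype(int)


def betweenness_centrality(adj: AdjacencyMatrix, mode: str = BINARY) -> np.ndarray:
    """Unnormalized betweenness via Brandes' dependency accumulation.

    Each unordered pair contributes g_xiy / g_xy to every intermediate i;
    endpoints are excluded.
    """
    adj.validate()
    lengths = _lengths(adj, mode)
    adjlist = _adjacency_lists(lengths)
    n = adj.n_nodes
    bc = np.zeros(n)
    for s in range(n):
        _, sigma, preds, order = _single_source(
            adjlist, s, n, binary=(mode == BINARY)
        )
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair was visited from both endpoints


def closeness_centrality(adj: AdjacencyMatrix, mode: str = BINARY) -> np.ndarray:
    """Wasserman-Faust closeness; reduces to (N-1)/sum(l) when connected."""
    adj.validate()
    table = geodesics(adj, mode)
    n = adj.n_nodes
    out = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(table.l[i])
        reach = int(finite.sum()) - 1  # exclude self
        if reach <= 0:
            continue
        total = table.l[i][finite].sum()
        out[i] = (reach / (n - 1)) * (reach / total)
    return out


def eigenvector_centrality(
    adj: AdjacencyMatrix,
    mode: str = BINARY,
    tol: float = _EV_TOL,
    max_iter: int = _EV_MAX_ITER,
) -> tuple[np.ndarray, float]:
    """Principal eigenvector (L1-normalized) and largest eigenvalue.

    Power iteration from a uniform start on the binary or |weight| matrix.
    A +1 spectral shift guarantees convergence on bipartite graphs, where
    the smallest eigenvalue equals -lambda_max; the shift is removed from
    the reported eigenvalue.
    """
    adj.validate()
    if adj.n_edges == 0:
        raise ValueError("eigenvector centrality is undefined on an empty graph")
    if mode not in (BINARY, WEIGHTED, "weighted_abs"):
        raise ValueError(f"unknown mode {mode!r}")
    M = adj.binary() if mode == BINARY else np.abs(adj.weights)
    _warn_if_disconnected(adj)
    n = adj.n_nodes
    shift = 1.0
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w = M @ v + shift * v
        w /= w.sum()  # positive throughout: M >= 0, start > 0
        residual = np.abs(w - v).sum()
        v = w
        if residual <= tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    lam = float(v @ (M @ v) / (v @ v))
    return v, lam


def _components(adj: AdjacencyMatrix) -> list[list[int]]:
    n = adj.n_nodes
    B = adj.binary()
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        queue = deque([s])
        seen[s] = True
        comp = [s]
        while queue:
            v = queue.popleft()
            for w in np.nonzero(B[v])[0]:
                if not seen[w]:
                    seen[w] = True
                    comp.append(int(w))
                    queue.append(int(w))
        comps.append(sorted(comp))
    return comps


def _warn_if_disconnected(adj: AdjacencyMatrix) -> None:
    comps = _components(adj)
    if len(comps) > 1:
        names = [[adj.labels[i] for i in comp] for comp in comps]
        warnings.warn(
            f"network is disconnected ({len(comps)} components): {names}; "
            "eigenvector centrality is dominated by the component with the "
            "largest eigenvalue",
            stacklevel=3,
        )


def compute_centrality_profile(
    adj: AdjacencyMatrix, path_mode: str = BINARY, eigen_mode: str = BINARY
) -> CentralityProfile:
    """All four metrics on one network, with the modes recorded."""
    ev, lam = eigenvector_centrality(adj, mode=eigen_mode)
    return CentralityProfile(
        labels=adj.labels,
        degree=degree_centrality(adj),
        betweenness=betweenness_centrality(adj, mode=path_mode),
        closeness=closeness_centrality(adj, mode=path_mode),
        eigenvector=ev,
        lam=lam,
        modes={"path": path_mode, "eigenvector": eigen_mode},
    )


METRICS = ("degree", "betweenness", "closeness", "eigenvector")


@dataclass
class HubReport:
    """Per-metric top-k rankings and the consensus hub set."""

    k: int
    top: dict[str, list[str]]  # metric -> labels, best first
    consensus: list[str]  # in canonical label order
    ties: dict[str, list[str]]  # labels tied with the k-th value but cut off
    modes: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "top": self.top,
            "consensus": self.consensus,
            "ties": self.ties,
            "modes": self.modes,
        }


def consensus_hubs(profile: CentralityProfile, k: int = 5) -> HubReport:
    """Nodes ranked in the top k for all four metrics simultaneously.

    Rankings are descending by value with ties broken by canonical label
    order; nodes sharing the k-th value but excluded by the tie-break are
    reported in ``ties``.
    """
    n = len(profile.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    top: dict[str, list[str]] = {}
    ties: dict[str, list[str]] = {}
    for metric in METRICS:
        values = np.asarray(getattr(profile, metric), dtype=float)
        order = sorted(range(n), key=lambda i: (-values[i], i))
        chosen = order[:k]
        top[metric] = [profile.labels[i] for i in chosen]
        cutoff = values[chosen[-1]]
        tied = [profile.labels[i] for i in order[k:] if values[i] == cutoff]
        if tied:
            ties[metric] = tied
            logger.warning(
                "%s: %d node(s) tied with the rank-%d value %.6g but excluded "
                "by label-order tie-break", metric, len(tied), k, cutoff,
            )
    consensus_set = set(top[METRICS[0]])
    for metric in METRICS[1:]:
        consensus_set &= set(top[metric])
    consensus = [lbl for lbl in profile.labels if lbl in consensus_set]
    return HubReport(k=k, top=top, consensus=consensus, ties=ties,
                     modes=dict(profile.modes))
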