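"""Structural covariance network over subfield volume changes.

Pairwise covariate-adjusted partial Pearson correlations between the
percentage volume changes of all subfield pairs form a symmetric 38 x 38
correlation matrix.  Significance thresholding (retain an edge only when
its p-value is below alpha, default 0.05) turns it into the adjacency
matrix of an undirected weighted graph whose nodes are subfields and whose
edge weights are the signed partial correlations; strength-based
computations downstream use |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import n_covariates, residualize
from .labels import CANONICAL_NAMES, N_SUBFIELDS
from .volumetrics import ChangeTable, benjamini_hochberg

_SYM_TOL = 1e-12


@dataclass
class CorrelationMatrices:
    """Partial-correlation matrix and matching two-sided p-values."""

    r: np.ndarray  # symmetric, unit diagonal
    p: np.ndarray  # symmetric, zero diagonal by convention
    labels: tuple = tuple(CANONICAL_NAMES)
    n: int = 0
    df: int = 0

    def validate(self) -> None:
        for name, m in (("r", self.r), ("p", self.p)):
            if m.shape != (len(self.labels), len(self.labels)):
                raise ValueError(f"{name} matrix has wrong shape")
            if np.max(np.abs(m - m.T)) > _SYM_TOL:
                raise ValueError(f"{name} matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=_SYM_TOL):
            raise ValueError("r diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + _SYM_TOL) or np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("entries out of range")


@dataclass
class AdjacencyMatrix:
    """Thresholded co-atrophy network; weights[i, j] = 0 means no edge."""

    weights: np.ndarray  # (N, N) symmetric, zero diagonal, signed partial r
    labels: tuple = tuple(CANONICAL_NAMES)
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def validate(self) -> None:
        W = self.weights
        if W.shape != (len(self.labels), len(self.labels)):
            raise ValueError("adjacency shape does not match labels")
        if np.max(np.abs(W - W.T)) > _SYM_TOL:
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-loops are not allowed")

    def binary(self) -> np.ndarray:
        """0/1 connection indicator (used by degree and binary path metrics)."""
        return (self.weights != 0).astype(float)


def pairwise_partial_correlations(
    changes: ChangeTable, covariates: np.ndarray
) -> CorrelationMatrices:
    """Covariate-adjusted partial correlations for every subfield pair.

    All columns are residualized against [1, Z] in a single least-squares
    solve; the correlation matrix of the residuals equals the pairwise
    partial correlations x_i ~ x_j | Z.
    """
    X = changes.volume_change_pct
    n = X.shape[0]
    k = n_covariates(covariates)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    R = residualize(X, covariates)
    sd = R.std(axis=0)
    floor = 1e-10 * np.maximum(X.std(axis=0), 1e-30)
    if np.any(sd <= floor):
        bad = changes_labels(changes)[int(np.argmax(sd <= floor))]
        raise ValueError(f"(near-)zero-variance residuals for subfield {bad!r}")
    C = np.corrcoef(R, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    # enforce exact symmetry: each unordered pair represented once
    C = np.triu(C, k=1)
    C = C + C.T
    np.fill_diagonal(C, 1.0)
    df = n - k - 2
    off = ~np.eye(C.shape[0], dtype=bool)
    P = np.zeros_like(C)
    rr = C[off]
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr * rr, 1e-300))
    P[off] = 2.0 * stats.t.sf(np.abs(t), df=df)
    corr = CorrelationMatrices(r=C, p=P, labels=changes_labels(changes), n=n, df=df)
    corr.validate()
    return corr


def changes_labels(changes: ChangeTable) -> tuple:
    return tuple(lbl.render() for lbl in changes.labels)


def threshold_network(
    corr: CorrelationMatrices,
    alpha: float = 0.05,
    fdr: bool = False,
    positive_only: bool = False,
) -> AdjacencyMatrix:
    """Retain edges with p < alpha; weights are the signed partial r.

    ``fdr`` thresholds Benjamini-Hochberg q-values instead of raw p-values;
    ``positive_only`` drops negative-weight edges.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    corr.validate()
    N = len(corr.labels)
    iu = np.triu_indices(N, k=1)
    p_upper = corr.p[iu]
    crit = benjamini_hochberg(p_upper) if fdr else p_upper
    # alpha = 1 keeps everything (p-values never exceed 1)
    keep = crit < alpha if alpha < 1.0 else np.ones_like(crit, dtype=bool)
    W = np.zeros_like(corr.r)
    W[iu] = np.where(keep, corr.r[iu], 0.0)
    if positive_only:
        W[iu] = np.where(W[iu] > 0, W[iu], 0.0)
    W = W + W.T
    adj = AdjacencyMatrix(
        weights=W,
        labels=corr.labels,
        alpha=alpha,
        meta={"fdr": fdr, "positive_only": positive_only, "n": corr.n},
    )
    adj.validate()
    return adj


def matrix_frame(m: np.ndarray, labels) -> pd.DataFrame:
    """Matrix as a DataFrame labeled on both axes."""
    return pd.DataFrame(m, index=list(labels), columns=list(labels))


def edge_list_frame(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Three-column edge list: node_i, node_j, weight (upper triangle)."""
    i, j = np.nonzero(np.triu(adj.weights, k=1))
    return pd.DataFrame(
        {
            "node_i": [adj.labels[a] for a in i],
            "node_j": [adj.labels[b] for b in j],
            "weight": adj.weights[i, j],
        }
    )


def to_networkx(adj: AdjacencyMatrix):
    """Weighted undirected networkx graph (for export / interop)."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(adj.labels)
    for _, row in edge_list_frame(adj).iterrows():
        G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
    return G


def write_graphml(adj: AdjacencyMatrix, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(adj), path)
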