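import numpy as np
import pytest

import hippnet as hn


@pytest.fixture(scope="session")
def default_cohort():
    return hn.generate_cohort(hn.default_config(seed=7))


@pytest.fixture(scope="session")
def default_changes(default_cohort):
    return hn.compute_change_table(default_cohort)


def make_adjacency(W, alpha=0.05):
    """AdjacencyMatrix over generic node labels for an arbitrary weight matrix."""
    W = np.asarray(W, dtype=float)
    labels = tuple(f"n{i}" for i in range(W.shape[0]))
    return hn.AdjacencyMatrix(weights=W, labels=labels, alpha=alpha)


def random_graph(rng, n, p=0.4, weighted=True, signed=True):
    """Random symmetric zero-diagonal weight matrix (possibly disconnected)."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = rng.uniform(0.3, 1.0) if weighted else 1.0
                if signed and rng.random() < 0.3:
                    w = -w
                W[i, j] = W[j, i] = w
    return W
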