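import numpy as np
import pytest

import hippnet as hn
from conftest import make_adjacency, random_graph
from oracles import (
    oracle_betweenness,
    oracle_closeness,
    oracle_degree,
    oracle_distances,
    oracle_eigenvector,
)


def star(n=5):
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    return make_adjacency(W)


def path3():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
    return make_adjacency(W)


def complete(n):
    W = 1.0 - np.eye(n)
    return make_adjacency(W)


class TestClosedForms:
    def test_star_degree(self):
        assert hn.degree_centrality(star()).tolist() == [4, 1, 1, 1, 1]

    def test_complete_graph_degree(self):
        assert np.all(hn.degree_centrality(complete(38)) == 37)

    def test_path_betweenness(self):
        assert hn.betweenness_centrality(path3()).tolist() == [0.0, 1.0, 0.0]

    def test_star_center_betweenness_is_choose_two(self):
        bc = hn.betweenness_centrality(star())
        assert bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.all(bc[1:] == 0)

    def test_star_closeness(self):
        cc = hn.closeness_centrality(star())
        assert cc[0] == pytest.approx(1.0)
        assert np.allclose(cc[1:], 4.0 / 7.0)

    def test_complete_graph_closeness_is_one(self):
        assert np.allclose(hn.closeness_centrality(complete(10)), 1.0)

    def test_complete_graph_eigenvector_uniform(self):
        ev, lam = hn.eigenvector_centrality(complete(4))
        assert np.allclose(ev, 0.25, atol=1e-10)
        assert lam == pytest.approx(3.0, abs=1e-10)

    def test_star_spectrum_and_component_ratio(self):
        # star on N nodes: lambda = sqrt(N-1); center = sqrt(N-1) x leaf
        ev, lam = hn.eigenvector_centrality(star(5))
        assert lam == pytest.approx(2.0, abs=1e-10)
        assert ev[0] / ev[1] == pytest.approx(2.0, abs=1e-9)

    def test_complete_graph_metrics_constant_across_nodes(self):
        adj = complete(7)
        prof = hn.compute_centrality_profile(adj)
        assert np.all(prof.degree == 6)
        assert np.allclose(prof.betweenness, 0.0)
        assert np.allclose(prof.closeness, 1.0)
        assert np.allclose(prof.eigenvector, 1.0 / 7.0)


class TestOracleAgreement:
    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_random_small_graphs_match_brute_force(self, mode):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(120):
            n = int(rng.integers(2, 7))
            W = random_graph(rng, n, p=rng.uniform(0.2, 0.9))
            adj = make_adjacency(W)
            assert np.array_equal(hn.degree_centrality(adj), oracle_degree(W))
            assert np.allclose(
                hn.betweenness_centrality(adj, mode=mode),
                oracle_betweenness(W, mode),
                atol=1e-9,
            )
            assert np.allclose(
                hn.closeness_centrality(adj, mode=mode),
                oracle_closeness(W, mode),
                atol=1e-12,
            )
            if adj.n_edges > 0:
                ev, lam = hn.eigenvector_centrality(
                    adj, mode="binary" if mode == "binary" else "weighted_abs"
                )
                ref, lam_ref = oracle_eigenvector(W, mode)
                assert np.allclose(ev, ref, atol=1e-8)
                assert lam == pytest.approx(lam_ref, abs=1e-8)
            checked += 1
        assert checked == 120

    def test_geodesics_match_library_distances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            W = random_graph(rng, n, p=0.4)
            table = hn.geodesics(make_adjacency(W), mode="binary")
            ref = oracle_distances(W, "binary")
            assert np.allclose(table.l, ref, equal_nan=False)
            # triangle inequality wherever both sides are finite
            for x in range(n):
                for y in range(n):
                    for z in range(n):
                        if np.isfinite(table.l[x, z]) and np.isfinite(table.l[z, y]):
                            assert table.l[x, y] <= table.l[x, z] + table.l[z, y] + 1e-12

    def test_betweenness_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            W = random_graph(rng, n, p=0.5, weighted=False, signed=False)
            adj = make_adjacency(W)
            G = nx.from_numpy_array(W)
            ref = nx.betweenness_centrality(G, normalized=False)
            got = hn.betweenness_centrality(adj)
            assert np.allclose(got, [ref[i] for i in range(n)], atol=1e-9)

    def test_closeness_matches_networkx_wasserman_faust(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            W = random_graph(rng, n, p=0.35, weighted=False, signed=False)
            adj = make_adjacency(W)
            G = nx.from_numpy_array(W)
            ref = nx.closeness_centrality(G, wf_improved=True)
            got = hn.closeness_centrality(adj)
            assert np.allclose(got, [ref[i] for i in range(n)], atol=1e-12)


class TestStructuralProperties:
    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        W = random_graph(rng, 8, p=0.5)
        perm = rng.permutation(8)
        adj = make_adjacency(W)
        padj = hn.AdjacencyMatrix(
            weights=W[np.ix_(perm, perm)],
            labels=tuple(adj.labels[i] for i in perm),
        )
        prof = hn.compute_centrality_profile(adj)
        pprof = hn.compute_centrality_profile(padj)
        assert np.array_equal(prof.degree[perm], pprof.degree)
        assert np.allclose(prof.betweenness[perm], pprof.betweenness, atol=1e-9)
        assert np.allclose(prof.closeness[perm], pprof.closeness, atol=1e-12)
        assert np.allclose(prof.eigenvector[perm], pprof.eigenvector, atol=1e-9)

    def test_adding_an_edge_never_hurts_degree_or_closeness(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = 7
            W = random_graph(rng, n, p=0.3, weighted=False, signed=False)
            absent = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if W[i, j] == 0
            ]
            if not absent:
                continue
            i, j = absent[int(rng.integers(len(absent)))]
            W2 = W.copy()
            W2[i, j] = W2[j, i] = 1.0
            d1, d2 = (hn.degree_centrality(make_adjacency(m)) for m in (W, W2))
            assert np.all(d2 >= d1)
            c1, c2 = (hn.closeness_centrality(make_adjacency(m)) for m in (W, W2))
            assert c2[i] >= c1[i] - 1e-12 and c2[j] >= c1[j] - 1e-12

    def test_eigenvector_l1_normalized_nonnegative_and_self_consistent(self):
        rng = np.random.default_rng(13)
        W = np.abs(random_graph(rng, 10, p=0.6))
        # connect everything to node 0 to guarantee connectivity
        W[0, 1:] = np.maximum(W[0, 1:], 0.5)
        W[1:, 0] = W[0, 1:]
        adj = make_adjacency(W)
        ev, lam = hn.eigenvector_centrality(adj, mode="weighted_abs")
        assert ev.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ev >= 0)
        assert np.allclose(np.abs(W) @ ev, lam * ev, atol=1e-9)

    def test_sum_of_degrees_is_even(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            W = random_graph(rng, 9, p=0.5)
            assert hn.degree_centrality(make_adjacency(W)).sum() % 2 == 0

    def test_empty_graph_eigenvector_raises(self):
        with pytest.raises(ValueError, match="empty"):
            hn.eigenvector_centrality(make_adjacency(np.zeros((4, 4))))

    def test_disconnected_graph_warns_and_isolated_nodes_get_zero_closeness(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0  # component {0,1}; nodes 2-4 isolated
        adj = make_adjacency(W)
        cc = hn.closeness_centrality(adj)
        assert np.all(cc[2:] == 0)
        with pytest.warns(UserWarning, match="disconnected"):
            hn.eigenvector_centrality(adj)
        bc = hn.betweenness_centrality(adj)
        assert np.all(bc == 0)  # unreachable pairs contribute nothing


class TestConsensusHubs:
    def test_star_center_is_sole_consensus_hub_at_k_one(self):
        prof = hn.compute_centrality_profile(star())
        report = hn.consensus_hubs(prof, k=1)
        assert report.consensus == ["n0"]
        for metric in ("degree", "betweenness", "closeness", "eigenvector"):
            assert report.top[metric][0] == "n0"

    def test_two_identical_cliques_resolved_by_tie_break_and_reported(self):
        n = 6
        W = np.zeros((n, n))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 1.0
        prof = hn.compute_centrality_profile(make_adjacency(W))
        report = hn.consensus_hubs(prof, k=3)
        assert report.top["degree"] == ["n0", "n1", "n2"]  # label-order tie-break
        assert set(report.ties["degree"]) == {"n3", "n4", "n5"}

    def test_k_out_of_range_rejected(self):
        prof = hn.compute_centrality_profile(star())
        with pytest.raises(ValueError):
            hn.consensus_hubs(prof, k=0)
        with pytest.raises(ValueError):
            hn.consensus_hubs(prof, k=6)

    def test_planted_hub_block_recovered_in_consensus(self):
        cfg = planted_hub_config(seed=5)
        cohort = hn.generate_cohort(cfg)
        corr = hn.pairwise_partial_correlations(
            hn.compute_change_table(cohort), cohort.covariates()
        )
        adj = hn.threshold_network(corr, alpha=0.05)
        prof = hn.compute_centrality_profile(adj)
        report = hn.consensus_hubs(prof, k=5)
        assert hn.CANONICAL_NAMES[HUB_INDEX] in report.consensus


HUB_INDEX = 2  # "CA1 head L"


def planted_hub_config(seed=0, n_subjects=258):
    """Default config rewired so one subfield dominates the covariance network.

    The hub loads strongly on the single shared factor while every other
    subfield keeps only a weak loading, so hub-other correlations are large
    and other-other correlations hover near the significance threshold: the
    hub out-ranks everything on degree, betweenness, closeness and
    eigenvector centrality.
    """
    loadings = np.zeros((38, 1))
    loadings[:, 0] = 0.5
    loadings[HUB_INDEX, 0] = 5.0
    return hn.default_config(n_subjects=n_subjects, seed=seed).replace(
        factor_loadings=loadings, noise_sd=2.0, cognition_coupling=0.0
    )
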