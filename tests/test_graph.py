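"""Graph metrics vs closed forms and brute-force enumeration oracles."""

import numpy as np
import pytest

from fbnkit import (
    BinaryNetwork,
    ModulePartition,
    average_neighbor_degree,
    betweenness_centrality,
    clustering_coefficient,
    degree,
    detect_modules,
    extract_features,
    local_efficiency,
    modularity_score,
    modularity_threshold_sweep,
    participation_coefficient,
    path_length_and_global_efficiency,
)
from fbnkit.graph import FeatureVector, feature_table
from fbnkit.models import ConnectivityResults

from . import _oracles as orc
from .conftest import random_binary_network


def complete(n):
    adj = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
    return BinaryNetwork(adjacency=adj)


def star(n):
    adj = np.zeros((n, n), dtype=np.int8)
    adj[0, 1:] = adj[1:, 0] = 1
    return BinaryNetwork(adjacency=adj)


def path(n):
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return BinaryNetwork(adjacency=adj)


# -- closed forms -----------------------------------------------------------


def test_complete_graph_closed_forms():
    g = complete(4)
    assert np.allclose(clustering_coefficient(g), 1.0)
    assert np.allclose(local_efficiency(g), 1.0)
    assert np.allclose(degree(g), 3.0)
    assert np.allclose(betweenness_centrality(g), 0.0)
    L, E = path_length_and_global_efficiency(g)
    assert L == pytest.approx(1.0) and E == pytest.approx(1.0)
    assert np.allclose(average_neighbor_degree(g), 3.0)


def test_star_graph_closed_forms():
    g = star(4)
    assert np.allclose(clustering_coefficient(g), 0.0)
    assert np.allclose(local_efficiency(g), 0.0)
    b = betweenness_centrality(g)
    assert b[0] == pytest.approx(1.0)
    assert np.allclose(b[1:], 0.0)
    knn = average_neighbor_degree(g)
    assert knn[0] == pytest.approx(1.0)
    assert np.allclose(knn[1:], 3.0)


def test_path3_integration_measures():
    L, E = path_length_and_global_efficiency(path(3))
    assert L == pytest.approx(4 / 3)
    assert E == pytest.approx(5 / 6)


def test_regular_graph_neighbor_degree():
    # 4-cycle is 2-regular
    g = path(4)
    adj = np.asarray(g.adjacency).copy()
    adj[0, 3] = adj[3, 0] = 1
    cyc = BinaryNetwork(adjacency=adj)
    assert np.allclose(average_neighbor_degree(cyc), 2.0)


def test_edgeless_graph_conventions():
    g = BinaryNetwork(adjacency=np.zeros((5, 5), dtype=np.int8))
    assert np.allclose(degree(g), 0)
    L, E = path_length_and_global_efficiency(g)
    assert np.isnan(L) and E == 0.0
    part = detect_modules(g)
    assert part.n_modules == 5
    with pytest.raises(ValueError):
        modularity_score(g, part)


# -- brute-force oracles on seeded random graphs ----------------------------


@pytest.mark.parametrize("seed,p", [(0, 0.3), (1, 0.5), (2, 0.2), (3, 0.7), (4, 0.4)])
def test_all_metrics_match_bruteforce(seed, p):
    g = random_binary_network(12, p, seed)
    adj = np.asarray(g.adjacency)
    assert np.allclose(clustering_coefficient(g), orc.oracle_clustering(adj), atol=1e-10)
    assert np.allclose(local_efficiency(g), orc.oracle_local_efficiency(adj), atol=1e-10)
    assert np.allclose(degree(g), adj.sum(1), atol=1e-10)
    assert np.allclose(betweenness_centrality(g), orc.oracle_betweenness(adj), atol=1e-10)
    assert np.allclose(
        average_neighbor_degree(g), orc.oracle_avg_neighbor_degree(adj), atol=1e-10
    )
    if g.n_edges:
        L, E = path_length_and_global_efficiency(g)
        L_o, E_o = orc.oracle_path_length_global_eff(adj)
        assert L == pytest.approx(L_o, abs=1e-10)
        assert E == pytest.approx(E_o, abs=1e-10)
        part = detect_modules(g)
        assign = np.asarray(part.assignment)
        assert modularity_score(g, part) == pytest.approx(
            orc.oracle_modularity(adj, assign), abs=1e-10
        )
        rng = np.random.default_rng(seed)
        rand_assign = rng.integers(0, 3, size=12)
        rand_part = ModulePartition(assignment=tuple(_contiguous(rand_assign)))
        assert np.allclose(
            participation_coefficient(g, rand_part),
            orc.oracle_participation(adj, np.asarray(rand_part.assignment)),
            atol=1e-10,
        )


def _contiguous(assign):
    ids = {a: i for i, a in enumerate(dict.fromkeys(assign))}
    return [ids[a] for a in assign]


def test_metric_ranges():
    for seed in range(3):
        g = random_binary_network(12, 0.4, 50 + seed)
        assert np.all((clustering_coefficient(g) >= 0) & (clustering_coefficient(g) <= 1))
        assert np.all((local_efficiency(g) >= 0) & (local_efficiency(g) <= 1))
        b = betweenness_centrality(g)
        assert np.all((b >= 0) & (b <= 1))
        part = detect_modules(g)
        y = participation_coefficient(g, part)
        assert np.all((y >= -1e-12) & (y <= 1))
        if g.n_edges:
            L, E = path_length_and_global_efficiency(g)
            assert 0 <= E <= 1 and L >= 1


def test_permutation_equivariance():
    g = random_binary_network(10, 0.4, 99)
    rng = np.random.default_rng(0)
    perm = rng.permutation(10)
    adj_p = np.asarray(g.adjacency)[np.ix_(perm, perm)]
    gp = BinaryNetwork(adjacency=adj_p)
    for fn in (clustering_coefficient, local_efficiency, degree,
               betweenness_centrality, average_neighbor_degree):
        assert np.allclose(fn(gp), fn(g)[perm], atol=1e-10)


# -- modules and modularity -------------------------------------------------


def two_cliques(k):
    adj = np.zeros((2 * k, 2 * k), dtype=np.int8)
    adj[:k, :k] = 1
    adj[k:, k:] = 1
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adjacency=adj)


def test_two_cliques_detected_and_q_half():
    g = two_cliques(5)
    part = detect_modules(g)
    assert part.n_modules == 2
    assert len(set(part.assignment[:5])) == 1 and len(set(part.assignment[5:])) == 1
    assert modularity_score(g, part) == pytest.approx(0.5)


def test_single_module_q_zero():
    g = random_binary_network(10, 0.5, 7)
    part = ModulePartition(assignment=(0,) * 10)
    assert modularity_score(g, part) == pytest.approx(0.0, abs=1e-12)
    greedy = detect_modules(g)
    assert modularity_score(g, greedy) >= 0.0


def test_planted_blocks_recovered():
    rng = np.random.default_rng(13)
    n, k = 24, 4
    truth = np.repeat(np.arange(k), n // k)
    prob = np.where(truth[:, None] == truth[None, :], 0.9, 0.05)
    adj = np.triu((rng.random((n, n)) < prob), 1).astype(np.int8)
    adj = adj + adj.T
    part = detect_modules(BinaryNetwork(adjacency=adj))
    # agreement up to label permutation: majority label per true block
    assign = np.asarray(part.assignment)
    agree = 0
    for b in range(k):
        members = assign[truth == b]
        agree += np.max(np.bincount(members))
    assert agree / n >= 0.9


def test_participation_two_module_node():
    # node 0 has exactly one link into each of two modules
    adj = np.zeros((5, 5), dtype=np.int8)
    adj[0, 1] = adj[1, 0] = 1
    adj[0, 3] = adj[3, 0] = 1
    adj[1, 2] = adj[2, 1] = 1
    adj[3, 4] = adj[4, 3] = 1
    g = BinaryNetwork(adjacency=adj)
    part = ModulePartition(assignment=(0, 0, 0, 1, 1))
    assert participation_coefficient(g, part)[0] == pytest.approx(0.5)
    whole = ModulePartition(assignment=(0,) * 5)
    assert np.allclose(participation_coefficient(g, whole), 0.0)


# -- threshold sweep --------------------------------------------------------


def _weighted_res(w):
    m = w.shape[0]
    return ConnectivityResults(
        weights=w, model_tag="x", params={},
        region_labels=tuple(f"R{i}" for i in range(m)),
        subject_id="s", symmetrized=True,
    )


def test_sweep_on_binary_network_at_zero_threshold():
    g = two_cliques(4)
    res = _weighted_res(np.asarray(g.adjacency, dtype=float))
    curve = modularity_threshold_sweep(res, [0.0])
    assert curve[0][1] == pytest.approx(modularity_score(g, detect_modules(g)))


def test_sweep_above_max_weight_is_missing():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.5
    curve = modularity_threshold_sweep(_weighted_res(w), [1.0])
    assert np.isnan(curve[0][1])


def test_sweep_planted_modular_matrix_positive_q():
    k = 5
    w = np.zeros((2 * k, 2 * k))
    rng = np.random.default_rng(3)
    w[:k, :k] = 0.8 + 0.1 * rng.random((k, k))
    w[k:, k:] = 0.8 + 0.1 * rng.random((k, k))
    w[:k, k:] = 0.05 * rng.random((k, k))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0)
    curve = modularity_threshold_sweep(_weighted_res(w), [0.1, 0.3])
    for _, q in curve:
        assert np.isfinite(q) and q > 0


# -- feature vector ---------------------------------------------------------


def test_feature_vector_lengths():
    assert len(extract_features(random_binary_network(10, 0.4, 1))) == 62
    assert len(extract_features(complete(5))) == 32


def test_complete_graph_feature_blocks():
    fv = extract_features(complete(5))
    assert np.allclose(fv.block("clustering"), 1)
    assert np.allclose(fv.block("local_efficiency"), 1)
    assert np.allclose(fv.block("degree"), 4)
    assert np.allclose(fv.block("betweenness"), 0)
    assert np.allclose(fv.block("participation"), 0)  # single detected module
    assert np.allclose(fv.block("avg_neighbor_degree"), 4)
    assert fv.block("char_path_length")[0] == pytest.approx(1.0)
    assert fv.block("global_efficiency")[0] == pytest.approx(1.0)


def test_describe_index_roundtrip():
    m = 7
    kinds = []
    for idx in range(6 * m + 2):
        kind, region = FeatureVector.describe_index(idx, m)
        kinds.append(kind)
        if idx < 6 * m:
            assert region == idx % m
        else:
            assert region is None
    assert len(set(kinds)) == 8


def test_feature_table_orientation():
    g1 = random_binary_network(6, 0.5, 0)
    fvs = [extract_features(g1, subject_id=f"s{i}") for i in range(3)]
    table = feature_table(fvs, [f"R{i}" for i in range(6)])
    assert table.shape == (38, 3)  # features x subjects
    assert table.index[0].startswith("clustering:")
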