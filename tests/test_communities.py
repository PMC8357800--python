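"""Map-equation detection, NMI, and the multi-threshold consensus."""

import itertools

import numpy as np
import pytest

from fetalconn import (detect_communities, pairwise_nmi, consensus, modularity,
                       map_equation_codelength)
from fetalconn.communities import Partition, canonical_labels


def two_cliques(n1=5, n2=5, bridge=False):
    n = n1 + n2
    adj = np.zeros((n, n), dtype=bool)
    adj[:n1, :n1] = True
    adj[n1:, n1:] = True
    np.fill_diagonal(adj, False)
    if bridge:
        adj[0, n1] = adj[n1, 0] = True
    return adj


def test_single_edge_codelength_is_one_bit():
    # two nodes, one edge, one module: L = H({1/2, 1/2}) = 1 bit
    adj = np.array([[0, 1], [1, 0]])
    assert map_equation_codelength(adj, [0, 0]) == pytest.approx(1.0)


def test_k5k5_matches_exhaustive_bipartition_search():
    """Infomap on two disjoint 5-cliques equals the best partition found by
    exhaustively scoring the 1-block partition and all 2-block partitions."""
    adj = two_cliques()
    best_L, best_labels = np.inf, None
    for assignment in itertools.product([0, 1], repeat=9):
        labels = np.array((0,) + assignment)
        if labels.max() == 0:
            continue
        L = map_equation_codelength(adj, labels)
        if L < best_L:
            best_L, best_labels = L, labels
    one_block = map_equation_codelength(adj, np.zeros(10, dtype=int))
    assert best_L < one_block
    assert list(canonical_labels(best_labels)) == [0] * 5 + [1] * 5

    part = detect_communities(adj, seed=0, trials=20)
    assert part.n_communities == 2
    assert list(part.labels) == [0] * 5 + [1] * 5
    assert part.quality["codelength"] == pytest.approx(best_L, abs=1e-9)


def test_complete_graph_single_community():
    adj = ~np.eye(8, dtype=bool)
    part = detect_communities(adj, seed=0, trials=10)
    assert part.n_communities == 1


def test_isolated_nodes_become_singletons():
    adj = two_cliques()
    adj2 = np.zeros((12, 12), dtype=bool)
    adj2[:10, :10] = adj
    part = detect_communities(adj2, seed=0, trials=10)
    assert part.n_communities == 4
    assert part.labels[10] != part.labels[11]


def test_detection_deterministic_under_seed():
    rng = np.random.default_rng(0)
    adj = rng.random((40, 40)) < 0.1
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    a = detect_communities(adj, seed=5, trials=10)
    b = detect_communities(adj, seed=5, trials=10)
    assert np.array_equal(a.labels, b.labels)


def test_empty_graph_rejected():
    with pytest.raises(ValueError):
        detect_communities(np.zeros((0, 0)), seed=0)


def test_nmi_identity_and_independence():
    p1 = Partition(labels=np.array([0, 0, 1, 1, 2, 2]))
    assert pairwise_nmi(p1, p1) == pytest.approx(1.0)
    singletons = Partition(labels=np.arange(6))
    one_block = Partition(labels=np.zeros(6, dtype=int))
    assert pairwise_nmi(singletons, one_block) == pytest.approx(0.0)


def test_nmi_matches_contingency_oracle():
    """Hand-computed NMI for labels 112233 vs 111223 from the contingency
    table, with arithmetic-mean normalization."""
    a = np.array([1, 1, 2, 2, 3, 3])
    b = np.array([1, 1, 1, 2, 2, 3])
    # oracle: direct contingency computation
    n = 6
    mi = 0.0
    for u in np.unique(a):
        for v in np.unique(b):
            nij = np.sum((a == u) & (b == v))
            if nij:
                mi += (nij / n) * np.log(nij * n / ((a == u).sum() * (b == v).sum()))
    ha = -sum((a == u).mean() * np.log((a == u).mean()) for u in np.unique(a))
    hb = -sum((b == v).mean() * np.log((b == v).mean()) for v in np.unique(b))
    oracle = mi / ((ha + hb) / 2)
    got = pairwise_nmi(Partition(labels=a), Partition(labels=b))
    assert got == pytest.approx(oracle, abs=1e-12)


def _stack_of_partitions(labels_list, thresholds=None):
    return [Partition(labels=np.array(l), threshold=(thresholds[i] if thresholds else None))
            for i, l in enumerate(labels_list)]


def test_consensus_unanimity():
    labels = [0] * 5 + [1] * 5
    parts = _stack_of_partitions([labels] * 7)
    model = consensus(parts, two_cliques(), window=3)
    assert list(model.final.labels) == labels
    assert model.n_networks == 2


def test_consensus_outlier_never_selected():
    good = [0] * 5 + [1] * 5
    outlier = list(range(10))
    seq = [good] * 3 + [outlier] + [good] * 3
    model = consensus(_stack_of_partitions(seq), two_cliques(), window=3)
    assert list(model.final.labels) == good


def test_consensus_invariant_to_relabeling():
    base = [0] * 5 + [1] * 5
    relabeled = [7] * 5 + [3] * 5   # same partition, different ids
    m1 = consensus(_stack_of_partitions([base] * 5), two_cliques(), window=3)
    m2 = consensus(_stack_of_partitions([base] * 2 + [relabeled] + [base] * 2),
                   two_cliques(), window=3)
    assert np.array_equal(m1.final.labels, m2.final.labels)


def test_consensus_modularity_at_least_median_solution():
    adj = two_cliques(bridge=True)
    rng = np.random.default_rng(3)
    parts = []
    for _ in range(9):
        labels = np.array([0] * 5 + [1] * 5)
        if rng.random() < 0.5:  # corrupt some solutions
            labels[rng.integers(0, 10)] = 2
        parts.append(Partition(labels=labels))
    model = consensus(parts, adj, window=3)
    med = parts[len(parts) // 2]
    assert (modularity(adj, model.final.labels)
            >= modularity(adj, med.labels) - 1e-12)


def test_consensus_window_validation():
    parts = _stack_of_partitions([[0, 0, 1, 1]] * 4)
    with pytest.raises(ValueError, match="window"):
        consensus(parts, two_cliques(2, 2), window=9)
    with pytest.raises(ValueError):
        consensus(parts[:2], two_cliques(2, 2), window=2)


def test_planted_blocks_recovered_at_moderate_density():
    """16-block planted graph at ~5% density: detection NMI >= 0.9 vs truth."""
    rng = np.random.default_rng(8)
    n, k = 96, 16
    truth = np.repeat(np.arange(k), n // k)
    p_in, p_out = 0.9, 0.01
    same = truth[:, None] == truth[None, :]
    adj = np.triu((rng.random((n, n)) < np.where(same, p_in, p_out)), 1)
    adj = adj | adj.T
    part = detect_communities(adj, seed=1, trials=20)
    assert pairwise_nmi(part, Partition(labels=truth)) >= 0.9
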