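"""The convolution engine against an independent dense-power oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcas import (
    DataError,
    GcasParams,
    Retention,
    UsageError,
    augment,
    infer_associations,
    normalize,
    normalize_network,
    propagate,
    score_matrix,
)
from conftest import dense_gcas_oracle, random_symmetric_graph


def test_params_validation():
    with pytest.raises(UsageError):
        GcasParams(K=0)
    with pytest.raises(UsageError):
        GcasParams(theta=1.5)
    p = GcasParams()
    assert (p.K, p.theta) == (9, 0.25)
    # damping skips the first two convolution steps; 0^0 := 1
    z = GcasParams(K=3, theta=0.0)
    assert [z.step_factor(t) for t in (1, 2, 3)] == [1.0, 1.0, 0.0]


def test_normalize_toys():
    np.testing.assert_allclose(normalize([[0.0]]).a_hat.toarray(), [[1.0]])
    n2 = normalize([[0, 1], [1, 0]])
    np.testing.assert_allclose(n2.a_hat.toarray(), [[0.5, 0.5], [0.5, 0.5]])
    n3 = normalize([[0, 3], [3, 0]])
    np.testing.assert_allclose(n3.a_hat.toarray(), [[0.25, 0.75], [0.75, 0.25]])


def test_normalize_rejects_bad_input():
    with pytest.raises(DataError):
        normalize([[0, 1], [0, 0]])  # asymmetric
    with pytest.raises(DataError):
        normalize([[0, -1], [-1, 0]])  # negative
    with pytest.raises(DataError):
        normalize([[1, 1], [1, 0]])  # nonzero diagonal


def test_isolated_node_keeps_unit_self_entry():
    norm = normalize([[0, 0], [0, 0]])
    assert norm.a_hat.toarray() == pytest.approx(np.eye(2))


def test_propagate_two_node_toy():
    norm = normalize([[0, 1], [1, 0]])
    assert propagate(norm, 0, GcasParams(K=1))[1] == pytest.approx(0.5)
    # Â is idempotent here, so both orders contribute 0.5
    for theta in (0.0, 0.25, 1.0):
        assert propagate(norm, 0, GcasParams(K=2, theta=theta))[1] == pytest.approx(1.0)


def test_propagate_three_node_path():
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    norm = normalize(a)
    assert norm.a_hat[0, 1] == pytest.approx(1 / np.sqrt(6))
    for theta in (0.0, 0.5, 1.0):
        s = propagate(norm, 0, GcasParams(K=2, theta=theta))
        assert s[2] == pytest.approx(1 / 6)


def test_propagate_seed_out_of_range():
    norm = normalize([[0, 1], [1, 0]])
    with pytest.raises(UsageError):
        propagate(norm, 5)


@pytest.mark.parametrize("theta", [0.0, 0.25, 1.0])
@pytest.mark.parametrize("k", [1, 3, 9])
def test_score_matrix_matches_dense_oracle(k, theta):
    rng = np.random.default_rng(k * 100 + int(theta * 10))
    a = random_symmetric_graph(rng, 12)
    s = score_matrix(normalize(a), GcasParams(K=k, theta=theta))
    expected = dense_gcas_oracle(a, k, theta)
    np.testing.assert_allclose(s.matrix, expected, atol=1e-10)


def test_closed_form_limits():
    rng = np.random.default_rng(7)
    a = random_symmetric_graph(rng, 10)
    norm = normalize(a)
    ahat = norm.a_hat.toarray()
    # K=1: S = offdiag(Â)
    s1 = score_matrix(norm, GcasParams(K=1)).matrix
    expected1 = ahat.copy()
    np.fill_diagonal(expected1, 0)
    np.testing.assert_allclose(s1, expected1, atol=1e-12)
    # theta=0, K>=2: S = offdiag(Â + Â²)
    s2 = score_matrix(norm, GcasParams(K=5, theta=0.0)).matrix
    expected2 = ahat + ahat @ ahat
    np.fill_diagonal(expected2, 0)
    np.testing.assert_allclose(s2, expected2, atol=1e-12)
    # theta=1: S = offdiag(sum of all powers)
    s3 = score_matrix(norm, GcasParams(K=4, theta=1.0)).matrix
    expected3 = sum(np.linalg.matrix_power(ahat, t) for t in range(1, 5))
    np.fill_diagonal(expected3, 0)
    np.testing.assert_allclose(s3, expected3, atol=1e-10)


@given(seed=st.integers(0, 5000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_scores_symmetric_monotone_in_k_and_bounded(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    a = random_symmetric_graph(rng, n)
    norm = normalize(a)
    prev = None
    for k in (1, 2, 4, 7):
        s = score_matrix(norm, GcasParams(K=k, theta=0.3)).matrix
        assert np.max(np.abs(s - s.T)) <= 1e-12
        assert s.max() <= k + 1e-9
        if prev is not None:
            assert np.all(s - prev >= -1e-12)
        prev = s


def test_propagate_agrees_with_score_matrix_columns():
    rng = np.random.default_rng(11)
    a = random_symmetric_graph(rng, 15)
    norm = normalize(a)
    params = GcasParams(K=6, theta=0.25)
    s = score_matrix(norm, params)
    for seed_idx in range(15):
        vec = propagate(norm, seed_idx, params)
        vec = vec.copy()
        vec[seed_idx] = 0.0
        np.testing.assert_allclose(s.matrix[seed_idx], vec, atol=1e-12)


def test_dense_guard():
    rng = np.random.default_rng(0)
    a = random_symmetric_graph(rng, 25)
    norm = normalize(a)
    with pytest.raises(UsageError, match="per-seed"):
        score_matrix(norm, dense_guard=10)
    s = score_matrix(norm, dense_guard=10, force=True)
    assert s.matrix.shape == (25, 25)


def test_infer_only_new_pairs(path3_net):
    inferred = infer_associations(path3_net, GcasParams(K=2, theta=0.25))
    pairs = {(a.a, a.b) for a in inferred}
    assert pairs == {("A", "C")}
    assert inferred[0].weight == pytest.approx(1 / 6)
    assert inferred[0].provenance == "inferred"


def test_infer_retention_policies(path3_net):
    # floor above max score: nothing retained
    assert infer_associations(
        path3_net, GcasParams(K=9), Retention(top_m=100, tau=100.0)
    ) == []
    # top_m=1: each node contributes at most one new partner
    rng = np.random.default_rng(5)
    from gcas import Entity, HeteroNetwork
    net = HeteroNetwork()
    for i in range(8):
        net.add_entity(Entity(f"G{i}", "gene", f"g{i}"))
    for i in range(7):
        net.add_assoc(f"G{i}", f"G{i+1}", float(rng.random() + 0.1), "curated")
    inferred = infer_associations(net, GcasParams(K=4), Retention(top_m=1, tau=0.0))
    from collections import Counter
    counts = Counter()
    for a in inferred:
        counts[a.a] += 1
        counts[a.b] += 1
    # a pair survives if either endpoint retains it, so a node can appear
    # more than once, but the retained-by count per node is at most top_m
    assert len(inferred) <= 8


def test_augment_idempotent_and_validated(path3_net):
    inferred = infer_associations(path3_net, GcasParams(K=2))
    h1 = augment(path3_net, inferred)
    assert h1.n_edges == path3_net.n_edges + 1
    h2 = augment(h1, inferred)
    assert h2 == h1
    assert augment(path3_net, []) == path3_net
    from gcas import Assoc, NetworkError
    with pytest.raises(NetworkError):
        augment(path3_net, [Assoc("A", "ZZ", 0.1, "inferred", "gcas")])


def test_normalize_network_order_matches(toy_net):
    norm = normalize_network(toy_net)
    assert norm.node_order == toy_net.node_order
    a, _ = toy_net.adjacency_matrix()
    degs = np.asarray(a.sum(axis=1)).ravel() + 1
    row = norm.a_hat.toarray()[0]
    # spot-check one entry against the formula
    i, j = 0, int(np.flatnonzero(row[1:])[0]) + 1
    assert row[j] == pytest.approx(a[i, j] / np.sqrt(degs[i] * degs[j]))
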