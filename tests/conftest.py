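"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
import scipy.sparse as sp

from gcas import (
    Entity,
    GcasParams,
    HeteroNetwork,
    SynthConfig,
    generate,
)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def dense_gcas_oracle(a: np.ndarray, k: int, theta: float) -> np.ndarray:
    """Explicit dense Σ_t θ^{max(t−2,0)} Â^t with Â built from scratch."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    a_tilde = a + np.eye(n)
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = np.diag(1.0 / np.sqrt(d))
    a_hat = d_inv_sqrt @ a_tilde @ d_inv_sqrt
    s = np.zeros((n, n))
    power = np.eye(n)
    for t in range(1, k + 1):
        power = power @ a_hat
        s += (theta ** max(t - 2, 0)) * power
    np.fill_diagonal(s, 0.0)
    return s


def roc_auc_n_oracle(target_ranks, n_candidates, n_limit, n_targets=None):
    """Step-by-step ROC enumeration: walk the ranked list, accumulate TP
    fraction at each of the first N false positives (list exhaustion means
    every remaining FP slot sees all found targets)."""
    targets = set(target_ranks)
    total = n_targets if n_targets is not None else len(targets)
    area = 0.0
    tp = 0
    fp = 0
    for pos in range(1, n_candidates + 1):
        if pos in targets:
            tp += 1
        else:
            fp += 1
            if fp <= n_limit:
                area += tp / total
            else:
                break
    while fp < n_limit:  # fewer negatives than N: flat tail at current TPR
        fp += 1
        area += tp / total
    return area / n_limit


def random_symmetric_graph(rng, n, density=0.3, weighted=True):
    """Random symmetric non-negative zero-diagonal adjacency."""
    mask = rng.random((n, n)) < density
    w = rng.random((n, n)) * 3 if weighted else np.ones((n, n))
    a = np.triu(mask * w, k=1)
    return a + a.T


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_net():
    """p1–d1–g1 plus g1–g2 interaction and g1 in pathway w1."""
    net = HeteroNetwork()
    net.add_entity(Entity("HP:0000001", "phenotype", "root phenotype"))
    net.add_entity(Entity("ORPHA:1", "disease", "toy disease"))
    net.add_entity(Entity("G1", "gene", "gene one"))
    net.add_entity(Entity("G2", "gene", "gene two"))
    net.add_entity(Entity("WP:1", "pathway", "toy pathway"))
    net.add_assoc("HP:0000001", "ORPHA:1", 0.9, "curated", "disease-resource")
    net.add_assoc("ORPHA:1", "G1", 1.0, "curated", "disease-resource")
    net.add_assoc("G1", "G2", 1.0, "curated", "ppi")
    net.add_assoc("G1", "WP:1", 1.0, "curated", "pathway")
    return net


@pytest.fixture
def path3_net():
    """Unweighted 3-node path a–b–c of gene nodes."""
    net = HeteroNetwork()
    for g in ("A", "B", "C"):
        net.add_entity(Entity(g, "gene", f"gene {g}"))
    net.add_assoc("A", "B", 1.0, "curated", "ppi")
    net.add_assoc("B", "C", 1.0, "curated", "ppi")
    return net


@pytest.fixture(scope="session")
def small_synth():
    """Small seeded synthetic network for mid-weight tests."""
    cfg = SynthConfig(
        n_phenotypes=60, n_diseases=15, n_genes=50, n_pathways=4,
        n_planted_cases=10, seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default-condition synthetic benchmark (shared: it is the
    heaviest object the suite builds)."""
    return generate(SynthConfig(seed=2024))
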