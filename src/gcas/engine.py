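"""Graph Convolution-based Association Scoring (GCAS).

The scoring operator is the first-order approximation of a spectral
graph convolution: with ``Ã = A + I`` and ``D̃`` its degree matrix, one
convolution multiplies a signal by ``Â = D̃^{-1/2} Ã D̃^{-1/2}``.
Information propagated to the t-th order neighbourhood after *t*
consecutive convolutions is ``C_t(x) = θ' Â^t x`` with a per-step filter
parameter; fixing the first two steps at 1 and the remainder at a
damping factor θ gives

    S = Σ_{t=1}^{K}  θ^{max(t−2, 0)} · Â^t

so damping applies only to information flowing along paths of three or
more links.  Only the off-diagonal entries of ``S`` are association
scores.  ``K`` bounds the convolution depth (pairs more than K links
apart score zero); default parameters are K=9 and θ=0.25.

Everything is computed by repeated sparse matrix products in double
precision, accumulated in ascending ``t`` for reproducibility; ``Â^t``
is never materialized in per-seed mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .errors import DataError, NetworkError, UsageError
from .network import Assoc, HeteroNetwork, copy_network

DEFAULT_K = 9
DEFAULT_THETA = 0.25
DENSE_GUARD = 20_000


@dataclass(frozen=True)
class GcasParams:
    """Convolution depth bound ``K`` and damping factor ``theta``."""

    K: int = DEFAULT_K
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise UsageError(f"K must be an integer >= 1, got {self.K!r}")
        if not 0.0 <= self.theta <= 1.0:
            raise UsageError(f"theta must lie in [0, 1], got {self.theta!r}")

    def step_factor(self, t: int) -> float:
        """Multiplier for the order-t term: 1, 1, θ, θ², ... (0⁰ := 1)."""
        return 1.0 if t <= 2 else float(self.theta) ** (t - 2)


@dataclass(frozen=True)
class Retention:
    """Which inferred scores become edges: per-node top-m and a score floor."""

    top_m: int = 100
    tau: float = 1e-4

    def __post_init__(self) -> None:
        if self.top_m < 1:
            raise UsageError("retention top_m must be >= 1")
        if self.tau < 0:
            raise UsageError("retention tau must be >= 0")


@dataclass
class NormalizedAdjacency:
    """Â = D̃^{-1/2}(A+I)D̃^{-1/2} plus the node order it was built under."""

    a_hat: sp.csr_matrix
    node_order: Tuple[str, ...]

    @property
    def n(self) -> int:
        return self.a_hat.shape[0]

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_order.index(node_id)
        except ValueError:
            raise DataError(f"node {node_id!r} not in this operator") from None


def normalize(
    a, node_order: Optional[Sequence[str]] = None
) -> NormalizedAdjacency:
    """Self-loop-normalized adjacency Â from a symmetric non-negative A.

    An isolated node has Ã row (0…1…0) and degree 1, so its Â entry is 1
    on its own position and it neither sends nor receives mass.
    """
    a = sp.csr_matrix(a, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise DataError(f"adjacency must be square, got {a.shape}")
    if (abs(a - a.T) > 1e-12).nnz:
        raise DataError("adjacency must be symmetric")
    if a.nnz and a.data.min() < 0:
        raise DataError("adjacency entries must be non-negative")
    if a.diagonal().any():
        raise DataError("adjacency must have a zero diagonal (self-loops enter via A+I)")
    n = a.shape[0]
    a_tilde = a + sp.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    a_hat = sp.csr_matrix(d_inv_sqrt @ a_tilde @ d_inv_sqrt)
    order = tuple(node_order) if node_order is not None else tuple(str(i) for i in range(n))
    if len(order) != n:
        raise UsageError("node_order length does not match the matrix size")
    return NormalizedAdjacency(a_hat=a_hat, node_order=order)


def normalize_network(net: HeteroNetwork) -> NormalizedAdjacency:
    """Â of a heterogeneous network (provenance-summed adjacency)."""
    a, order = net.adjacency_matrix()
    return normalize(a, order)


def propagate(
    norm: NormalizedAdjacency, seed: int, params: GcasParams = GcasParams()
) -> np.ndarray:
    """Cumulative damped convolution signal from one seed node.

    Returns ``s = Σ_{t=1}^{K} θ^{max(t−2,0)} Â^t e_seed`` as a dense
    vector over ``node_order``.  The seed's own coordinate is included
    in the vector but is not an association score (diagonal excluded
    downstream).  Uses K sparse matrix–vector products only.
    """
    n = norm.n
    if not 0 <= seed < n:
        raise UsageError(f"seed index {seed} out of range [0, {n})")
    x = np.zeros(n)
    x[seed] = 1.0
    cur = norm.a_hat @ x          # Â^1 e
    s = cur.copy()
    for t in range(2, params.K + 1):
        cur = norm.a_hat @ cur    # Â^t e, undamped
        s += params.step_factor(t) * cur
    return s


@dataclass
class ScoreSet:
    """Off-diagonal pairwise GCAS scores under a fixed node order."""

    matrix: np.ndarray
    node_order: Tuple[str, ...]
    params: GcasParams

    def __post_init__(self) -> None:
        np.fill_diagonal(self.matrix, 0.0)
        self._index = {nid: i for i, nid in enumerate(self.node_order)}

    def score(self, a: str, b: str) -> float:
        if a == b:
            raise UsageError("scores are defined for distinct node pairs only")
        try:
            return float(self.matrix[self._index[a], self._index[b]])
        except KeyError as exc:
            raise DataError(f"unknown node {exc.args[0]!r}") from None

    def iter_pairs(self, tau: float = 0.0) -> Iterator[Tuple[str, str, float]]:
        """Unordered pairs with score >= tau (>0), in node-order sequence."""
        n = len(self.node_order)
        for i in range(n):
            row = self.matrix[i]
            for j in range(i + 1, n):
                v = row[j]
                if v > 0 and v >= tau:
                    yield self.node_order[i], self.node_order[j], float(v)


def score_matrix(
    norm: NormalizedAdjacency,
    params: GcasParams = GcasParams(),
    dense_guard: int = DENSE_GUARD,
    force: bool = False,
) -> ScoreSet:
    """Full pairwise score matrix ``S = Σ_t θ^{max(t−2,0)} Â^t`` (off-diagonal).

    Equivalent to one :func:`propagate` per node; guarded against
    accidentally densifying very large networks — pass ``force=True`` or
    use per-seed propagation for those.
    """
    n = norm.n
    if n > dense_guard and not force:
        raise UsageError(
            f"network has {n} nodes (> dense guard {dense_guard}); "
            "use per-seed propagate() or pass force=True"
        )
    cur = norm.a_hat.toarray()
    s = cur.copy()
    for t in range(2, params.K + 1):
        cur = norm.a_hat @ cur
        s += params.step_factor(t) * cur
    return ScoreSet(matrix=s, node_order=norm.node_order, params=params)


def infer_associations(
    net: HeteroNetwork,
    params: GcasParams = GcasParams(),
    retention: Retention = Retention(),
    dense_guard: int = DENSE_GUARD,
    force: bool = False,
) -> List[Assoc]:
    """Run GCAS on the initial network and return new inferred edges.

    Only node pairs *not* already joined by a stored (curated or
    ontological) edge become inferred associations, weighted by their
    GCAS score.  Retention keeps, per node, its ``top_m`` best new
    partners with score at least ``tau``; a pair survives if either
    endpoint retains it.
    """
    norm = normalize_network(net)
    scores = score_matrix(norm, params, dense_guard=dense_guard, force=force)
    order = scores.node_order
    n = len(order)
    existing = np.zeros((n, n), dtype=bool)
    index = {nid: i for i, nid in enumerate(order)}
    for assoc in net.edges():
        i, j = index[assoc.a], index[assoc.b]
        existing[i, j] = existing[j, i] = True
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        row = scores.matrix[i].copy()
        row[existing[i]] = -np.inf
        row[i] = -np.inf
        eligible = np.flatnonzero((row >= retention.tau) & (row > 0))
        if eligible.size > retention.top_m:
            # ties broken toward smaller node index for determinism
            top = eligible[np.lexsort((eligible, -row[eligible]))][: retention.top_m]
        else:
            top = eligible
        keep[i, top] = True
    keep |= keep.T
    out: List[Assoc] = []
    for i in range(n):
        for j in np.flatnonzero(keep[i]):
            if j <= i:
                continue
            out.append(
                Assoc(order[i], order[j], float(scores.matrix[i, j]), "inferred", "gcas")
            )
    return out


def augment(net: HeteroNetwork, inferred: Sequence[Assoc]) -> HeteroNetwork:
    """Initial network ∪ inferred edges — the integrated association network.

    The node set is unchanged; provenance tags keep inferred edges
    distinguishable.  Idempotent under re-augmentation with the same set
    (max-merge edge semantics).
    """
    out = copy_network(net)
    for assoc in inferred:
        if not (out.has_node(assoc.a) and out.has_node(assoc.b)):
            missing = assoc.a if not out.has_node(assoc.a) else assoc.b
            raise NetworkError(f"inferred edge touches unknown node {missing!r}")
        out.add_assoc(assoc.a, assoc.b, assoc.weight, assoc.provenance, assoc.source)
    return out
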