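"""Heterogeneous association network: domain types, matrix export, projection.

The network holds four entity types (phenotype, disease, gene, pathway)
joined by undirected, non-negatively weighted edges.  Each stored edge
carries a provenance tag (``ontological``, ``curated`` or ``inferred``);
at most one edge is stored per unordered node pair per provenance, and
re-adding the same pair+provenance keeps the maximum weight so ingestion
is idempotent across overlapping source files.  When the network is
exported as an adjacency matrix, parallel edges across provenances are
summed — curated and inferred evidence both contribute propagation mass.

Node order for matrix export is the lexicographic sort of node ids, so
matrices are bit-reproducible across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .errors import NetworkError

ENTITY_TYPES = ("phenotype", "disease", "gene", "pathway")
PROVENANCES = ("ontological", "curated", "inferred")


@dataclass
class Entity:
    """A node: namespaced id, entity type, preferred label, synonyms."""

    id: str
    etype: str
    label: str
    synonyms: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise NetworkError(f"unknown entity type {self.etype!r} for {self.id!r}")
        if not self.label:
            raise NetworkError(f"entity {self.id!r} has an empty label")
        self.synonyms = set(self.synonyms)


@dataclass
class Assoc:
    """An undirected weighted edge; (a, b) is stored with a < b."""

    a: str
    b: str
    weight: float
    provenance: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise NetworkError(f"self-loop on {self.a!r} rejected")
        if self.weight < 0:
            raise NetworkError(
                f"negative weight {self.weight} on ({self.a!r}, {self.b!r})"
            )
        if self.provenance not in PROVENANCES:
            raise NetworkError(f"unknown provenance {self.provenance!r}")
        if self.a > self.b:
            self.a, self.b = self.b, self.a

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.a, self.b, self.provenance)


class HeteroNetwork:
    """Weighted undirected multityped graph with provenance-tagged edges."""

    def __init__(self) -> None:
        self._nodes: Dict[str, Entity] = {}
        self._edges: Dict[Tuple[str, str, str], Assoc] = {}
        # combined (provenance-summed) weight per neighbour, kept incrementally
        self._adj: Dict[str, Dict[str, float]] = {}

    # -- nodes ---------------------------------------------------------------

    def add_entity(self, e: Entity) -> "HeteroNetwork":
        existing = self._nodes.get(e.id)
        if existing is None:
            self._nodes[e.id] = Entity(e.id, e.etype, e.label, set(e.synonyms))
            self._adj[e.id] = {}
        elif existing.etype != e.etype:
            raise NetworkError(
                f"id {e.id!r} already present as {existing.etype!r}, "
                f"cannot re-add as {e.etype!r}"
            )
        else:  # same id, same type: merge synonyms, keep first label
            existing.synonyms |= e.synonyms
        return self

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def entity(self, node_id: str) -> Entity:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise NetworkError(f"unknown node {node_id!r}") from None

    def nodes(self, etype: Optional[str] = None) -> List[str]:
        if etype is None:
            return sorted(self._nodes)
        return sorted(i for i, e in self._nodes.items() if e.etype == etype)

    def etype(self, node_id: str) -> str:
        return self.entity(node_id).etype

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    # -- edges ---------------------------------------------------------------

    def add_assoc(
        self,
        a: str,
        b: str,
        weight: float,
        provenance: str,
        source: str = "",
    ) -> "HeteroNetwork":
        for end in (a, b):
            if end not in self._nodes:
                raise NetworkError(f"edge endpoint {end!r} is not in the network")
        assoc = Assoc(a, b, float(weight), provenance, source)
        prev = self._edges.get(assoc.key)
        if prev is not None and prev.weight >= assoc.weight:
            return self  # max-merge: keep the stronger record
        self._edges[assoc.key] = assoc
        self._reindex_pair(assoc.a, assoc.b)
        return self

    def _reindex_pair(self, a: str, b: str) -> None:
        total = sum(
            self._edges[(a, b, p)].weight for p in PROVENANCES if (a, b, p) in self._edges
        )
        self._adj[a][b] = total
        self._adj[b][a] = total

    def edges(self) -> Iterator[Assoc]:
        for key in sorted(self._edges):
            yield self._edges[key]

    def get_assoc(self, a: str, b: str, provenance: str) -> Optional[Assoc]:
        if a > b:
            a, b = b, a
        return self._edges.get((a, b, provenance))

    def combined_weight(self, a: str, b: str) -> float:
        """Provenance-summed weight between two nodes (0 if unlinked)."""
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, node_id: str) -> Dict[str, float]:
        if node_id not in self._nodes:
            raise NetworkError(f"unknown node {node_id!r}")
        return dict(self._adj[node_id])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, {})

    def degree(self, node_id: str) -> int:
        return len(self._adj.get(node_id, {}))

    # -- matrix export -------------------------------------------------------

    @property
    def node_order(self) -> Tuple[str, ...]:
        """Lexicographic node ordering used for all matrix exports."""
        return tuple(sorted(self._nodes))

    def adjacency_matrix(self) -> Tuple[sp.csr_matrix, Tuple[str, ...]]:
        """Symmetric zero-diagonal adjacency; weights summed across provenances."""
        if not self._nodes:
            raise NetworkError("cannot export the adjacency of an empty network")
        order = self.node_order
        index = {nid: i for i, nid in enumerate(order)}
        rows: List[int] = []
        cols: List[int] = []
        vals: List[float] = []
        seen: Set[Tuple[str, str]] = set()
        for assoc in self.edges():
            pair = (assoc.a, assoc.b)
            if pair in seen:
                continue
            seen.add(pair)
            w = self._adj[assoc.a][assoc.b]
            i, j = index[assoc.a], index[assoc.b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        a = sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)),
            shape=(len(order), len(order)),
        )
        return a, order

    # -- projection ----------------------------------------------------------

    def collapse_to_trunc(self) -> "HeteroNetwork":
        """Project onto phenotype and gene nodes (the *trunc* network).

        Disease and pathway intermediaries are removed.  Every 2-hop
        phenotype–disease–gene path becomes a direct phenotype–gene edge
        whose weight is the sum over mediating diseases of the product of
        the two path-edge weights.  Phenotype–phenotype and gene–gene
        edges are retained unchanged.
        """
        phenos = set(self.nodes("phenotype"))
        genes = set(self.nodes("gene"))
        if not phenos or not genes:
            raise NetworkError("trunc projection needs at least one phenotype and one gene")
        out = HeteroNetwork()
        keep = phenos | genes
        for nid in sorted(keep):
            e = self._nodes[nid]
            out.add_entity(Entity(e.id, e.etype, e.label, set(e.synonyms)))
        for assoc in self.edges():
            if assoc.a in keep and assoc.b in keep:
                out.add_assoc(assoc.a, assoc.b, assoc.weight, assoc.provenance, assoc.source)
        # introduce phenotype–disease–gene shortcuts
        introduced: Dict[Tuple[str, str], float] = {}
        for d in self.nodes("disease"):
            nbrs = self._adj[d]
            d_phenos = [(n, w) for n, w in nbrs.items() if n in phenos]
            d_genes = [(n, w) for n, w in nbrs.items() if n in genes]
            for p, wp in d_phenos:
                for g, wg in d_genes:
                    key = (p, g) if p < g else (g, p)
                    introduced[key] = introduced.get(key, 0.0) + wp * wg
        for (a, b), w in sorted(introduced.items()):
            if w > 0:
                out.add_assoc(a, b, w, "curated", "trunc")
        return out

    # -- serialization -------------------------------------------------------

    def save(self, outdir) -> None:
        """Write the 2-file TSV dialect (nodes.tsv + edges.tsv)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "nodes.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["id", "etype", "label", "synonyms"])
            for nid in sorted(self._nodes):
                e = self._nodes[nid]
                w.writerow([e.id, e.etype, e.label, "|".join(sorted(e.synonyms))])
        with open(outdir / "edges.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["a", "b", "weight", "provenance", "source"])
            for assoc in self.edges():
                w.writerow([assoc.a, assoc.b, repr(assoc.weight), assoc.provenance, assoc.source])

    @classmethod
    def load(cls, indir) -> "HeteroNetwork":
        indir = Path(indir)
        net = cls()
        with open(indir / "nodes.tsv", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            next(r)  # header
            for row in r:
                nid, etype, label, syn = row
                syns = set(s for s in syn.split("|") if s)
                net.add_entity(Entity(nid, etype, label, syns))
        with open(indir / "edges.tsv", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            next(r)
            for row in r:
                a, b, wt, prov, source = row
                net.add_assoc(a, b, float(wt), prov, source)
        return net

    # -- equality ------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroNetwork):
            return NotImplemented
        if set(self._nodes) != set(other._nodes):
            return False
        for nid, e in self._nodes.items():
            o = other._nodes[nid]
            if (e.etype, e.label, e.synonyms) != (o.etype, o.label, o.synonyms):
                return False
        if set(self._edges) != set(other._edges):
            return False
        for key, a in self._edges.items():
            o = other._edges[key]
            if a.weight != o.weight or a.source != o.source:
                return False
        return True

    def __repr__(self) -> str:
        counts = {t: len(self.nodes(t)) for t in ENTITY_TYPES}
        return f"HeteroNetwork(nodes={counts}, edges={self.n_edges})"


def copy_network(net: HeteroNetwork) -> HeteroNetwork:
    """Deep copy preserving node order, edges and provenance tags."""
    out = HeteroNetwork()
    for nid in net.nodes():
        e = net.entity(nid)
        out.add_entity(Entity(e.id, e.etype, e.label, set(e.synonyms)))
    for assoc in net.edges():
        out.add_assoc(assoc.a, assoc.b, assoc.weight, assoc.provenance, assoc.source)
    return out
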