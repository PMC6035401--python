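"""Information content and Lin similarity over the phenotype is-a DAG.

Edge weights for phenotype–phenotype associations come from the Lin
measure, ``2·IC(mica) / (IC(p1) + IC(p2))``, where ``mica`` is the most
informative common ancestor and ``IC(p) = −ln(f(p)/N)`` with ``f(p)``
the descendant-inclusive annotation frequency of term ``p`` in a corpus
of total size ``N``.  The corpus is injectable; by default the network
builder uses the disease→phenotype annotation counts of the disease
resource.  Zero-frequency terms receive add-one smoothing so the IC is
finite everywhere and every ontology edge gets a defined weight.

Lin edges are assigned only to direct is-a pairs — all-pairs similarity
would densify the graph quadratically without adding ontological
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import math

import networkx as nx

from .errors import DataError
from .network import Assoc

SYNTHETIC_ROOT = "VIRTUAL:ROOT"


class OntologyDAG:
    """Rooted is-a DAG over phenotype terms.

    Multi-rooted sources get a synthetic super-root (IC 0 by
    construction) so that every pair of terms has a common ancestor.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        g = nx.DiGraph()  # edges child -> parent
        for term, ps in parents.items():
            g.add_node(term)
            for p in ps:
                g.add_node(p)
                g.add_edge(term, p)
        if g.number_of_nodes() == 0:
            raise DataError("empty ontology")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataError(f"is_a cycle detected: {cycle}")
        roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
        if len(roots) > 1:
            for r in roots:
                g.add_edge(r, SYNTHETIC_ROOT)
            root = SYNTHETIC_ROOT
        else:
            root = roots[0]
        self._g = g
        self.root = root
        self._ancestors: Dict[str, FrozenSet[str]] = {}

    @property
    def terms(self) -> List[str]:
        return sorted(self._g.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def parents(self, term: str) -> Set[str]:
        self._check(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> Set[str]:
        self._check(term)
        return set(self._g.predecessors(term))

    def is_a_pairs(self) -> List[Tuple[str, str]]:
        """Direct (parent, child) pairs, sorted, synthetic root excluded."""
        return sorted(
            (p, c) for c, p in self._g.edges if p != SYNTHETIC_ROOT
        )

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Reflexive ancestor set (the term itself included)."""
        self._check(term)
        cached = self._ancestors.get(term)
        if cached is None:
            anc = {term}
            for p in self._g.successors(term):
                anc |= self.ancestors(p)
            cached = frozenset(anc)
            self._ancestors[term] = cached
        return cached

    def descendants(self, term: str) -> FrozenSet[str]:
        self._check(term)
        return frozenset(nx.ancestors(self._g, term) | {term})

    def _check(self, term: str) -> None:
        if term not in self._g:
            raise DataError(f"term {term!r} is not in the ontology")


@dataclass
class ICMap:
    """Per-term information content with its underlying frequency table."""

    ic: Dict[str, float]
    n_total: int
    f: Dict[str, int]

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise DataError(f"no information content for term {term!r}") from None


def descendant_counts(
    dag: OntologyDAG, annotations: Mapping[str, int]
) -> Tuple[Dict[str, int], int]:
    """Descendant-inclusive annotation frequencies ``f`` and corpus size ``N``.

    ``f(p)`` sums direct annotation counts over ``p`` and all its
    descendants with set-union semantics: a term annotated below a
    diamond is counted once at each ancestor, not once per path.  Terms
    left at zero get add-one smoothing; ``N = f(root)`` after smoothing.
    """
    unknown = sorted(t for t in annotations if t not in dag)
    if unknown:
        raise DataError(f"annotations on unknown terms: {', '.join(unknown)}")
    f: Dict[str, int] = {t: 0 for t in dag.terms}
    for term, count in annotations.items():
        if count < 0:
            raise DataError(f"negative annotation count on {term!r}")
        if count == 0:
            continue
        for anc in dag.ancestors(term):
            f[anc] += count
    for t in f:
        if f[t] == 0:
            f[t] = 1
    return f, f[dag.root]


def information_content(f: Mapping[str, int], n_total: int) -> ICMap:
    """``IC(p) = −ln(f(p)/N)``; the root (``f = N``) has IC 0."""
    if n_total <= 0:
        raise DataError("corpus size N must be positive")
    ic: Dict[str, float] = {}
    for term in sorted(f):
        freq = f[term]
        if not 0 < freq <= n_total:
            raise DataError(
                f"frequency f({term!r}) = {freq} outside (0, N={n_total}]"
            )
        ic[term] = -math.log(freq / n_total)
    return ICMap(ic=ic, n_total=int(n_total), f=dict(f))


def most_informative_common_ancestor(
    dag: OntologyDAG, ic: ICMap, p1: str, p2: str
) -> str:
    """Common ancestor with maximal IC; ties go to the smallest term id."""
    common = dag.ancestors(p1) & dag.ancestors(p2)
    if not common:
        raise DataError(f"{p1!r} and {p2!r} share no ancestor")
    return min(common, key=lambda t: (-ic[t], t))


def lin_similarity(dag: OntologyDAG, ic: ICMap, p1: str, p2: str) -> float:
    """Lin similarity in [0, 1]; the degenerate 0/0 case is defined as 0."""
    mica = most_informative_common_ancestor(dag, ic, p1, p2)
    denom = ic[p1] + ic[p2]
    if denom == 0:
        return 0.0
    s = 2.0 * ic[mica] / denom
    # numerically clamp; analytically 0 <= s <= 1 since IC(mica) <= min IC
    return min(max(s, 0.0), 1.0)


def ontology_edges(dag: OntologyDAG, ic: ICMap) -> List[Assoc]:
    """One ontological edge per direct is-a pair, weighted by Lin similarity."""
    out: List[Assoc] = []
    for parent, child in dag.is_a_pairs():
        w = lin_similarity(dag, ic, parent, child)
        out.append(Assoc(parent, child, w, "ontological", "ontology"))
    return out
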