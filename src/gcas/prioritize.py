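"""Phenotype-set queries: ranked causal-gene lists by cumulative score.

Each query phenotype contributes its edge weights (curated + inferred,
provenance-summed) to its gene neighbours; the cumulative score of a
gene over a phenotype set is the plain sum over the individual
phenotypes.  Ranking is by score descending with ties broken by gene id
so output is deterministic.  Query phenotypes absent from the network
are skipped with a warning rather than failing — clinical inputs are
noisy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .engine import GcasParams, NormalizedAdjacency, normalize_network, propagate
from .errors import DataError
from .ingest import CaseRecord
from .network import HeteroNetwork

log = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Ordered genes for a phenotype query, with per-phenotype breakdown."""

    query: Tuple[str, ...]
    entries: List[Tuple[str, float, Dict[str, float]]]
    skipped: Tuple[str, ...] = ()

    def rank_of(self, gene: str) -> Optional[int]:
        """1-based rank of a gene, or None if it is not in the list."""
        for rank, (g, _s, _b) in enumerate(self.entries, 1):
            if g == gene:
                return rank
        return None

    def __len__(self) -> int:
        return len(self.entries)


def gene_scores(hanrd: HeteroNetwork, phenotype: str) -> Dict[str, float]:
    """Provenance-summed edge weight from one phenotype to each gene neighbour."""
    if not hanrd.has_node(phenotype):
        raise DataError(f"phenotype {phenotype!r} is not in the network")
    return {
        nbr: w
        for nbr, w in hanrd.neighbors(phenotype).items()
        if hanrd.etype(nbr) == "gene" and w > 0
    }


def _live_gene_scores(
    hanrd: HeteroNetwork,
    phenotype: str,
    norm: NormalizedAdjacency,
    params: GcasParams,
) -> Dict[str, float]:
    """Per-query propagation instead of reading stored (retained) edges."""
    vec = propagate(norm, norm.node_order.index(phenotype), params)
    out: Dict[str, float] = {}
    for idx, nid in enumerate(norm.node_order):
        if nid != phenotype and vec[idx] > 0 and hanrd.etype(nid) == "gene":
            out[nid] = float(vec[idx])
    return out


def rank_genes(
    hanrd: HeteroNetwork,
    query: Iterable[str],
    live_propagation: bool = False,
    params: GcasParams = GcasParams(),
) -> RankedGeneList:
    """Cumulative-score gene ranking for a set of query phenotypes.

    With ``live_propagation`` the scores are recomputed by running the
    convolution from each query phenotype over the current network,
    bypassing the retention truncation applied when the network was
    augmented.
    """
    query = tuple(sorted(set(query)))
    present = [p for p in query if hanrd.has_node(p) and hanrd.etype(p) == "phenotype"]
    skipped = tuple(p for p in query if p not in present)
    if not present:
        raise DataError("no resolvable phenotypes in query")
    for p in skipped:
        log.warning("query phenotype %r not in network; skipped", p)
    norm = normalize_network(hanrd) if live_propagation else None
    cumulative: Dict[str, float] = {}
    breakdown: Dict[str, Dict[str, float]] = {}
    for p in present:
        per = (
            _live_gene_scores(hanrd, p, norm, params)
            if live_propagation
            else gene_scores(hanrd, p)
        )
        for g, w in per.items():
            cumulative[g] = cumulative.get(g, 0.0) + w
            breakdown.setdefault(g, {})[p] = w
    entries = [
        (g, cumulative[g], breakdown[g])
        for g in sorted(cumulative, key=lambda g: (-cumulative[g], g))
    ]
    return RankedGeneList(query=tuple(present), entries=entries, skipped=skipped)


def rank_for_case(
    hanrd: HeteroNetwork,
    case: CaseRecord,
    live_propagation: bool = False,
    params: GcasParams = GcasParams(),
) -> Tuple[RankedGeneList, Dict[str, Optional[int]], Optional[int]]:
    """Ranked list for a clinical case plus its causal-gene ranks.

    Returns ``(ranked list, {causal gene -> 1-based rank or None},
    case rank)`` where the case rank is the best (minimum) rank over the
    causal genes — a case counts as captured in Top-k when any of its
    causal genes does.
    """
    ranked = rank_genes(hanrd, case.phenotypes, live_propagation, params)
    position = {g: r for r, (g, _s, _b) in enumerate(ranked.entries, 1)}
    causal_ranks: Dict[str, Optional[int]] = {
        g: position.get(g) for g in sorted(case.causal_genes)
    }
    found = [r for r in causal_ranks.values() if r is not None]
    return ranked, causal_ranks, (min(found) if found else None)
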