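"""Parsers for the input resource dialects and assembly of the initial network.

Five sources feed the initial (pre-inference) network, mirroring its five
curated/ontological edge classes:

* a phenotype ontology in OBO format       → phenotype nodes + Lin-weighted
  phenotype–phenotype edges over the is-a hierarchy;
* a disease resource (TSV or XML dialect)  → disease nodes, phenotype–disease
  edges weighted by frequency qualifier, disease–gene edges of weight 1;
* a gene registry TSV of approved symbols  → gene nodes with aliases;
* pathway gene sets in GMT format          → pathway nodes + weight-1
  gene–pathway membership edges;
* a curated protein interaction TSV        → weight-1 gene–gene edges.

Clinical case files (one case = id, phenotype ids, causal gene symbols) are
parsed separately for the evaluation protocols.
"""

from __future__ import annotations

import csv
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import obonet

from .errors import DataError, ParseError
from .network import Assoc, Entity, HeteroNetwork
from .ontology import (
    ICMap,
    OntologyDAG,
    descendant_counts,
    information_content,
    ontology_edges,
)

log = logging.getLogger(__name__)

#: Frequency-qualifier → edge-weight map: midpoints of the published
#: frequency ranges (99–80% → 0.9, 79–30% → 0.55, 29–5% → 0.17, <4.9% → 0.02).
QUALIFIER_WEIGHTS: Dict[str, float] = {
    "obligate": 1.0,
    "very_frequent": 0.9,
    "frequent": 0.55,
    "occasional": 0.17,
    "very_rare": 0.02,
    "excluded": 0.0,
}

_TERM_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")
_SYNONYM_RE = re.compile(r'"([^"]*)"')


@dataclass
class CaseRecord:
    """One solved clinical case: phenotype query plus known causal gene(s)."""

    case_id: str
    phenotypes: Set[str]
    causal_genes: Set[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise DataError(f"case {self.case_id!r} has no phenotypes")
        if not self.causal_genes:
            raise DataError(f"case {self.case_id!r} has no causal genes")
        bad = sorted(p for p in self.phenotypes if not _TERM_ID_RE.match(p))
        if bad:
            raise DataError(
                f"case {self.case_id!r} has malformed phenotype ids: {', '.join(bad)}"
            )


def qualifier_weight(label: str) -> float:
    """Numeric weight for a frequency qualifier label.

    Labels are normalized before lookup: ``"Very frequent (99-80%)"`` →
    ``very_frequent``.
    """
    norm = re.sub(r"\([^)]*\)", "", label).strip().lower()
    norm = re.sub(r"[\s\-]+", "_", norm)
    try:
        return QUALIFIER_WEIGHTS[norm]
    except KeyError:
        raise DataError(f"unknown frequency qualifier {label!r}") from None


# ---------------------------------------------------------------------------
# ontology (OBO)
# ---------------------------------------------------------------------------

def _prevalidate_obo(path: Path) -> None:
    """Cheap line-level sanity pass so parse failures carry file + line."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") and line.endswith("]"):
                continue
            if ":" in line:
                continue
            raise ParseError(
                f"malformed OBO line {line!r}", path=str(path), line=lineno
            )


def parse_ontology(path) -> Tuple[OntologyDAG, List[Entity]]:
    """Read an OBO file into an is-a DAG plus one phenotype Entity per term.

    Obsolete terms are excluded; synonym and xref tag values are kept as
    entity synonyms.
    """
    path = Path(path)
    _prevalidate_obo(path)
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # pragma: no cover - depends on obonet internals
        raise ParseError(f"cannot parse OBO: {exc}", path=str(path)) from exc

    parents: Dict[str, Set[str]] = {}
    entities: List[Entity] = []
    live = {
        tid for tid, data in graph.nodes(data=True)
        if str(data.get("is_obsolete", "false")).lower() != "true"
    }
    for tid in sorted(live):
        data = graph.nodes[tid]
        name = data.get("name") or tid
        syns: Set[str] = set()
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            syns.add(m.group(1) if m else raw)
        syns.update(data.get("xref", []))
        entities.append(Entity(tid, "phenotype", name, syns))
        parents[tid] = {p for p in graph.successors(tid) if p in live}
    if not parents:
        raise ParseError("OBO file contains no usable terms", path=str(path))
    try:
        dag = OntologyDAG(parents)
    except DataError as exc:
        raise ParseError(str(exc), path=str(path)) from exc
    return dag, entities


# ---------------------------------------------------------------------------
# disease resource (TSV or XML dialect)
# ---------------------------------------------------------------------------

def parse_disease_resource(
    path, known_phenotypes: Optional[Set[str]] = None
) -> Tuple[List[Entity], List[Tuple[str, str, float]], List[Tuple[str, str]]]:
    """Disease entities, qualifier-weighted phenotype–disease pairs,
    and weight-1 disease–gene pairs.

    The flat TSV dialect has columns ``disease_id, disease_name, kind,
    target, qualifier`` with ``kind`` in {phenotype, gene}; the XML
    dialect nests ``<phenotype id= qualifier=/>`` and ``<gene symbol=/>``
    under ``<disease id= name=>``.  Associations whose phenotype id is
    not in ``known_phenotypes`` (when given) are skipped with a warning;
    excluded-qualifier (weight 0) annotations are dropped — they cannot
    carry propagation mass.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    rows = (
        _disease_rows_xml(path) if head == "<" else _disease_rows_tsv(path)
    )
    diseases: Dict[str, Entity] = {}
    pd_pairs: Dict[Tuple[str, str], float] = {}
    dg_pairs: Set[Tuple[str, str]] = set()
    for did, dname, kind, target, qualifier, lineno in rows:
        if did not in diseases:
            diseases[did] = Entity(did, "disease", dname or did)
        if kind == "phenotype":
            w = qualifier_weight(qualifier)
            if known_phenotypes is not None and target not in known_phenotypes:
                log.warning(
                    "%s:%s: unknown phenotype %r for disease %r; skipped",
                    path, lineno, target, did,
                )
                continue
            if w > 0:
                key = (target, did)
                pd_pairs[key] = max(pd_pairs.get(key, 0.0), w)
        elif kind == "gene":
            dg_pairs.add((did, target))
        else:
            raise ParseError(
                f"unknown association kind {kind!r}", path=str(path), line=lineno
            )
    return (
        [diseases[d] for d in sorted(diseases)],
        sorted((p, d, w) for (p, d), w in pd_pairs.items()),
        sorted(dg_pairs),
    )


def _disease_rows_tsv(path: Path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["disease_id", "disease_name"]:
            raise ParseError("bad disease TSV header", path=str(path), line=1)
        for lineno, row in enumerate(reader, 2):
            if not row or not row[0]:
                continue
            if len(row) < 5:
                raise ParseError("short disease row", path=str(path), line=lineno)
            yield row[0], row[1], row[2], row[3], row[4], lineno


def _disease_rows_xml(path: Path):
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"bad XML: {exc}", path=str(path)) from exc
    for dis in tree.getroot().iter("disease"):
        did = dis.get("id")
        dname = dis.get("name", "")
        if not did:
            raise ParseError("disease element without id", path=str(path))
        for ph in dis.iter("phenotype"):
            yield did, dname, "phenotype", ph.get("id", ""), ph.get("qualifier", ""), None
        for g in dis.iter("gene"):
            yield did, dname, "gene", g.get("symbol", ""), "", None


# ---------------------------------------------------------------------------
# gene registry, pathways, interactions, cases
# ---------------------------------------------------------------------------

def parse_gene_registry(path) -> List[Entity]:
    """TSV of approved symbols (columns: symbol, name, status, aliases)."""
    path = Path(path)
    genes: Dict[str, Entity] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "symbol" not in reader.fieldnames:
            raise ParseError("gene registry needs a 'symbol' column", path=str(path), line=1)
        for row in reader:
            symbol = (row.get("symbol") or "").strip()
            if not symbol:
                continue
            status = (row.get("status") or "Approved").strip().lower()
            if status == "withdrawn":
                continue
            aliases = {a for a in (row.get("aliases") or "").split("|") if a}
            if symbol in genes:
                genes[symbol].synonyms |= aliases
            else:
                genes[symbol] = Entity(
                    symbol, "gene", row.get("name") or symbol, aliases
                )
    return [genes[s] for s in sorted(genes)]


def parse_pathways(path_gmt) -> Tuple[List[Entity], List[Tuple[str, str]]]:
    """GMT gene sets → pathway entities plus (gene, pathway) memberships."""
    path = Path(path_gmt)
    pathways: List[Entity] = []
    memberships: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("GMT line needs name and description", path=str(path), line=lineno)
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            pathways.append(Entity(name, "pathway", desc or name))
            if not genes:
                log.warning("%s:%s: pathway %r has no member genes", path, lineno, name)
            for g in set(genes):
                memberships.add((g, name))
    return pathways, sorted(memberships)


def parse_ppi(path) -> List[Tuple[str, str]]:
    """Curated interaction TSV → undirected unique gene symbol pairs."""
    path = Path(path)
    pairs: Set[Tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ParseError("empty interaction file", path=str(path), line=1)
        for lineno, row in enumerate(reader, 2):
            if not row or not row[0]:
                continue
            if len(row) < 2:
                raise ParseError("interaction row needs two symbols", path=str(path), line=lineno)
            a, b = row[0].strip(), row[1].strip()
            if a == b:
                continue  # self-interactions carry no between-node association
            pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def parse_cases(path) -> List[CaseRecord]:
    """Clinical case TSV (case_id, phenotypes, causal_genes, source)."""
    path = Path(path)
    cases: List[CaseRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"case_id", "phenotypes", "causal_genes"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                "case file needs columns case_id, phenotypes, causal_genes",
                path=str(path), line=1,
            )
        for lineno, row in enumerate(reader, 2):
            cid = (row.get("case_id") or "").strip()
            if not cid:
                continue
            phenos = {p.strip() for p in (row.get("phenotypes") or "").split(",") if p.strip()}
            genes = {g.strip() for g in (row.get("causal_genes") or "").split(",") if g.strip()}
            try:
                cases.append(
                    CaseRecord(cid, phenos, genes, (row.get("source") or "").strip())
                )
            except DataError as exc:
                raise ParseError(str(exc), path=str(path), line=lineno) from exc
    return cases


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _norm_label(label: str) -> str:
    return re.sub(r"\s+", " ", label).strip().casefold()


def build_network(
    ontology: Tuple[OntologyDAG, List[Entity]],
    diseases: Tuple[List[Entity], List[Tuple[str, str, float]], List[Tuple[str, str]]],
    genes: List[Entity],
    pathways: Optional[Tuple[List[Entity], List[Tuple[str, str]]]] = None,
    ppi: Optional[List[Tuple[str, str]]] = None,
    ic_annotations: Optional[Mapping[str, int]] = None,
) -> HeteroNetwork:
    """Assemble the initial ontological + curated association network.

    Edge classes: Lin-weighted phenotype–phenotype (ontological),
    qualifier-weighted phenotype–disease, weight-1 disease–gene, weight-1
    gene–gene interactions, weight-1 gene–pathway memberships.  Concepts
    present as both a phenotype and a disease (same normalized label) are
    kept as two nodes bridged by a weight-1 curated edge.

    The IC corpus defaults to the disease→phenotype annotation counts of
    the disease resource; pass ``ic_annotations`` to substitute any other
    count table.
    """
    dag, pheno_entities = ontology
    disease_entities, pd_pairs, dg_pairs = diseases
    net = HeteroNetwork()
    for e in pheno_entities:
        net.add_entity(e)
    for e in disease_entities:
        net.add_entity(e)
    for e in genes:
        net.add_entity(e)
    if pathways is not None:
        for e in pathways[0]:
            net.add_entity(e)
    if net.n_nodes == 0:
        raise DataError("no entities in any input source")

    # ontological phenotype–phenotype edges over the is-a hierarchy
    if ic_annotations is None:
        counts: Dict[str, int] = {}
        for p, _d, _w in pd_pairs:
            counts[p] = counts.get(p, 0) + 1
        ic_annotations = counts
    f, n_total = descendant_counts(dag, ic_annotations)
    ic = information_content(f, n_total)
    for assoc in ontology_edges(dag, ic):
        if net.has_node(assoc.a) and net.has_node(assoc.b):
            net.add_assoc(assoc.a, assoc.b, assoc.weight, assoc.provenance, assoc.source)

    # curated phenotype–disease, disease–gene
    for p, d, w in pd_pairs:
        if not net.has_node(p):
            log.warning("phenotype %r not in ontology; association to %r skipped", p, d)
            continue
        net.add_assoc(p, d, w, "curated", "disease-resource")
    for d, g in dg_pairs:
        if not net.has_node(g):
            log.warning("gene %r from disease resource absent from registry; node created", g)
            net.add_entity(Entity(g, "gene", g))
        net.add_assoc(d, g, 1.0, "curated", "disease-resource")

    # curated gene–gene interactions
    for a, b in ppi or []:
        for g in (a, b):
            if not net.has_node(g):
                log.warning("interaction symbol %r absent from registry; node created", g)
                net.add_entity(Entity(g, "gene", g))
        net.add_assoc(a, b, 1.0, "curated", "ppi")

    # gene–pathway memberships
    if pathways is not None:
        for g, pw in pathways[1]:
            if not net.has_node(g):
                log.warning("pathway member %r absent from registry; node created", g)
                net.add_entity(Entity(g, "gene", g))
            net.add_assoc(g, pw, 1.0, "curated", "pathway")

    # cross-vocabulary duplicates: same concept as phenotype and disease
    by_label: Dict[str, str] = {}
    for p in net.nodes("phenotype"):
        by_label.setdefault(_norm_label(net.entity(p).label), p)
    for d in net.nodes("disease"):
        p = by_label.get(_norm_label(net.entity(d).label))
        if p is not None:
            net.add_assoc(p, d, 1.0, "curated", "xref")
    return net
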