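"""Synthetic heterogeneous networks with planted phenotype–gene truth.

The generator emulates the structure of the real sources: a rooted
random is-a DAG of phenotype terms, diseases annotated to a phenotype
clade with sampled frequency qualifiers and to a handful of causal
genes, an interaction network and pathway gene sets over the genes, and
clinical case records derived from disease-mediated phenotype sets.
Planted (phenotype, gene) pairs are connected only through a disease
intermediary — never by a direct edge — so recovering them genuinely
requires multi-hop propagation.

All randomness flows from one seeded generator; the same seed yields a
byte-identical network, and a written fixture bundle re-ingested through
the parsers reproduces the generated network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from . import ingest
from .errors import ConfigError
from .ingest import CaseRecord, QUALIFIER_WEIGHTS
from .network import Entity, HeteroNetwork
from .ontology import OntologyDAG

#: weight → qualifier label, for writing disease fixtures back out
_WEIGHT_TO_QUALIFIER = {w: q for q, w in QUALIFIER_WEIGHTS.items()}

_QUALIFIER_POOL = ("obligate", "very_frequent", "frequent", "occasional", "very_rare")
_QUALIFIER_P = (0.10, 0.30, 0.35, 0.20, 0.05)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a desk-scale network (200 phenotypes, 40 diseases,
    150 genes, 10 pathways) with 50 planted cases; rates are per-disease
    annotation means and per-pair interaction probability.
    """

    n_phenotypes: int = 200
    n_diseases: int = 40
    n_genes: int = 150
    n_pathways: int = 10
    ontology_branching: float = 3.0
    disease_phenotype_rate: float = 4.0
    disease_gene_rate: float = 2.0
    ppi_rate: float = 0.02
    pathway_size: float = 12.0
    n_planted_cases: int = 50
    withhold_planted_links: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phenotypes", "n_diseases", "n_genes", "n_pathways", "n_planted_cases"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("ontology_branching", "disease_phenotype_rate", "disease_gene_rate", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.ppi_rate <= 1:
            raise ConfigError("ppi_rate must lie in (0, 1]")


@dataclass
class SynthTruth:
    """Planted (phenotype, gene) pairs and the case records built from them."""

    planted_pairs: Set[Tuple[str, str]]
    cases: List[CaseRecord]
    withheld_links: Set[Tuple[str, str]] = field(default_factory=set)


def _pheno_id(i: int) -> str:
    return f"HP:{i:07d}"


def _disease_id(i: int) -> str:
    return f"ORPHA:{100000 + i}"


def _gene_symbol(i: int) -> str:
    return f"SGN{i:04d}"


def _pathway_id(i: int) -> str:
    return f"WP:{i:04d}"


def generate(config: SynthConfig) -> Tuple[HeteroNetwork, SynthTruth, OntologyDAG]:
    """Generate a network, its planted truth, and the phenotype DAG.

    The network is assembled through the same builder the parsers feed,
    so writing fixtures and re-ingesting them is an exact round trip.
    """
    rng = np.random.default_rng(config.seed)

    # --- ontology: random rooted tree plus occasional extra parents -------
    terms = [_pheno_id(i + 1) for i in range(config.n_phenotypes)]
    parents: Dict[str, Set[str]] = {terms[0]: set()}
    for i in range(1, config.n_phenotypes):
        # parent among the last ~branching·depth window biases tree shape
        j = int(rng.integers(0, i))
        parents[terms[i]] = {terms[j]}
        if i > 2 and rng.random() < 0.1:  # extra is-a link, keeps DAG (index < i)
            k = int(rng.integers(0, i))
            if k != j:
                parents[terms[i]].add(terms[k])
    dag = OntologyDAG(parents)
    pheno_entities = [
        Entity(t, "phenotype", f"Synthetic phenotype {t.split(':')[1]}")
        for t in terms
    ]

    # --- diseases: a phenotype clade + 1-3 causal genes -------------------
    gene_syms = [_gene_symbol(i + 1) for i in range(config.n_genes)]
    gene_entities = [Entity(g, "gene", f"Synthetic gene {g}") for g in gene_syms]
    disease_entities: List[Entity] = []
    pd_pairs: List[Tuple[str, str, float]] = []
    dg_pairs: List[Tuple[str, str]] = []
    disease_phenos: Dict[str, List[str]] = {}
    disease_genes: Dict[str, List[str]] = {}
    qualifier_of: Dict[Tuple[str, str], str] = {}
    for i in range(config.n_diseases):
        did = _disease_id(i + 1)
        disease_entities.append(Entity(did, "disease", f"Synthetic disease {i + 1}"))
        anchor = terms[int(rng.integers(0, config.n_phenotypes))]
        clade = sorted(dag.descendants(anchor))
        if len(clade) < 2:
            clade = terms
        n_ann = max(2, int(rng.poisson(config.disease_phenotype_rate)))
        n_ann = min(n_ann, len(clade))
        chosen = sorted(rng.choice(len(clade), size=n_ann, replace=False))
        phenos = [clade[c] for c in chosen]
        disease_phenos[did] = phenos
        for p in phenos:
            q = _QUALIFIER_POOL[
                int(rng.choice(len(_QUALIFIER_POOL), p=_QUALIFIER_P))
            ]
            qualifier_of[(p, did)] = q
            pd_pairs.append((p, did, QUALIFIER_WEIGHTS[q]))
        n_g = int(min(3, max(1, rng.poisson(config.disease_gene_rate))))
        gidx = sorted(rng.choice(config.n_genes, size=n_g, replace=False))
        dgenes = [gene_syms[g] for g in gidx]
        disease_genes[did] = dgenes
        for g in dgenes:
            dg_pairs.append((did, g))

    # --- interactions and pathways over genes -----------------------------
    ppi_pairs: List[Tuple[str, str]] = []
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            if rng.random() < config.ppi_rate:
                ppi_pairs.append((gene_syms[i], gene_syms[j]))
    pathway_entities: List[Entity] = []
    memberships: List[Tuple[str, str]] = []
    for i in range(config.n_pathways):
        pid = _pathway_id(i + 1)
        pathway_entities.append(Entity(pid, "pathway", f"Synthetic pathway {i + 1}"))
        size = min(config.n_genes, max(2, int(rng.poisson(config.pathway_size))))
        for g in sorted(rng.choice(config.n_genes, size=size, replace=False)):
            memberships.append((gene_syms[g], pid))
    memberships.sort()

    # --- planted cases: distinct (disease, causal gene) pairs -------------
    pair_pool = sorted(
        (did, g) for did, genes in disease_genes.items() for g in genes
    )
    if config.n_planted_cases > len(pair_pool):
        raise ConfigError(
            f"cannot plant {config.n_planted_cases} cases from only "
            f"{len(pair_pool)} disease–gene pairs"
        )
    picked = sorted(
        rng.choice(len(pair_pool), size=config.n_planted_cases, replace=False)
    )
    cases: List[CaseRecord] = []
    planted: Set[Tuple[str, str]] = set()
    withheld: Set[Tuple[str, str]] = set()
    for idx, pool_i in enumerate(picked, 1):
        did, gene = pair_pool[pool_i]
        phenos = disease_phenos[did]
        n_q = int(min(len(phenos), max(3, rng.integers(3, 6))))
        sel = sorted(rng.choice(len(phenos), size=n_q, replace=False))
        query = {phenos[s] for s in sel}
        cases.append(
            CaseRecord(f"CASE{idx:04d}", query, {gene}, source="synthetic")
        )
        planted |= {(p, gene) for p in query}
        if config.withhold_planted_links:
            withheld.add((did, gene))
    if withheld:
        dg_pairs = [pg for pg in dg_pairs if pg not in withheld]

    net = ingest.build_network(
        (dag, pheno_entities),
        (disease_entities, sorted(set(pd_pairs)), sorted(set(dg_pairs))),
        gene_entities,
        (pathway_entities, memberships),
        sorted(set(ppi_pairs)),
    )
    truth = SynthTruth(planted_pairs=planted, cases=cases, withheld_links=withheld)
    return net, truth, dag


def write_fixtures(
    net: HeteroNetwork, dag: OntologyDAG, truth: SynthTruth, outdir
) -> Dict[str, Path]:
    """Write the miniature fixture bundle in every supported input dialect.

    Emits ``ontology.obo``, ``diseases.tsv``, ``genes.tsv``,
    ``pathways.gmt``, ``ppi.tsv`` and ``cases.tsv`` such that
    :func:`gcas.ingest.build_network` over the bundle reproduces ``net``
    exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("ontology", "ontology.obo"), ("diseases", "diseases.tsv"),
        ("genes", "genes.tsv"), ("pathways", "pathways.gmt"),
        ("ppi", "ppi.tsv"), ("cases", "cases.tsv"),
    ]}

    with open(paths["ontology"], "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotypes\n")
        for term in dag.terms:
            e = net.entity(term)
            fh.write(f"\n[Term]\nid: {term}\nname: {e.label}\n")
            for syn in sorted(e.synonyms):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")

    with open(paths["diseases"], "w") as fh:
        fh.write("disease_id\tdisease_name\tkind\ttarget\tqualifier\n")
        for did in net.nodes("disease"):
            label = net.entity(did).label
            for nbr, _w in sorted(net.neighbors(did).items()):
                assoc = net.get_assoc(did, nbr, "curated")
                if assoc is None or assoc.source != "disease-resource":
                    continue
                if net.etype(nbr) == "phenotype":
                    q = _WEIGHT_TO_QUALIFIER[assoc.weight]
                    fh.write(f"{did}\t{label}\tphenotype\t{nbr}\t{q}\n")
                elif net.etype(nbr) == "gene":
                    fh.write(f"{did}\t{label}\tgene\t{nbr}\t\n")

    with open(paths["genes"], "w") as fh:
        fh.write("symbol\tname\tstatus\taliases\n")
        for g in net.nodes("gene"):
            e = net.entity(g)
            fh.write(f"{g}\t{e.label}\tApproved\t{'|'.join(sorted(e.synonyms))}\n")

    with open(paths["pathways"], "w") as fh:
        for pw in net.nodes("pathway"):
            e = net.entity(pw)
            members = [
                nbr for nbr in sorted(net.neighbors(pw))
                if net.etype(nbr) == "gene"
            ]
            fh.write("\t".join([pw, e.label] + members) + "\n")

    with open(paths["ppi"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for assoc in net.edges():
            if assoc.source == "ppi":
                fh.write(f"{assoc.a}\t{assoc.b}\n")

    with open(paths["cases"], "w") as fh:
        fh.write("case_id\tphenotypes\tcausal_genes\tsource\n")
        for case in truth.cases:
            fh.write(
                f"{case.case_id}\t{','.join(sorted(case.phenotypes))}\t"
                f"{','.join(sorted(case.causal_genes))}\t{case.source}\n"
            )
    return paths


def ingest_fixtures(outdir) -> Tuple[HeteroNetwork, List[CaseRecord]]:
    """Re-ingest a fixture bundle through the standard parsers."""
    outdir = Path(outdir)
    dag, phenos = ingest.parse_ontology(outdir / "ontology.obo")
    diseases = ingest.parse_disease_resource(
        outdir / "diseases.tsv", known_phenotypes=set(dag.terms)
    )
    genes = ingest.parse_gene_registry(outdir / "genes.tsv")
    pathways = ingest.parse_pathways(outdir / "pathways.gmt")
    ppi = ingest.parse_ppi(outdir / "ppi.tsv")
    net = ingest.build_network((dag, phenos), diseases, genes, pathways, ppi)
    cases = ingest.parse_cases(outdir / "cases.tsv")
    return net, cases
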