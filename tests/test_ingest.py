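"""Resource parsers and initial-network assembly."""

import textwrap

import pytest

from gcas import ParseError, build_network, parse_cases, parse_ontology, qualifier_weight
from gcas.errors import DataError
from gcas.ingest import (
    parse_disease_resource,
    parse_gene_registry,
    parse_pathways,
    parse_ppi,
)

OBO_3TERM = textwrap.dedent("""\
    format-version: 1.2
    ontology: test

    [Term]
    id: HP:0000001
    name: All

    [Term]
    id: HP:0000002
    name: Abnormality
    synonym: "anomaly" EXACT []
    is_a: HP:0000001

    [Term]
    id: HP:0000003
    name: Specific finding
    is_a: HP:0000002
""")


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_parse_ontology_fixture(tmp_path):
    dag, entities = parse_ontology(_write(tmp_path, "o.obo", OBO_3TERM))
    assert len(entities) == 3
    assert len(dag.is_a_pairs()) == 2
    assert dag.root == "HP:0000001"
    by_id = {e.id: e for e in entities}
    assert "anomaly" in by_id["HP:0000002"].synonyms


def test_parse_ontology_skips_obsolete(tmp_path):
    obo = OBO_3TERM + "\n[Term]\nid: HP:0000004\nname: gone\nis_obsolete: true\n"
    dag, entities = parse_ontology(_write(tmp_path, "o.obo", obo))
    assert len(entities) == 3
    assert "HP:0000004" not in dag


def test_parse_ontology_cycle(tmp_path):
    obo = textwrap.dedent("""\
        format-version: 1.2
        ontology: test

        [Term]
        id: HP:0000001
        name: a
        is_a: HP:0000002

        [Term]
        id: HP:0000002
        name: b
        is_a: HP:0000001
    """)
    with pytest.raises(ParseError, match="cycle"):
        parse_ontology(_write(tmp_path, "bad.obo", obo))


def test_parse_ontology_malformed_line_reports_position(tmp_path):
    bad = OBO_3TERM + "this line has no tag separator\n"
    with pytest.raises(ParseError) as exc:
        parse_ontology(_write(tmp_path, "bad.obo", bad))
    assert exc.value.line is not None
    assert "bad.obo" in str(exc.value)


def test_qualifier_weight_table_and_normalization():
    assert qualifier_weight("obligate") == 1.0
    assert qualifier_weight("excluded") == 0.0
    assert qualifier_weight("Very frequent (99-80%)") == 0.9
    assert qualifier_weight("frequent") == 0.55
    assert qualifier_weight("occasional") == 0.17
    assert qualifier_weight("very rare") == 0.02
    with pytest.raises(DataError):
        qualifier_weight("sometimes")


DISEASE_TSV = textwrap.dedent("""\
    disease_id\tdisease_name\tkind\ttarget\tqualifier
    ORPHA:1\tdisease one\tphenotype\tHP:0000002\tvery_frequent
    ORPHA:1\tdisease one\tgene\tG1\t
    ORPHA:2\tdisease two\tphenotype\tHP:0000003\texcluded
    ORPHA:2\tdisease two\tgene\tG1\t
""")


def test_parse_disease_resource_tsv(tmp_path):
    entities, pd, dg = parse_disease_resource(_write(tmp_path, "d.tsv", DISEASE_TSV))
    assert [e.id for e in entities] == ["ORPHA:1", "ORPHA:2"]
    assert pd == [("HP:0000002", "ORPHA:1", 0.9)]  # excluded edge dropped
    assert dg == [("ORPHA:1", "G1"), ("ORPHA:2", "G1")]


def test_parse_disease_resource_unknown_phenotype_skipped(tmp_path, caplog):
    path = _write(tmp_path, "d.tsv", DISEASE_TSV)
    _e, pd, _dg = parse_disease_resource(path, known_phenotypes={"HP:0000003"})
    assert pd == []  # HP:0000002 unknown -> warned and skipped


def test_parse_disease_resource_xml(tmp_path):
    xml = textwrap.dedent("""\
        <diseases>
          <disease id="ORPHA:1" name="disease one">
            <phenotype id="HP:0000002" qualifier="very_frequent"/>
            <gene symbol="G1"/>
          </disease>
        </diseases>
    """)
    entities, pd, dg = parse_disease_resource(_write(tmp_path, "d.xml", xml))
    assert pd == [("HP:0000002", "ORPHA:1", 0.9)]
    assert dg == [("ORPHA:1", "G1")]


def test_parse_gene_registry(tmp_path):
    tsv = textwrap.dedent("""\
        symbol\tname\tstatus\taliases
        G1\tgene one\tApproved\tA1|A2|A3
        G2\tgene two\tApproved\t
        G3\tgene three\tWithdrawn\t
    """)
    genes = parse_gene_registry(_write(tmp_path, "g.tsv", tsv))
    assert [g.id for g in genes] == ["G1", "G2"]
    assert genes[0].synonyms == {"A1", "A2", "A3"}


def test_parse_pathways(tmp_path):
    gmt = "WP:1\tfirst pathway\tG1\tG2\tG3\tG4\nWP:2\tsecond\tG1\tG1\n"
    pathways, members = parse_pathways(_write(tmp_path, "p.gmt", gmt))
    assert [p.id for p in pathways] == ["WP:1", "WP:2"]
    assert len([m for m in members if m[1] == "WP:1"]) == 4
    assert members.count(("G1", "WP:2")) == 1  # duplicate within line deduped
    assert ("G1", "WP:1") in members and ("G1", "WP:2") in members


def test_parse_ppi(tmp_path):
    tsv = "gene_a\tgene_b\nG1\tG2\nG2\tG1\nG3\tG3\nG1\tG3\nG2\tG4\n"
    pairs = parse_ppi(_write(tmp_path, "ppi.tsv", tsv))
    assert pairs == [("G1", "G2"), ("G1", "G3"), ("G2", "G4")]


def test_parse_cases(tmp_path):
    tsv = textwrap.dedent("""\
        case_id\tphenotypes\tcausal_genes\tsource
        C1\tHP:0000002,HP:0000003\tG1\tpub1
        C2\tHP:0000002\tG1,G2\tpub2
    """)
    cases = parse_cases(_write(tmp_path, "c.tsv", tsv))
    assert len(cases) == 2
    assert cases[1].causal_genes == {"G1", "G2"}


def test_parse_cases_rejects_malformed(tmp_path):
    bad = "case_id\tphenotypes\tcausal_genes\nC1\tHP:BAD\tG1\n"
    with pytest.raises(ParseError, match="C1"):
        parse_cases(_write(tmp_path, "c.tsv", bad))
    empty = "case_id\tphenotypes\tcausal_genes\nC1\t\tG1\n"
    with pytest.raises(ParseError):
        parse_cases(_write(tmp_path, "c2.tsv", empty))


def _fixture_bundle(tmp_path):
    ontology = parse_ontology(_write(tmp_path, "o.obo", OBO_3TERM))
    diseases = parse_disease_resource(_write(tmp_path, "d.tsv", DISEASE_TSV))
    genes = parse_gene_registry(_write(
        tmp_path, "g.tsv",
        "symbol\tname\tstatus\taliases\nG1\tgene one\tApproved\t\nG2\tgene two\tApproved\t\n",
    ))
    pathways = parse_pathways(_write(tmp_path, "p.gmt", "WP:1\tpw\tG1\tG2\n"))
    ppi = parse_ppi(_write(tmp_path, "ppi.tsv", "gene_a\tgene_b\nG1\tG2\n"))
    return ontology, diseases, genes, pathways, ppi


def test_build_network_tally(tmp_path):
    ontology, diseases, genes, pathways, ppi = _fixture_bundle(tmp_path)
    net = build_network(ontology, diseases, genes, pathways, ppi)
    # by-hand tally: 3 phenotypes + 2 diseases + 2 genes + 1 pathway
    assert net.n_nodes == 8
    # edges: 2 ontological is-a, 1 phenotype-disease (excluded dropped),
    # 2 disease-gene, 1 ppi, 2 gene-pathway
    assert net.n_edges == 8
    assert net.combined_weight("HP:0000002", "ORPHA:1") == 0.9
    assert net.combined_weight("ORPHA:2", "G1") == 1.0


def test_build_network_without_pathways(tmp_path):
    ontology, diseases, genes, _pathways, ppi = _fixture_bundle(tmp_path)
    net = build_network(ontology, diseases, genes, None, ppi)
    assert net.nodes("pathway") == []
    assert net.n_edges == 6


def test_build_network_cross_vocabulary_bridge(tmp_path):
    ontology, diseases, genes, pathways, ppi = _fixture_bundle(tmp_path)
    # disease one's label made to collide with a phenotype label
    tsv = DISEASE_TSV.replace("disease one", "Abnormality")
    diseases = parse_disease_resource(_write(tmp_path, "d2.tsv", tsv))
    net = build_network(ontology, diseases, genes, pathways, ppi)
    bridge = net.get_assoc("HP:0000002", "ORPHA:1", "curated")
    assert bridge is not None and bridge.source == "xref"
    assert bridge.weight == 1.0
    # both nodes still exist separately
    assert net.etype("HP:0000002") == "phenotype"
    assert net.etype("ORPHA:1") == "disease"
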