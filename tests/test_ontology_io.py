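"""OWL/JSON serialization: vocabulary, round-trips, external import."""

import json

import pytest
from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL

from sonq import fixtures, query_gen
from sonq.ontology_io import (
    SON,
    SON_CLASSES,
    SON_PROPERTIES,
    MissingVocabularyError,
    UngeneratedQueriesError,
    check_json_schema,
    from_owl,
    import_external_ontology,
    to_json,
    to_json_obj,
    to_owl,
    to_owl_graph,
)
from sonq.son_model import DSON

COMPOSITE_EXAMPLE = (
    "(unexpected OR unforeseeable OR unknown) "
    "AND (complication OR failure OR incident)"
)


def _vocab_counts(graph):
    classes = [
        c for c in graph.subjects(RDF.type, OWL.Class)
        if str(c).startswith(str(SON))
    ]
    props = [
        p for p in graph.subjects(RDF.type, OWL.AnnotationProperty)
        if str(p).startswith(str(SON))
    ]
    return len(classes), len(props)


def test_empty_dson_emits_base_vocabulary_only():
    graph = to_owl_graph(DSON(name="empty"))
    assert _vocab_counts(graph) == (9, 13)
    domain = [
        c for c in graph.subjects(RDF.type, OWL.Class)
        if not str(c).startswith(str(SON))
    ]
    assert domain == []


def test_vocabulary_rosters_match_their_counts():
    assert len(SON_CLASSES) == 9 and len(set(SON_CLASSES)) == 9
    assert len(SON_PROPERTIES) == 13 and len(set(SON_PROPERTIES)) == 13


def test_every_document_carries_the_vocabulary(niti_generated):
    assert _vocab_counts(to_owl_graph(niti_generated)) == (9, 13)


def test_composite_class_carries_generated_query(niti_generated):
    graph = to_owl_graph(niti_generated)
    ns = Namespace(niti_generated.namespace)
    iri = ns["Unexpected__Complication"]
    assert (iri, RDFS.subClassOf, SON.Composite_Term) in graph
    queries = [str(o) for o in graph.objects(iri, SON.query)]
    assert COMPOSITE_EXAMPLE in queries
    assert graph.value(iri, SON.has_term_of_concept_as_part_1) == ns.Unexpected
    assert graph.value(iri, SON.has_term_of_concept_as_part_2) == ns.Complication


def test_facet_hierarchy_mirrored_as_subclass_axioms(niti_generated):
    graph = to_owl_graph(niti_generated)
    ns = Namespace(niti_generated.namespace)
    assert (ns["Endoscopic_Clipping_System"], RDFS.subClassOf, ns["Clip"]) in graph
    assert (ns["Clip"], RDFS.subClassOf, SON.Standard_Concept) in graph
    assert (ns["No_Preclinical"], RDFS.subClassOf, SON.Negated_Concept) in graph


def test_simple_terms_are_language_tagged(niti_generated):
    graph = to_owl_graph(niti_generated)
    ns = Namespace(niti_generated.namespace)
    literals = list(graph.objects(ns["Nitinol"], SON.simple_term))
    assert sorted(str(l) for l in literals) == [
        "NiTi", "Nickel Titanium", "Nitinol",
    ]
    assert all(l.language == "en" for l in literals)


def test_ungenerated_dson_is_rejected(niti_dson):
    with pytest.raises(UngeneratedQueriesError):
        to_owl(niti_dson)


def test_owl_roundtrip_on_example(niti_generated):
    assert from_owl(to_owl(niti_generated)) == niti_generated


@pytest.mark.parametrize("seed", range(25))
def test_owl_roundtrip_on_random_dsons(seed):
    dson = fixtures.random_dson(seed)
    query_gen.generate_all(dson)
    assert from_owl(to_owl(dson)) == dson


def test_owl_output_is_deterministic(niti_generated):
    first = to_owl(niti_generated)
    rebuilt = fixtures.build_niti_dson()
    query_gen.generate_all(
        rebuilt, query_gen.GenerationOptions(languages=("en",))
    )
    assert to_owl(rebuilt) == first


def test_turtle_accepted_on_read(niti_generated):
    turtle = to_owl_graph(niti_generated).serialize(format="turtle")
    assert from_owl(turtle) == niti_generated


def test_vocabulary_only_document_reads_as_empty_dson():
    dson = from_owl(to_owl(DSON(name="empty")))
    assert dson.facets == [] and not list(dson.iter_concepts())


def test_missing_vocabulary_is_an_error():
    g = Graph()
    g.add((URIRef("http://x#A"), RDF.type, OWL.Class))
    with pytest.raises(MissingVocabularyError):
        from_owl(g.serialize(format="xml"))


def test_orphan_class_is_skipped_with_warning(niti_generated):
    graph = to_owl_graph(niti_generated)
    ns = Namespace(niti_generated.namespace)
    graph.add((ns["Orphan"], RDF.type, OWL.Class))
    with pytest.warns(UserWarning, match="Orphan"):
        dson = from_owl(graph.serialize(format="xml"))
    assert dson.find_concept("Orphan") is None
    assert dson == niti_generated


# -- JSON -------------------------------------------------------------------


def test_empty_dson_json_shape():
    doc = to_json_obj(DSON(name="empty"))
    assert list(doc) == [
        "name", "facets", "negated_concepts", "multiple_concept_queries",
    ]
    assert doc["facets"] == [] and doc["negated_concepts"] == []
    assert check_json_schema(doc) == []


def test_nitinol_node_has_three_english_terms(niti_generated):
    doc = to_json_obj(niti_generated)
    material = doc["facets"][0]
    (nitinol,) = material["children"]
    assert nitinol["name"] == "Nitinol"
    assert len(nitinol["simple_terms"]["en"]) == 3
    assert check_json_schema(doc) == []


def test_node_key_order_is_fixed(niti_generated):
    doc = to_json_obj(niti_generated)
    node = doc["facets"][0]["children"][0]
    assert list(node) == ["name", "type", "simple_terms", "query", "children"]


def test_json_via_owl_equals_json_direct(niti_generated):
    direct = to_json(niti_generated)
    via_owl = to_json(from_owl(to_owl(niti_generated)))
    assert direct == via_owl
    assert json.loads(direct)["name"] == "dSON-Niti"


@pytest.mark.parametrize("seed", range(10))
def test_json_path_equivalence_random(seed):
    dson = fixtures.random_dson(seed)
    query_gen.generate_all(dson)
    assert to_json(dson) == to_json(from_owl(to_owl(dson)))
    assert check_json_schema(to_json_obj(dson)) == []


# -- external import --------------------------------------------------------


def _toy_ontology():
    g = Graph()
    ex = Namespace("http://toy#")
    g.add((ex.A, RDF.type, OWL.Class))
    g.add((ex.B, RDF.type, OWL.Class))
    g.add((ex.A, RDFS.subClassOf, ex.B))
    g.add((ex.A, RDFS.label, Literal("alpha", lang="en")))
    return g, ex


def test_import_labels_become_terms_and_subclass_becomes_parent():
    g, ex = _toy_ontology()
    facet = import_external_ontology(g.serialize(format="xml"), "Imported")
    by_name = {c.name: c for c in facet.concepts}
    assert by_name["A"].parent == "B" and by_name["B"].parent is None
    assert [t.text for t in by_name["A"].simple_terms] == ["alpha"]
    # parent precedes child
    assert [c.name for c in facet.concepts].index("B") < [
        c.name for c in facet.concepts
    ].index("A")


def test_import_label_less_class_falls_back_to_local_name():
    g = Graph()
    g.add((URIRef("http://toy#Stent"), RDF.type, OWL.Class))
    facet = import_external_ontology(g.serialize(format="xml"), "F")
    (concept,) = facet.concepts
    assert concept.name == "Stent"
    assert [t.text for t in concept.simple_terms] == ["Stent"]


def test_import_diamond_keeps_first_parent_and_warns():
    g, ex = _toy_ontology()
    g.add((ex.C, RDF.type, OWL.Class))
    g.add((ex.A, RDFS.subClassOf, ex.C))
    with pytest.warns(UserWarning) as record:
        facet = import_external_ontology(g.serialize(format="xml"), "F")
    assert len(record) == 1
    by_name = {c.name: c for c in facet.concepts}
    assert by_name["A"].parent in ("B", "C")


def test_import_empty_ontology_is_an_error():
    from sonq.ontology_io import OntologyError

    with pytest.raises(OntologyError):
        import_external_ontology(Graph().serialize(format="xml"), "F")
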