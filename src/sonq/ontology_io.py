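"""OWL and JSON serialization of dSONs.

The upper search-ontology vocabulary — 9 classes (Search_Concept with
Standard/Negated specialisations, Search_Term with Simple/Composite,
Search_Query with Single/Multiple-concept) and 13 annotation properties
— lives in its own namespace and is emitted into every document.
Domain classes specialise these: facet roots sit under
``Standard_Concept`` with the facet hierarchy mirrored as subclass
axioms, negated concepts under ``Negated_Concept``, composite terms
under ``Composite_Term`` and multiple-concept queries under
``Multiple_Concept_Query``.  Simple terms and generated queries are
attached as language-tagged annotations.

RDF graphs are unordered, but term and operand order is significant
(generated query strings depend on it), so ordered collections carry
OWL axiom reifications with an ``index`` annotation in an auxiliary
namespace; facet order is kept in an RDF Seq on the ontology header.
All reification nodes are named IRIs, never blank nodes, which makes
the RDF/XML output byte-deterministic.

RDF/XML is the canonical output syntax; Turtle is also accepted on
input.  ``described_by``, ``has_part`` and
``has_terms_of_concept_as_part`` are emitted as vocabulary for v1.0
compatibility but are not instantiated.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from typing import Optional, Union

from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL

from .son_model import (
    DSON,
    CompositeTermSpec,
    Facet,
    MultipleConceptQuerySpec,
    SearchConcept,
    TermLiteral,
)
from .template_io import (
    near_to_cell,
    parse_near_cell,
    parse_term_cell,
    term_to_cell_fragment,
)

SON = Namespace("http://example.org/son#")
AUX = Namespace("http://example.org/son-aux#")

SON_CLASSES = (
    "Search_Concept",
    "Standard_Concept",
    "Negated_Concept",
    "Search_Term",
    "Simple_Term",
    "Composite_Term",
    "Search_Query",
    "Single_Concept_Query",
    "Multiple_Concept_Query",
)

SON_PROPERTIES = (
    "described_by",
    "has_part",
    "has_terms_of_concept_as_part",
    "has_term_of_concept_as_part_1",
    "has_term_of_concept_as_part_2",
    "has_query_of_concept_as_part",
    "simple_term",
    "composite_term",
    "query",
    "excluded_concept",
    "excluded_simple_term",
    "mode",
    "near",
)

_CLASS_HIERARCHY = {
    "Standard_Concept": "Search_Concept",
    "Negated_Concept": "Search_Concept",
    "Simple_Term": "Search_Term",
    "Composite_Term": "Search_Term",
    "Single_Concept_Query": "Search_Query",
    "Multiple_Concept_Query": "Search_Query",
}


class OntologyError(ValueError):
    pass


class UngeneratedQueriesError(OntologyError):
    """An item has terms but its query map is empty; run generate_all."""


class MissingVocabularyError(OntologyError):
    """The document does not contain the search-ontology base classes."""


# ---------------------------------------------------------------------------
# writing


class _Writer:
    def __init__(self, dson: DSON):
        self.dson = dson
        self.ns = Namespace(dson.namespace)
        self.graph = Graph()
        self.graph.bind("son", SON)
        self.graph.bind("aux", AUX)
        self.graph.bind("dson", self.ns)
        self.graph.bind("owl", OWL)
        self._axiom_count = 0

    def write(self) -> Graph:
        g = self.graph
        ont = URIRef(self.dson.namespace.rstrip("#/"))
        g.add((ont, RDF.type, OWL.Ontology))
        g.add((ont, AUX.name, Literal(self.dson.name)))
        g.add((ont, AUX.namespace, Literal(self.dson.namespace)))

        for name in SON_CLASSES:
            g.add((SON[name], RDF.type, OWL.Class))
        for child, parent in _CLASS_HIERARCHY.items():
            g.add((SON[child], RDFS.subClassOf, SON[parent]))
        for name in SON_PROPERTIES:
            g.add((SON[name], RDF.type, OWL.AnnotationProperty))

        # facet order on the ontology header
        seq = self.ns["Facet_Order"]
        g.add((ont, AUX.facets, seq))
        g.add((seq, RDF.type, RDF.Seq))
        for i, facet in enumerate(self.dson.facets, start=1):
            g.add((seq, URIRef(str(RDF) + f"_{i}"), Literal(facet.name)))

        for facet in self.dson.facets:
            for index, concept in enumerate(facet.concepts):
                self._write_concept(concept, facet, index)
        for index, concept in enumerate(self.dson.negated_concepts):
            self._write_concept(concept, None, index)
        for index, ct in enumerate(self.dson.composite_terms):
            self._write_composite(ct, index)
        for index, mq in enumerate(self.dson.multiple_queries):
            self._write_multiple_query(mq, index)
        return g

    # -- helpers ----------------------------------------------------------

    def _annotate(
        self, subject: URIRef, prop: URIRef, obj, index: Optional[int] = None
    ) -> None:
        """Add an annotation triple, optionally order-reified."""
        self.graph.add((subject, prop, obj))
        if index is None:
            return
        axiom = self.ns[f"Axiom_{self._axiom_count}"]
        self._axiom_count += 1
        g = self.graph
        g.add((axiom, RDF.type, OWL.Axiom))
        g.add((axiom, OWL.annotatedSource, subject))
        g.add((axiom, OWL.annotatedProperty, prop))
        g.add((axiom, OWL.annotatedTarget, obj))
        g.add((axiom, AUX["index"], Literal(index)))

    def _term_literal(self, term: TermLiteral) -> Literal:
        return Literal(term_to_cell_fragment(term), lang=term.language)

    def _check_generated(self, item, has_terms: bool, what: str) -> None:
        if has_terms and not item.query:
            raise UngeneratedQueriesError(
                f"{what} has terms but no generated query; "
                "run query_gen.generate_all first"
            )

    def _write_concept(
        self, concept: SearchConcept, facet: Optional[Facet], index: int
    ) -> None:
        g, ns = self.graph, self.ns
        iri = ns[concept.name]
        g.add((iri, RDF.type, OWL.Class))
        self._check_generated(
            concept,
            bool(concept.simple_terms or concept.composite_term_refs
                 or concept.excluded_concept_refs),
            f"concept {concept.name!r}",
        )
        if concept.is_negated:
            g.add((iri, RDFS.subClassOf, SON.Negated_Concept))
            term_prop = SON.excluded_simple_term
        else:
            parent = ns[concept.parent] if concept.parent else SON.Standard_Concept
            g.add((iri, RDFS.subClassOf, parent))
            term_prop = SON.simple_term
        if facet is not None:
            g.add((iri, AUX.facet, Literal(facet.name)))
        g.add((iri, AUX["index"], Literal(index)))
        for t_index, term in enumerate(concept.simple_terms):
            self._annotate(iri, term_prop, self._term_literal(term), t_index)
        for c_index, ref in enumerate(concept.composite_term_refs):
            self._annotate(iri, SON.composite_term, ns[ref], c_index)
        for e_index, ref in enumerate(concept.excluded_concept_refs):
            self._annotate(iri, SON.excluded_concept, ns[ref], e_index)
        for lang in sorted(concept.query):
            g.add((iri, SON.query, Literal(concept.query[lang], lang=lang)))

    def _write_composite(self, ct: CompositeTermSpec, index: int) -> None:
        g, ns = self.graph, self.ns
        iri = ns[ct.name]
        self._check_generated(ct, True, f"composite term {ct.name!r}")
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.subClassOf, SON.Composite_Term))
        g.add((iri, AUX["index"], Literal(index)))
        g.add((iri, AUX.concept, ns[ct.concept]))
        g.add((iri, SON.has_term_of_concept_as_part_1, ns[ct.part1]))
        g.add((iri, SON.has_term_of_concept_as_part_2, ns[ct.part2]))
        if ct.mode:
            g.add((iri, SON.mode, Literal(ct.mode)))
        if ct.near:
            g.add((iri, SON.near, Literal(near_to_cell(ct.near))))
        for lang in sorted(ct.query):
            g.add((iri, SON.query, Literal(ct.query[lang], lang=lang)))

    def _write_multiple_query(
        self, mq: MultipleConceptQuerySpec, index: int
    ) -> None:
        g, ns = self.graph, self.ns
        iri = ns[mq.name]
        self._check_generated(mq, bool(mq.concepts),
                              f"multiple-concept query {mq.name!r}")
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.subClassOf, SON.Multiple_Concept_Query))
        g.add((iri, AUX["index"], Literal(index)))
        for c_index, ref in enumerate(mq.concepts):
            self._annotate(iri, SON.has_query_of_concept_as_part,
                           ns[ref], c_index)
        if mq.mode:
            g.add((iri, SON.mode, Literal(mq.mode)))
        if mq.near:
            g.add((iri, SON.near, Literal(near_to_cell(mq.near))))
        for lang in sorted(mq.query):
            g.add((iri, SON.query, Literal(mq.query[lang], lang=lang)))


def to_owl_graph(dson: DSON) -> Graph:
    """Build the RDF graph for a dSON (vocabulary + domain classes)."""
    return _Writer(dson).write()


def to_owl(dson: DSON) -> str:
    """Serialise a generated dSON to an RDF/XML OWL document."""
    return to_owl_graph(dson).serialize(format="pretty-xml")


# ---------------------------------------------------------------------------
# reading


def _parse_graph(document: Union[str, bytes, Graph]) -> Graph:
    if isinstance(document, Graph):
        return document
    errors = []
    for fmt in ("xml", "turtle"):
        try:
            return Graph().parse(data=document, format=fmt)
        except Exception as exc:  # noqa: BLE001 - report both attempts
            errors.append(f"{fmt}: {exc}")
    raise OntologyError(
        "document is neither RDF/XML nor Turtle: " + "; ".join(errors)
    )


def _local_name(iri: URIRef, namespace: str) -> str:
    return str(iri)[len(namespace):]


class _Reader:
    def __init__(self, graph: Graph):
        self.graph = graph
        if (SON.Search_Concept, RDF.type, OWL.Class) not in graph:
            raise MissingVocabularyError(
                "search-ontology base classes not found in document"
            )
        self.order = self._load_order()

    def _load_order(self) -> dict[tuple, int]:
        """(subject, property, object) -> index, from axiom reifications."""
        out: dict[tuple, int] = {}
        g = self.graph
        for axiom in g.subjects(RDF.type, OWL.Axiom):
            s = g.value(axiom, OWL.annotatedSource)
            p = g.value(axiom, OWL.annotatedProperty)
            o = g.value(axiom, OWL.annotatedTarget)
            idx = g.value(axiom, AUX["index"])
            if s is not None and p is not None and o is not None and idx is not None:
                out[(s, p, o)] = int(idx)
        return out

    def _ordered_objects(self, subject: URIRef, prop: URIRef) -> list:
        objs = list(self.graph.objects(subject, prop))
        objs.sort(key=lambda o: (self.order.get((subject, prop, o), 0), str(o)))
        return objs

    def read(self) -> DSON:
        g = self.graph
        ont = g.value(predicate=RDF.type, object=OWL.Ontology)
        if ont is None:
            raise OntologyError("no owl:Ontology header found")
        name = str(g.value(ont, AUX.name) or "dson")
        namespace = str(g.value(ont, AUX.namespace) or str(ont) + "#")
        dson = DSON(name=name, namespace=namespace)
        ns = namespace

        facet_names: list[str] = []
        seq = g.value(ont, AUX.facets)
        if seq is not None:
            i = 1
            while True:
                member = g.value(seq, URIRef(str(RDF) + f"_{i}"))
                if member is None:
                    break
                facet_names.append(str(member))
                i += 1
        facets = {fname: Facet(name=fname) for fname in facet_names}
        dson.facets = [facets[fname] for fname in facet_names]

        domain_classes = [
            c
            for c in g.subjects(RDF.type, OWL.Class)
            if isinstance(c, URIRef) and str(c).startswith(ns)
            and not str(c).startswith(str(SON))
        ]

        standard, negated, composites, queries, orphans = [], [], [], [], []
        for cls in domain_classes:
            base = self._base_class(cls, ns)
            if base == "Standard_Concept":
                standard.append(cls)
            elif base == "Negated_Concept":
                negated.append(cls)
            elif base == "Composite_Term":
                composites.append(cls)
            elif base == "Multiple_Concept_Query":
                queries.append(cls)
            elif str(cls) != ns.rstrip("#/") and _local_name(cls, ns) not in (
                "Facet_Order",
            ) and not _local_name(cls, ns).startswith("Axiom_"):
                orphans.append(cls)
        for cls in orphans:
            warnings.warn(
                f"class {cls} is under no search-ontology base class; skipped",
                stacklevel=3,
            )

        def order_key(cls):
            idx = g.value(cls, AUX["index"])
            return (int(idx) if idx is not None else 0, str(cls))

        for cls in sorted(standard, key=order_key):
            concept = self._read_concept(cls, ns, negated=False)
            fname = str(g.value(cls, AUX.facet) or "")
            if fname not in facets:
                facets[fname] = Facet(name=fname)
                dson.facets.append(facets[fname])
            concept.facet = fname
            facets[fname].concepts.append(concept)
        for cls in sorted(negated, key=order_key):
            dson.negated_concepts.append(
                self._read_concept(cls, ns, negated=True)
            )
        for cls in sorted(composites, key=order_key):
            dson.composite_terms.append(self._read_composite(cls, ns))
        for cls in sorted(queries, key=order_key):
            dson.multiple_queries.append(self._read_multiple_query(cls, ns))
        return dson

    def _base_class(self, cls: URIRef, ns: str) -> Optional[str]:
        """Name of the SON base class reached via subClassOf, else None."""
        seen = set()
        frontier = [cls]
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            for parent in self.graph.objects(node, RDFS.subClassOf):
                if str(parent).startswith(str(SON)):
                    return _local_name(parent, str(SON))
                frontier.append(parent)
        return None

    def _read_terms(self, cls: URIRef, prop: URIRef) -> list[TermLiteral]:
        terms = []
        for lit in self._ordered_objects(cls, prop):
            lang = lit.language or "en"
            terms.extend(parse_term_cell(str(lit), lang, str(cls)))
        return terms

    def _read_queries(self, cls: URIRef) -> dict[str, str]:
        out = {}
        for lit in self.graph.objects(cls, SON.query):
            out[lit.language or "en"] = str(lit)
        return dict(sorted(out.items()))

    def _read_concept(
        self, cls: URIRef, ns: str, negated: bool
    ) -> SearchConcept:
        g = self.graph
        name = _local_name(cls, ns)
        parent = None
        if not negated:
            for sup in g.objects(cls, RDFS.subClassOf):
                if isinstance(sup, URIRef) and str(sup).startswith(ns):
                    parent = _local_name(sup, ns)
        term_prop = SON.excluded_simple_term if negated else SON.simple_term
        return SearchConcept(
            name=name,
            parent=parent,
            is_negated=negated,
            simple_terms=self._read_terms(cls, term_prop),
            composite_term_refs=[
                _local_name(o, ns)
                for o in self._ordered_objects(cls, SON.composite_term)
            ],
            excluded_concept_refs=[
                _local_name(o, ns)
                for o in self._ordered_objects(cls, SON.excluded_concept)
            ],
            query=self._read_queries(cls),
        )

    def _mode_near(self, cls: URIRef) -> tuple[Optional[str], Optional[str]]:
        g = self.graph
        mode = g.value(cls, SON.mode)
        near = g.value(cls, SON.near)
        return (
            str(mode) if mode is not None else None,
            parse_near_cell(str(near), str(cls)) if near is not None else None,
        )

    def _read_composite(self, cls: URIRef, ns: str) -> CompositeTermSpec:
        g = self.graph
        mode, near = self._mode_near(cls)
        owner = g.value(cls, AUX.concept)
        return CompositeTermSpec(
            name=_local_name(cls, ns),
            concept=_local_name(owner, ns) if owner is not None else "",
            part1=_local_name(
                g.value(cls, SON.has_term_of_concept_as_part_1), ns
            ),
            part2=_local_name(
                g.value(cls, SON.has_term_of_concept_as_part_2), ns
            ),
            mode=mode,
            near=near,
            query=self._read_queries(cls),
        )

    def _read_multiple_query(
        self, cls: URIRef, ns: str
    ) -> MultipleConceptQuerySpec:
        mode, near = self._mode_near(cls)
        return MultipleConceptQuerySpec(
            name=_local_name(cls, ns),
            concepts=[
                _local_name(o, ns)
                for o in self._ordered_objects(
                    cls, SON.has_query_of_concept_as_part
                )
            ],
            mode=mode,
            near=near,
            query=self._read_queries(cls),
        )


def from_owl(document: Union[str, bytes, Graph]) -> DSON:
    """Parse an OWL document (RDF/XML or Turtle) back into a dSON.

    Inverse of :func:`to_owl` up to annotation ordering; classes under
    no search-ontology base class are skipped with a warning.
    """
    return _Reader(_parse_graph(document)).read()


# ---------------------------------------------------------------------------
# external ontology import


def import_external_ontology(
    document: Union[str, bytes, Graph], facet_name: str
) -> Facet:
    """Turn any label-carrying ontology into a facet.

    Every class becomes a search concept, subclass axioms become parent
    links (a class with several parents is attached to the first seen,
    with a warning), language-tagged ``rdfs:label`` values become simple
    terms, and a label-less class falls back to its local name as its
    single term.
    """
    g = _parse_graph(document)
    classes = sorted(
        {
            c
            for c in g.subjects(RDF.type, OWL.Class)
            if isinstance(c, URIRef)
        }
        | {
            c
            for triple_part in (g.subjects(RDFS.subClassOf, None),
                                g.objects(None, RDFS.subClassOf))
            for c in triple_part
            if isinstance(c, URIRef)
        },
        key=str,
    )
    if not classes:
        raise OntologyError("no classes found in external ontology")

    def local(iri: URIRef) -> str:
        text = str(iri)
        for sep in ("#", "/"):
            if sep in text:
                text = text.rsplit(sep, 1)[1]
        return text or str(iri)

    parent_of: dict[URIRef, URIRef] = {}
    for cls in classes:
        for sup in sorted(g.objects(cls, RDFS.subClassOf), key=str):
            if not isinstance(sup, URIRef) or sup not in classes:
                continue
            if cls in parent_of:
                warnings.warn(
                    f"class {cls} has multiple superclasses; keeping "
                    f"{parent_of[cls]}",
                    stacklevel=2,
                )
            else:
                parent_of[cls] = sup

    # topological order, parents before children, stable by IRI
    facet = Facet(name=facet_name)
    emitted: set[URIRef] = set()

    def emit(cls: URIRef) -> None:
        if cls in emitted:
            return
        parent = parent_of.get(cls)
        if parent is not None:
            emit(parent)
        emitted.add(cls)
        terms = []
        for label in sorted(g.objects(cls, RDFS.label), key=str):
            if isinstance(label, Literal):
                terms.append(
                    TermLiteral(text=str(label), language=label.language or "en")
                )
        if not terms:
            terms = [TermLiteral(text=local(cls), language="en")]
        facet.concepts.append(
            SearchConcept(
                name=local(cls),
                facet=facet_name,
                parent=local(parent) if parent is not None else None,
                simple_terms=terms,
            )
        )

    for cls in classes:
        emit(cls)
    return facet


# ---------------------------------------------------------------------------
# JSON


def _term_strings(concept: SearchConcept) -> dict[str, list[str]]:
    return {
        lang: [term_to_cell_fragment(t) for t in concept.terms_in(lang)]
        for lang in ("en", "de")
    }


def _node(
    name: str,
    node_type: str,
    simple_terms: dict[str, list[str]],
    query: dict[str, str],
    children: list[dict],
) -> dict:
    return {
        "name": name,
        "type": node_type,
        "simple_terms": simple_terms,
        "query": {lang: query[lang] for lang in ("en", "de") if lang in query},
        "children": children,
    }


def _concept_node(concept: SearchConcept, dson: DSON,
                  children_of: dict[str, list[SearchConcept]]) -> dict:
    children = []
    for ref in concept.composite_term_refs:
        ct = dson.find_composite(ref)
        if ct is not None:
            children.append(
                _node(ct.name, "composite_term",
                      {"en": [], "de": []}, ct.query, [])
            )
    for child in children_of.get(concept.name, []):
        children.append(_concept_node(child, dson, children_of))
    return _node(
        concept.name,
        "negated_concept" if concept.is_negated else "concept",
        _term_strings(concept),
        concept.query,
        children,
    )


def to_json_obj(dson: DSON) -> dict:
    """JSON-ready dict: one tree per facet plus negated and
    multiple-concept-query sections."""
    facets = []
    for facet in dson.facets:
        children_of: dict[str, list[SearchConcept]] = {}
        roots = []
        for concept in facet.concepts:
            if concept.parent is None:
                roots.append(concept)
            else:
                children_of.setdefault(concept.parent, []).append(concept)
        facets.append({
            "name": facet.name,
            "children": [
                _concept_node(c, dson, children_of) for c in roots
            ],
        })
    return {
        "name": dson.name,
        "facets": facets,
        "negated_concepts": [
            _concept_node(c, dson, {}) for c in dson.negated_concepts
        ],
        "multiple_concept_queries": [
            _node(mq.name, "multiple_concept_query",
                  {"en": [], "de": []}, mq.query, [])
            for mq in dson.multiple_queries
        ],
    }


def to_json(dson: DSON) -> str:
    """Serialise to the canonical JSON form (fixed key order, UTF-8)."""
    return json.dumps(to_json_obj(dson), ensure_ascii=False, indent=2)


def load_json_schema() -> dict:
    """The published JSON Schema for :func:`to_json` output."""
    text = (
        resources.files("sonq").joinpath("data/dson.schema.json").read_text()
    )
    return json.loads(text)


def check_json_schema(doc: dict, schema: Optional[dict] = None,
                      path: str = "$") -> list[str]:
    """Structural validation against the shipped schema subset
    (type / required / properties / items / enum / additionalProperties).
    Returns a list of violation messages; empty means valid."""
    schema = schema if schema is not None else load_json_schema()
    return _check(doc, schema, schema, path)


def _check(doc, schema: dict, root: dict, path: str) -> list[str]:
    if "$ref" in schema:
        target = root
        for part in schema["$ref"].lstrip("#/").split("/"):
            target = target[part]
        return _check(doc, target, root, path)
    errs: list[str] = []
    expected = schema.get("type")
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "boolean": bool,
    }
    if expected and not isinstance(doc, type_map[expected]):
        return [f"{path}: expected {expected}, got {type(doc).__name__}"]
    if "enum" in schema and doc not in schema["enum"]:
        errs.append(f"{path}: {doc!r} not in {schema['enum']}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in doc:
                errs.append(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, value in doc.items():
            if key in props:
                errs.extend(_check(value, props[key], root, f"{path}.{key}"))
            elif schema.get("additionalProperties") is False:
                errs.append(f"{path}: unexpected key {key!r}")
    if expected == "array" and "items" in schema:
        for i, item in enumerate(doc):
            errs.extend(_check(item, schema["items"], root, f"{path}[{i}]"))
    return errs
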