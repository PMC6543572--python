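"""Programmatic builders of test inputs.

Three kinds of input are built here, all deterministic under a seed:

* the *Niti* example ontology — a small post-market-surveillance dSON
  about unexpected complications of Nitinol endoscopic clipping
  systems — both as an in-memory model and as a template workbook;
* synthetic corpora with *planted* term occurrences: the builder emits
  filler sentences from a vocabulary disjoint from every fixture term
  and records the exact token position, sentence and paragraph of each
  planted term as it writes it, so ground-truth proximity labels come
  from plain arithmetic, independent of the query engine;
* a demo lexicon (en/de inflected forms and German compounds) for the
  baseform/compound matching modes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Optional, Union

from .son_model import (
    DSON,
    CompositeTermSpec,
    Facet,
    MultipleConceptQuerySpec,
    SearchConcept,
    TermLiteral,
)
from .query_engine import Lexicon
from .template_io import write_template

# ---------------------------------------------------------------------------
# the Niti example


def build_niti_dson() -> DSON:
    """The example dSON: facets Material, Medical_Device and Incident,
    the negated concept No_Preclinical, the composite term
    Unexpected__Complication and one multiple-concept query."""

    def concept(name, facet, terms, parent=None, refs=()):
        return SearchConcept(
            name=name,
            facet=facet,
            parent=parent,
            simple_terms=[
                TermLiteral(text=t, language="en", boost=b) for t, b in terms
            ],
            composite_term_refs=list(refs),
        )

    material = Facet(
        name="Material",
        concepts=[
            concept("Nitinol", "Material",
                    [("Nitinol", None), ("Nickel Titanium", None),
                     ("NiTi", None)]),
        ],
    )
    device = Facet(
        name="Medical_Device",
        concepts=[
            concept("Clip", "Medical_Device", [("clip", None)]),
            concept("Endoscopic_Clipping_System", "Medical_Device",
                    [("endoscopic clipping system", None)], parent="Clip"),
            concept("Stent", "Medical_Device", [("stent", None)]),
            concept("Occluder", "Medical_Device", [("occluder", None)]),
            concept("PFO_Occluder", "Medical_Device",
                    [("PFO occluder", None)], parent="Occluder"),
            concept("PDA_Occluder", "Medical_Device",
                    [("PDA occluder", None)], parent="Occluder"),
            concept("Implant", "Medical_Device", [("implant", None)]),
        ],
    )
    incident = Facet(
        name="Incident",
        concepts=[
            concept("Unexpected", "Incident",
                    [("unexpected", None), ("unforeseeable", None),
                     ("unknown", None)]),
            concept("Complication", "Incident",
                    [("complication", None), ("failure", None),
                     ("incident", None)]),
            concept("Unexpected_Complication", "Incident", [],
                    refs=["Unexpected__Complication"]),
            concept("Severe_Incident", "Incident", [("incident", 5)]),
        ],
    )
    return DSON(
        name="dSON-Niti",
        namespace="http://example.org/dson/niti#",
        facets=[material, device, incident],
        negated_concepts=[
            SearchConcept(
                name="No_Preclinical",
                is_negated=True,
                simple_terms=[
                    TermLiteral(text=t, language="en")
                    for t in ("animal", "study", "preclinical")
                ],
            ),
        ],
        composite_terms=[
            CompositeTermSpec(
                name="Unexpected__Complication",
                concept="Unexpected_Complication",
                part1="Unexpected",
                part2="Complication",
            ),
        ],
        multiple_queries=[
            MultipleConceptQuerySpec(
                name="Niti_Query",
                concepts=["Unexpected_Complication", "Nitinol",
                          "Endoscopic_Clipping_System", "No_Preclinical"],
            ),
        ],
    )


def build_niti_workbook(target: Union[str, IO[bytes], None] = None):
    """The Niti example as a template workbook (see
    :func:`sonq.template_io.write_template`)."""
    return write_template(build_niti_dson(), target)


def demo_lexicon() -> Lexicon:
    """The shipped ~50-entry en/de demo lexicon."""
    text = (
        resources.files("sonq").joinpath("data/demo_lexicon.tsv").read_text()
    )
    import io

    return Lexicon.from_file(io.StringIO(text))


# ---------------------------------------------------------------------------
# planted corpora

#: filler vocabulary, disjoint from every fixture concept term
FILLER_WORDS = (
    "lorem", "ipsum", "dolor", "sit", "amet", "consectetur", "adipiscing",
    "elit", "sed", "eiusmod", "tempor", "incididunt", "labore", "dolore",
    "magna", "aliqua", "veniam", "quis", "nostrud", "ullamco",
)

BOUNDARIES = ("none", "sentence", "paragraph")


@dataclass
class PlantSpec:
    """Plant ``terms`` in order with ``gaps[i]`` filler tokens between
    term ``i`` and ``i+1`` and ``boundaries[i]`` separating them
    ("none": same sentence; "sentence": a sentence break in between;
    "paragraph": a paragraph break in between)."""

    terms: list[str]
    gaps: list[int] = field(default_factory=list)
    boundaries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.terms)
        if not self.gaps:
            self.gaps = [0] * (n - 1)
        if not self.boundaries:
            self.boundaries = ["none"] * (n - 1)
        if len(self.gaps) != n - 1 or len(self.boundaries) != n - 1:
            raise ValueError("need one gap/boundary per adjacent term pair")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be >= 0")
        if any(b not in BOUNDARIES for b in self.boundaries):
            raise ValueError(f"boundaries must be in {BOUNDARIES}")


@dataclass
class DocumentRecipe:
    plants: list[PlantSpec] = field(default_factory=list)
    filler_sentences: int = 2


@dataclass
class CorpusRecipe:
    documents: list[DocumentRecipe]
    seed: int = 0


@dataclass
class PlantedOccurrence:
    """Ground truth for one planted term: half-open token span plus
    sentence and paragraph indices (always within one sentence)."""

    term: str
    start: int
    end: int
    sentence: int
    paragraph: int


@dataclass
class BuiltDocument:
    text: str
    occurrences: list[PlantedOccurrence]

    def spans_of(self, term: str) -> list[PlantedOccurrence]:
        return [o for o in self.occurrences if o.term == term]


class _DocWriter:
    """Emits words sentence by sentence, tracking token/sentence/
    paragraph counters exactly as the engine tokenizer counts them."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.paragraphs: list[list[list[str]]] = [[]]
        self.sentence: list[str] = []
        self.position = 0
        self.sentence_index = 0
        self.occurrences: list[PlantedOccurrence] = []

    def words(self, text: str) -> list[str]:
        return text.split()

    def emit_word(self, word: str) -> None:
        self.sentence.append(word)
        self.position += 1

    def emit_filler(self, count: int) -> None:
        for _ in range(count):
            self.emit_word(self.rng.choice(FILLER_WORDS))

    def emit_term(self, term: str) -> None:
        start = self.position
        for word in self.words(term):
            self.emit_word(word)
        self.occurrences.append(
            PlantedOccurrence(
                term=term,
                start=start,
                end=self.position,
                sentence=self.sentence_index,
                paragraph=len(self.paragraphs) - 1,
            )
        )

    def end_sentence(self) -> None:
        if self.sentence:
            self.paragraphs[-1].append(self.sentence)
            self.sentence = []
            self.sentence_index += 1

    def end_paragraph(self) -> None:
        self.end_sentence()
        if self.paragraphs[-1]:
            self.paragraphs.append([])

    def filler_sentence(self) -> None:
        self.end_sentence()
        self.emit_filler(self.rng.randint(3, 7))
        self.end_sentence()

    def render(self) -> BuiltDocument:
        self.end_sentence()
        paragraphs = [
            " ".join(" ".join(s) + "." for s in para)
            for para in self.paragraphs
            if para
        ]
        return BuiltDocument(
            text="\n\n".join(paragraphs), occurrences=self.occurrences
        )


def build_document(recipe: DocumentRecipe, rng: random.Random) -> BuiltDocument:
    writer = _DocWriter(rng)
    writer.filler_sentence()
    for plant in recipe.plants:
        writer.end_sentence()
        for i, term in enumerate(plant.terms):
            writer.emit_term(term)
            if i < len(plant.terms) - 1:
                gap, boundary = plant.gaps[i], plant.boundaries[i]
                if boundary == "none":
                    writer.emit_filler(gap)
                else:
                    head = gap // 2
                    writer.emit_filler(head)
                    if boundary == "sentence":
                        writer.end_sentence()
                    else:
                        writer.end_paragraph()
                    writer.emit_filler(gap - head)
        writer.end_sentence()
        for _ in range(recipe.filler_sentences):
            writer.filler_sentence()
    return writer.render()


def build_corpus(recipe: CorpusRecipe) -> list[BuiltDocument]:
    """Deterministic corpus: identical recipe and seed give identical
    documents, with per-document planted-term ground truth."""
    rng = random.Random(recipe.seed)
    return [build_document(doc, rng) for doc in recipe.documents]


# -- convenience corpora ----------------------------------------------------


def proximity_corpus(
    n_docs: int,
    seed: int,
    left: str = "unexpected",
    right: str = "complication",
    max_gap: int = 6,
) -> tuple[list[BuiltDocument], list[dict]]:
    """Documents planting ``left`` and ``right`` once each at a random
    filler gap and boundary.  Returns documents plus ground-truth dicts
    with keys ``distance`` (token distance between the pair),
    ``same_sentence`` and ``same_paragraph``."""
    rng = random.Random(seed)
    recipes, truths = [], []
    for _ in range(n_docs):
        gap = rng.randint(0, max_gap)
        boundary = rng.choice(BOUNDARIES)
        recipes.append(
            DocumentRecipe(
                plants=[PlantSpec(terms=[left, right], gaps=[gap],
                                  boundaries=[boundary])]
            )
        )
        truths.append({
            "distance": gap + 1,
            "same_sentence": boundary == "none",
            "same_paragraph": boundary in ("none", "sentence"),
        })
    docs = build_corpus(CorpusRecipe(documents=recipes, seed=rng.randint(0, 2**31 - 1)))
    return docs, truths


NITI_UNEXPECTED = ("unexpected", "unforeseeable", "unknown")
NITI_COMPLICATION = ("complication", "failure", "incident")
NITI_MATERIAL = ("Nitinol", "Nickel Titanium", "NiTi")
NITI_DEVICE = "endoscopic clipping system"
NITI_NEGATED = ("animal", "study", "preclinical")


def niti_corpus(
    n_docs: int, seed: int
) -> tuple[list[BuiltDocument], list[bool]]:
    """Documents planting random subsets of the Niti query's features.

    The expected label for the multiple-concept query is computed from
    the plant plan alone: an unexpected-term and a complication-term
    and a material term and the device phrase present, and no negated
    term present.
    """
    rng = random.Random(seed)
    recipes, expected = [], []
    for _ in range(n_docs):
        with_unexpected = rng.random() < 0.8
        with_complication = rng.random() < 0.8
        with_material = rng.random() < 0.8
        with_device = rng.random() < 0.8
        with_negated = rng.random() < 0.3
        plants = []
        if with_unexpected and with_complication:
            plants.append(
                PlantSpec(
                    terms=[rng.choice(NITI_UNEXPECTED),
                           rng.choice(NITI_COMPLICATION)],
                    gaps=[rng.randint(0, 4)],
                    boundaries=[rng.choice(BOUNDARIES)],
                )
            )
        elif with_unexpected:
            plants.append(PlantSpec(terms=[rng.choice(NITI_UNEXPECTED)]))
        elif with_complication:
            plants.append(PlantSpec(terms=[rng.choice(NITI_COMPLICATION)]))
        if with_material:
            plants.append(PlantSpec(terms=[rng.choice(NITI_MATERIAL)]))
        if with_device:
            plants.append(PlantSpec(terms=[NITI_DEVICE]))
        if with_negated:
            plants.append(PlantSpec(terms=[rng.choice(NITI_NEGATED)]))
        recipes.append(DocumentRecipe(plants=plants, filler_sentences=1))
        expected.append(
            with_unexpected and with_complication and with_material
            and with_device and not with_negated
        )
    docs = build_corpus(CorpusRecipe(documents=recipes, seed=rng.randint(0, 2**31 - 1)))
    return docs, expected


# ---------------------------------------------------------------------------
# random valid dSONs (round-trip testing)

_WORD_POOL = (
    "fracture", "migration", "corrosion", "erosion", "leak", "rupture",
    "embolism", "thrombosis", "stenosis", "occlusion", "infection",
    "allergy", "toxicity", "degradation", "wear", "fatigue", "recall",
    "malfunction", "defect", "hazard", "bruch", "riss", "fehler",
    "ausfall", "schaden", "wanderung",
)


def random_dson(seed: int, *, n_facets: int = 2,
                concepts_per_facet: int = 4) -> DSON:
    """A random structurally valid dSON (queries ungenerated).

    Every standard concept gets at least one English term; German
    terms, phrases, boosts, wildcards, hierarchy, negated concepts,
    composite terms and multiple-concept queries are randomized.
    """
    rng = random.Random(seed)

    def one_term(lang: str) -> TermLiteral:
        word = rng.choice(_WORD_POOL)
        if rng.random() < 0.2:
            word = f"{word} {rng.choice(_WORD_POOL)}"  # phrase
        elif rng.random() < 0.15:
            word = word[: max(2, len(word) // 2)] + "*"  # wildcard
        boost = float(rng.randint(2, 9)) if rng.random() < 0.2 else None
        return TermLiteral(text=word, language=lang, boost=boost)

    def some_terms(min_n: int = 1) -> list[TermLiteral]:
        # grouped en then de, matching the template's per-language cells;
        # duplicates within a concept are invalid, so draw until distinct
        terms: list[TermLiteral] = []
        seen: set[tuple[str, str]] = set()
        for lang, n in (("en", rng.randint(min_n, 2)), ("de", rng.randint(0, 2))):
            for _ in range(n):
                for _attempt in range(10):
                    term = one_term(lang)
                    if (term.text, lang) not in seen:
                        seen.add((term.text, lang))
                        terms.append(term)
                        break
        return terms

    dson = DSON(name=f"Random_{seed}")
    counter = 0
    for f in range(n_facets):
        facet = Facet(name=f"Facet_{chr(ord('A') + f)}")
        # stack-based generation keeps the facet in forest pre-order,
        # the only order the template's indentation encoding expresses
        stack: list[str] = []
        for _ in range(rng.randint(1, concepts_per_facet)):
            depth = rng.randint(0, min(len(stack), 3))
            del stack[depth:]
            facet.concepts.append(
                SearchConcept(
                    name=f"Concept_{counter}",
                    facet=facet.name,
                    parent=stack[-1] if stack else None,
                    simple_terms=some_terms(),
                )
            )
            stack.append(f"Concept_{counter}")
            counter += 1
        dson.facets.append(facet)

    standard = [c for facet in dson.facets for c in facet.concepts]

    for _ in range(rng.randint(0, 2)):
        dson.negated_concepts.append(
            SearchConcept(
                name=f"No_Concept_{counter}",
                is_negated=True,
                simple_terms=some_terms(),
                excluded_concept_refs=(
                    [rng.choice(standard).name] if rng.random() < 0.3 else []
                ),
            )
        )
        counter += 1

    if len(standard) >= 2 and rng.random() < 0.8:
        part1, part2 = rng.sample(standard, 2)
        owner = rng.choice(standard)
        name = CompositeTermSpec.canonical_name(part1.name, part2.name)
        dson.composite_terms.append(
            CompositeTermSpec(
                name=name,
                concept=owner.name,
                part1=part1.name,
                part2=part2.name,
                mode=rng.choice((None, "E", "B")),
                near=rng.choice((None, "n:3", "S", "P")),
            )
        )
        owner.composite_term_refs.append(name)

    if len(standard) >= 2 and rng.random() < 0.8:
        chosen = rng.sample(standard, 2) + (
            [rng.choice(dson.negated_concepts)] if dson.negated_concepts else []
        )
        dson.multiple_queries.append(
            MultipleConceptQuerySpec(
                name=f"Query_{counter}",
                concepts=[c.name for c in chosen],
                near=rng.choice((None, "n:5")),
            )
        )
    return dson
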