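"""Core data model for search ontologies.

A domain-specific search ontology (dSON) organises *search concepts* into
facets (one hierarchy per facet, e.g. Material, Medical_Device, Incident).
Each concept carries per-language *simple terms* — single words or fixed
phrases, optionally boosted (``incident^5``) or wildcarded — from which
query strings are generated later.  Three further constructs exist:

* negated concepts, whose terms must *not* occur in matching documents;
* composite terms, an AND/NEAR combination of the OR-linked simple terms
  of two standard concepts (named ``Part1__Part2``, double underscore);
* multiple-concept queries, the AND-connection of the single-concept
  queries of several selected concepts.

This module holds the types, identifier normalisation, validation and
name resolution.  Serialization lives in :mod:`sonq.template_io` and
:mod:`sonq.ontology_io`; query-string generation in :mod:`sonq.query_gen`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

LANGUAGES = ("en", "de")

#: Search modes: E exact surface, D diacritics/case-normalized,
#: B lemmatized baseform, C compound-parts.
MODES = ("E", "D", "B", "C")

_IDENT_RE = re.compile(r"^[^\s]+$")
_WILDCARD_RE = re.compile(r"[*?]")


class UnknownConceptError(KeyError):
    """Raised when a concept name cannot be resolved in a dSON."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; we want a message
        return f"unknown concept: {self.name!r}"


def normalize_identifier(text: str) -> str:
    """Turn spreadsheet cell text into a concept identifier.

    Internal whitespace runs become single underscores and each
    underscore-separated word is capitalized (first letter upper, rest
    kept), so ``"endoscopic clipping system"`` becomes
    ``Endoscopic_Clipping_System``.  Text already containing underscores
    or capitals is preserved apart from first-letter capitalization.
    """
    words = re.split(r"\s+", text.strip())
    words = [w for w in words if w]
    out = "_".join(words)
    parts = out.split("_")
    parts = [p[:1].upper() + p[1:] if p else p for p in parts]
    return "_".join(parts)


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str  # e.g. "facet Material / concept Nitinol" or "sheet!row"
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.location}: {self.message}"


@dataclass
class TermLiteral:
    """A simple term: single word or fixed phrase, with optional boost.

    ``is_phrase`` is derived from the text (contains whitespace) and
    determines rendering: phrases are double-quoted, words are bare.
    Wildcards (``*``/``?``) are only meaningful in single words.
    """

    text: str
    language: str = "en"
    boost: Optional[float] = None

    def __post_init__(self) -> None:
        self.text = self.text.strip()

    @property
    def is_phrase(self) -> bool:
        return bool(re.search(r"\s", self.text))

    @property
    def has_wildcard(self) -> bool:
        return bool(_WILDCARD_RE.search(self.text))

    def validate(self, location: str) -> list[ValidationIssue]:
        issues = []
        if not self.text:
            issues.append(ValidationIssue("error", location, "empty term text"))
        if self.language not in LANGUAGES:
            issues.append(
                ValidationIssue(
                    "error", location, f"unsupported language {self.language!r}"
                )
            )
        if self.boost is not None and not self.boost > 0:
            issues.append(
                ValidationIssue(
                    "error", location, f"boost must be positive, got {self.boost}"
                )
            )
        for forbidden in (";", "^", '"'):
            if forbidden in self.text:
                issues.append(
                    ValidationIssue(
                        "error",
                        location,
                        f"term text {self.text!r} contains reserved "
                        f"character {forbidden!r}",
                    )
                )
        if self.is_phrase and self.has_wildcard:
            issues.append(
                ValidationIssue(
                    "error",
                    location,
                    f"wildcard not allowed inside phrase {self.text!r}",
                )
            )
        return issues


@dataclass
class SearchConcept:
    """A node in a facet hierarchy (or a negated concept outside facets)."""

    name: str
    facet: Optional[str] = None
    parent: Optional[str] = None
    simple_terms: list[TermLiteral] = field(default_factory=list)
    composite_term_refs: list[str] = field(default_factory=list)
    is_negated: bool = False
    excluded_concept_refs: list[str] = field(default_factory=list)
    query: dict[str, str] = field(default_factory=dict)
    #: sheet/row provenance for error messages, "" when built in memory
    origin: str = field(default="", compare=False)

    def terms_in(self, lang: str) -> list[TermLiteral]:
        return [t for t in self.simple_terms if t.language == lang]


@dataclass
class CompositeTermSpec:
    """AND/NEAR combination of the simple terms of two standard concepts.

    The canonical name is ``part1 + "__" + part2`` (two underscores),
    e.g. ``Unexpected__Complication``.
    """

    name: str
    concept: str  # owning concept
    part1: str
    part2: str
    mode: Optional[str] = None  # E/D/B/C
    near: Optional[str] = None  # "n:<k>" | "S" | "P"
    query: dict[str, str] = field(default_factory=dict)
    origin: str = field(default="", compare=False)

    @staticmethod
    def canonical_name(part1: str, part2: str) -> str:
        return f"{part1}__{part2}"


@dataclass
class MultipleConceptQuerySpec:
    """AND-connection of the single-concept queries of selected concepts."""

    name: str
    concepts: list[str] = field(default_factory=list)
    mode: Optional[str] = None
    near: Optional[str] = None
    query: dict[str, str] = field(default_factory=dict)
    origin: str = field(default="", compare=False)


@dataclass
class Facet:
    """One user-defined axis of the search: an ordered concept forest.

    Order is significant: every non-root concept's parent precedes it.
    """

    name: str
    concepts: list[SearchConcept] = field(default_factory=list)

    def roots(self) -> list[SearchConcept]:
        return [c for c in self.concepts if c.parent is None]


_NEAR_RE = re.compile(r"^(?:n:([1-9][0-9]*)|S|P)$")


@dataclass
class DSON:
    """A complete domain-specific search ontology."""

    name: str
    namespace: str = ""
    facets: list[Facet] = field(default_factory=list)
    negated_concepts: list[SearchConcept] = field(default_factory=list)
    composite_terms: list[CompositeTermSpec] = field(default_factory=list)
    multiple_queries: list[MultipleConceptQuerySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.namespace:
            self.namespace = f"http://example.org/dson/{self.name}#"

    # -- access -----------------------------------------------------------

    def iter_concepts(self) -> Iterator[SearchConcept]:
        """All concepts, facet order then negated concepts."""
        for facet in self.facets:
            yield from facet.concepts
        yield from self.negated_concepts

    def find_concept(self, name: str) -> Optional[SearchConcept]:
        for c in self.iter_concepts():
            if c.name == name:
                return c
        return None

    def find_composite(self, name: str) -> Optional[CompositeTermSpec]:
        for ct in self.composite_terms:
            if ct.name == name:
                return ct
        return None


def resolve_concept(dson: DSON, name: str) -> SearchConcept:
    """Return the unique concept called ``name``.

    Searches facets in order, then negated concepts.  Raises
    :class:`UnknownConceptError` if absent.
    """
    concept = dson.find_concept(name)
    if concept is None:
        raise UnknownConceptError(name)
    return concept


def validate_dson(dson: DSON) -> list[ValidationIssue]:
    """Check every structural invariant; return issues, never raise.

    An empty list means the dSON is valid.  Locations carry sheet/row
    provenance when the model came from a template workbook.
    """
    issues: list[ValidationIssue] = []

    def err(location: str, message: str) -> None:
        issues.append(ValidationIssue("error", location, message))

    # namespace is an IRI ending in # or /
    ns = dson.namespace
    if not re.match(r"^[A-Za-z][A-Za-z0-9+.-]*://[^\s]+[#/]$", ns):
        err("dson", f"namespace {ns!r} is not an IRI ending in '#' or '/'")

    # global name uniqueness + per-concept checks
    seen: dict[str, str] = {}
    for facet in dson.facets:
        facet_names = set()
        for concept in facet.concepts:
            loc = concept.origin or f"facet {facet.name} / {concept.name}"
            if not _IDENT_RE.match(concept.name or ""):
                err(loc, f"invalid concept identifier {concept.name!r}")
            if concept.name in seen:
                err(loc, f"duplicate concept name {concept.name!r} "
                         f"(also at {seen[concept.name]})")
            else:
                seen[concept.name] = loc
            if concept.is_negated:
                err(loc, "negated concept inside a facet")
            if concept.parent is not None and concept.parent not in facet_names:
                err(loc, f"parent {concept.parent!r} does not precede "
                         f"{concept.name!r} in facet {facet.name!r}")
            facet_names.add(concept.name)
            issues.extend(_check_terms(concept, loc))
    for concept in dson.negated_concepts:
        loc = concept.origin or f"negated concept {concept.name}"
        if not _IDENT_RE.match(concept.name or ""):
            err(loc, f"invalid concept identifier {concept.name!r}")
        if concept.name in seen:
            err(loc, f"duplicate concept name {concept.name!r} "
                     f"(also at {seen[concept.name]})")
        else:
            seen[concept.name] = loc
        if not concept.is_negated:
            err(loc, "concept in negated list is not marked negated")
        if concept.composite_term_refs:
            err(loc, "negated concept must not reference composite terms")
        issues.extend(_check_terms(concept, loc))
        for ref in concept.excluded_concept_refs:
            if ref not in seen and dson.find_concept(ref) is None:
                err(loc, f"excluded concept {ref!r} is not defined")

    all_names = {c.name for c in dson.iter_concepts()}
    standard_names = {
        c.name for c in dson.iter_concepts() if not c.is_negated
    }

    # composite terms
    ct_seen: set[str] = set()
    for ct in dson.composite_terms:
        loc = ct.origin or f"composite term {ct.name}"
        if ct.part1 == ct.part2:
            err(loc, f"composite term {ct.name!r} has identical parts "
                     f"({ct.part1!r})")
        expected = CompositeTermSpec.canonical_name(ct.part1, ct.part2)
        if ct.name != expected:
            err(loc, f"composite name {ct.name!r} should be {expected!r} "
                     "(part1__part2, two underscores)")
        for part in (ct.part1, ct.part2):
            if part not in all_names:
                err(loc, f"composite part {part!r} is not a defined concept")
            elif part not in standard_names:
                err(loc, f"composite part {part!r} is a negated concept")
        if ct.concept not in all_names:
            err(loc, f"owning concept {ct.concept!r} is not defined")
        if ct.name in ct_seen:
            err(loc, f"duplicate composite term {ct.name!r}")
        ct_seen.add(ct.name)
        issues.extend(_check_mode_near(ct.mode, ct.near, loc))

    # concept -> composite references
    for concept in dson.iter_concepts():
        loc = concept.origin or f"concept {concept.name}"
        for ref in concept.composite_term_refs:
            if ref not in ct_seen:
                err(loc, f"composite term {ref!r} is not defined")

    # multiple-concept queries
    mq_seen: set[str] = set()
    for mq in dson.multiple_queries:
        loc = mq.origin or f"multiple-concept query {mq.name}"
        if not _IDENT_RE.match(mq.name or ""):
            err(loc, f"invalid query identifier {mq.name!r}")
        if mq.name in mq_seen:
            err(loc, f"duplicate query name {mq.name!r}")
        mq_seen.add(mq.name)
        if len(mq.concepts) < 2:
            err(loc, f"query {mq.name!r} needs at least 2 concepts, "
                     f"has {len(mq.concepts)}")
        for ref in mq.concepts:
            if ref not in all_names:
                err(loc, f"unresolved concept reference {ref!r}")
        issues.extend(_check_mode_near(mq.mode, mq.near, loc))

    return issues


def _check_terms(concept: SearchConcept, location: str) -> list[ValidationIssue]:
    issues = []
    seen: set[tuple[str, str, Optional[float]]] = set()
    for term in concept.simple_terms:
        issues.extend(term.validate(location))
        key = (term.text, term.language, term.boost)
        if key in seen:
            issues.append(
                ValidationIssue(
                    "error",
                    location,
                    f"duplicate simple term {term.text!r} ({term.language})",
                )
            )
        seen.add(key)
    return issues


def _check_mode_near(
    mode: Optional[str], near: Optional[str], location: str
) -> list[ValidationIssue]:
    issues = []
    if mode is not None and mode not in MODES:
        issues.append(
            ValidationIssue(
                "error", location, f"MODE must be one of {MODES}, got {mode!r}"
            )
        )
    if near is not None and not _NEAR_RE.match(near):
        issues.append(
            ValidationIssue(
                "error",
                location,
                f"NEAR must be 'n:<positive int>', 'S' or 'P', got {near!r}",
            )
        )
    return issues
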