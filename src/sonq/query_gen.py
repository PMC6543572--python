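"""Generate extended-Lucene query strings for a dSON.

Generation proceeds bottom-up, per language:

* **composite term** — the AND-connection of the OR-linked simple terms
  of its two part concepts, e.g.
  ``(unexpected OR unforeseeable OR unknown) AND (complication OR
  failure OR incident)``; a NEAR setting replaces the ``AND`` joiner
  with ``NEAR/k`` / ``NEAR/S`` / ``NEAR/P``, a MODE setting wraps the
  whole expression as ``MODE/X (…)``;
* **single-concept query** — the OR-connection of all of a concept's
  terms (simple and composite); for a negated concept, ``NOT`` applied
  to the OR-connection of its excluded terms;
* **multiple-concept query** — the AND-connection of the single-concept
  queries of the selected concepts; NEAR, when set, joins only the
  standard-concept sub-queries (negated ones always attach with AND
  since proximity to an excluded term is meaningless).

Operand order follows spreadsheet order everywhere; operators are
uppercase with single-space separation, so generated strings are
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .son_model import (
    DSON,
    CompositeTermSpec,
    MultipleConceptQuerySpec,
    SearchConcept,
    TermLiteral,
    ValidationIssue,
)


class GenerationError(ValueError):
    """An item cannot produce a query in the requested language."""


@dataclass
class GenerationOptions:
    languages: tuple[str, ...] = ("en", "de")
    #: silently omit concepts with no terms in a language from
    #: multiple-concept queries (warning) instead of failing the query
    skip_empty_concepts: bool = True

    def __post_init__(self) -> None:
        if not self.languages:
            raise ValueError("languages must be non-empty")


def _format_boost(boost: float) -> str:
    return str(int(boost)) if float(boost).is_integer() else str(boost)


def render_term(term: TermLiteral) -> str:
    """Render one term: bare word or quoted phrase, ``^boost`` appended."""
    out = f'"{term.text}"' if term.is_phrase else term.text
    if term.boost is not None:
        out += f"^{_format_boost(term.boost)}"
    return out


def _near_joiner(near: str) -> str:
    if near.startswith("n:"):
        return f"NEAR/{near[2:]}"
    return f"NEAR/{near}"


def _wrap_mode(mode: str | None, expression: str) -> str:
    if mode is None:
        return expression
    return f"MODE/{mode} ({expression})"


def _or_join_terms(terms: list[TermLiteral]) -> str:
    return " OR ".join(render_term(t) for t in terms)


def generate_composite_term(
    spec: CompositeTermSpec, dson: DSON, lang: str
) -> str:
    """``( part1 terms OR-joined ) JOINER ( part2 terms OR-joined )``."""
    parts = []
    for part_name in (spec.part1, spec.part2):
        concept = dson.find_concept(part_name)
        if concept is None:
            raise GenerationError(
                f"composite term {spec.name!r}: unknown part {part_name!r}"
            )
        terms = concept.terms_in(lang)
        if not terms:
            raise GenerationError(
                f"composite term {spec.name!r}: part {part_name!r} has no "
                f"{lang!r} simple terms"
            )
        parts.append(f"({_or_join_terms(terms)})")
    joiner = _near_joiner(spec.near) if spec.near else "AND"
    return _wrap_mode(spec.mode, f"{parts[0]} {joiner} {parts[1]}")


def generate_single_concept_query(
    concept: SearchConcept, dson: DSON, lang: str
) -> str:
    """OR-connection of a concept's terms; ``NOT (…)`` when negated."""
    if concept.is_negated:
        terms = list(concept.terms_in(lang))
        for ref in concept.excluded_concept_refs:
            excluded = dson.find_concept(ref)
            if excluded is None:
                raise GenerationError(
                    f"negated concept {concept.name!r}: unknown excluded "
                    f"concept {ref!r}"
                )
            terms.extend(excluded.terms_in(lang))
        if not terms:
            raise GenerationError(
                f"negated concept {concept.name!r} has no {lang!r} terms"
            )
        return f"NOT ({_or_join_terms(terms)})"

    operands = [render_term(t) for t in concept.terms_in(lang)]
    for ref in concept.composite_term_refs:
        ct = dson.find_composite(ref)
        if ct is None:
            raise GenerationError(
                f"concept {concept.name!r}: unknown composite term {ref!r}"
            )
        try:
            # composite strings are self-delimiting under the grammar
            # (AND/NEAR bind tighter than the OR-join added here)
            operands.append(
                ct.query.get(lang) or generate_composite_term(ct, dson, lang)
            )
        except GenerationError:
            # composite unavailable in this language; the concept's own
            # terms still form a query
            continue
    if not operands:
        raise GenerationError(
            f"concept {concept.name!r} has no {lang!r} terms"
        )
    return f"({' OR '.join(operands)})"


def generate_multiple_concept_query(
    spec: MultipleConceptQuerySpec,
    dson: DSON,
    lang: str,
    options: GenerationOptions | None = None,
) -> str:
    """AND/NEAR-connection of single-concept queries.

    NEAR joins the standard-concept sub-queries only; negated concepts
    are appended with AND (their NOT is part of their own query).
    """
    options = options or GenerationOptions()
    standard: list[str] = []
    negated: list[str] = []
    for name in spec.concepts:
        concept = dson.find_concept(name)
        if concept is None:
            raise GenerationError(
                f"query {spec.name!r}: unknown concept {name!r}"
            )
        try:
            sub = concept.query.get(lang) or generate_single_concept_query(
                concept, dson, lang
            )
        except GenerationError:
            if options.skip_empty_concepts:
                continue
            raise
        (negated if concept.is_negated else standard).append(sub)
    if not standard and not negated:
        raise GenerationError(
            f"query {spec.name!r}: no concept yields a {lang!r} query"
        )
    if spec.near:
        if len(standard) < 2:
            raise GenerationError(
                f"query {spec.name!r}: NEAR needs at least two standard "
                f"concepts with {lang!r} terms, found {len(standard)}"
            )
        core = f" {_near_joiner(spec.near)} ".join(standard)
    else:
        core = " AND ".join(standard)
    pieces = [core] if core else []
    pieces.extend(negated)
    return _wrap_mode(spec.mode, " AND ".join(pieces))


@dataclass
class GenerationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def warn(self, location: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", location, message))

    def error(self, location: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", location, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


def generate_all(
    dson: DSON, options: GenerationOptions | None = None
) -> GenerationReport:
    """Fill every query map in place: composites, then single-concept
    queries, then multiple-concept queries.

    Per-item failures are collected in the returned report without
    aborting the remaining items.  Idempotent: a second run regenerates
    identical strings.
    """
    options = options or GenerationOptions()
    report = GenerationReport()

    for ct in dson.composite_terms:
        for lang in options.languages:
            try:
                ct.query[lang] = generate_composite_term(ct, dson, lang)
            except GenerationError as exc:
                ct.query.pop(lang, None)
                report.warn(ct.origin or f"composite term {ct.name}", str(exc))

    for concept in dson.iter_concepts():
        for lang in options.languages:
            try:
                concept.query[lang] = generate_single_concept_query(
                    concept, dson, lang
                )
            except GenerationError as exc:
                concept.query.pop(lang, None)
                has_lang_composite = any(
                    (ct := dson.find_composite(ref)) is not None
                    and lang in ct.query
                    for ref in concept.composite_term_refs
                )
                if concept.terms_in(lang) or has_lang_composite:
                    report.error(
                        concept.origin or f"concept {concept.name}", str(exc)
                    )
                else:
                    report.warn(
                        concept.origin or f"concept {concept.name}", str(exc)
                    )

    for mq in dson.multiple_queries:
        for lang in options.languages:
            try:
                mq.query[lang] = generate_multiple_concept_query(
                    mq, dson, lang, options
                )
            except GenerationError as exc:
                mq.query.pop(lang, None)
                report.warn(mq.origin or f"query {mq.name}", str(exc))

    return report
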