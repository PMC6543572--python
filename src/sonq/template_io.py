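"""Read and write the search-ontology Excel template.

A template workbook has three reserved sheets — ``Negated_Concept``,
``Composite_Term`` and ``Multiple_Concept_Query`` — and any number of
user-defined *facet sheets*, one per search facet (e.g. Material,
Medical_Device, Incident).

Facet sheet layout: the first ``hierarchy_depth`` columns (default 4)
encode the concept hierarchy — a concept's name sits in exactly one of
them and its parent is the nearest preceding row whose name sits in a
shallower column — followed by the per-language term columns
``Simple Terms (en)`` and ``Simple Terms (de)``.  Term cells hold
``;``-separated terms, each optionally boosted with a trailing
``^number`` (e.g. ``incident^5``).

Reserved sheet layouts:

* ``Negated_Concept``: ``Concept``, ``Excluded Simple Terms (en)``,
  ``Excluded Simple Terms (de)`` (a legacy single ``Excluded Simple
  Terms`` column is read as English), optional ``Excluded Concepts``;
* ``Composite_Term``: ``Concept``, ``part1``, ``part2``, ``MODE``,
  ``NEAR``;
* ``Multiple_Concept_Query``: ``Query``, ``MODE``, ``NEAR``, then one
  or more ``Concept`` columns.

``NEAR`` cells accept a bare positive integer, ``S`` or ``P``, or the
spelled-out forms ``NEAR/5`` / ``NEAR/S`` / ``NEAR/P``.
"""

from __future__ import annotations

import re
from typing import IO, Optional, Union

from openpyxl import Workbook, load_workbook
from openpyxl.worksheet.worksheet import Worksheet

from .son_model import (
    DSON,
    CompositeTermSpec,
    Facet,
    MultipleConceptQuerySpec,
    SearchConcept,
    TermLiteral,
    normalize_identifier,
)

RESERVED_SHEETS = ("Negated_Concept", "Composite_Term", "Multiple_Concept_Query")

DEFAULT_HIERARCHY_DEPTH = 4

TERM_COL_EN = "Simple Terms (en)"
TERM_COL_DE = "Simple Terms (de)"
EXCL_COL_EN = "Excluded Simple Terms (en)"
EXCL_COL_DE = "Excluded Simple Terms (de)"
EXCL_COL_LEGACY = "Excluded Simple Terms"
EXCL_CONCEPTS_COL = "Excluded Concepts"


class TemplateFormatError(ValueError):
    """A workbook does not follow the template layout."""


_BOOST_RE = re.compile(r"^(.*?)\^([^\^]*)$", re.S)


def parse_term_cell(cell: str, language: str, location: str) -> list[TermLiteral]:
    """Split a ``;``-separated term cell into literals, parsing ``^boost``."""
    terms: list[TermLiteral] = []
    for raw in cell.split(";"):
        raw = raw.strip()
        if not raw:
            continue
        boost: Optional[float] = None
        m = _BOOST_RE.match(raw)
        if m:
            text, boost_str = m.group(1).strip(), m.group(2).strip()
            try:
                boost = float(boost_str)
            except ValueError:
                raise TemplateFormatError(
                    f"{location}: malformed boost {'^' + boost_str!r} "
                    f"in term {raw!r}"
                ) from None
            if not boost > 0:
                raise TemplateFormatError(
                    f"{location}: boost must be positive in term {raw!r}"
                )
            if "^" in text:
                raise TemplateFormatError(
                    f"{location}: multiple boost markers in term {raw!r}"
                )
            raw = text
        terms.append(TermLiteral(text=raw, language=language, boost=boost))
    return terms


def _format_boost(boost: float) -> str:
    return str(int(boost)) if float(boost).is_integer() else str(boost)


def term_to_cell_fragment(term: TermLiteral) -> str:
    if term.boost is not None:
        return f"{term.text}^{_format_boost(term.boost)}"
    return term.text


def parse_near_cell(cell: str, location: str) -> str:
    """Normalise a NEAR cell to the internal ``n:<k>`` / ``S`` / ``P`` form."""
    value = cell.strip()
    if value.upper().startswith("NEAR/"):
        value = value[5:]
    if value in ("S", "P"):
        return value
    if value.isdigit() and int(value) > 0:
        return f"n:{int(value)}"
    raise TemplateFormatError(
        f"{location}: NEAR must be a positive integer, 'S' or 'P', got {cell!r}"
    )


def near_to_cell(near: Optional[str]) -> Optional[str]:
    if near is None:
        return None
    if near.startswith("n:"):
        return near[2:]
    return near


def _headers(ws: Worksheet) -> dict[str, int]:
    """Map stripped header text -> 0-based column index (first wins)."""
    out: dict[str, int] = {}
    for idx, cell in enumerate(next(ws.iter_rows(min_row=1, max_row=1), [])):
        text = str(cell.value).strip() if cell.value is not None else ""
        if text and text not in out:
            out[text] = idx
    return out


def _cell(row: tuple, idx: Optional[int]) -> str:
    if idx is None or idx >= len(row) or row[idx].value is None:
        return ""
    return str(row[idx].value).strip()


def _require(headers: dict[str, int], sheet: str, column: str) -> int:
    if column not in headers:
        raise TemplateFormatError(
            f"sheet {sheet!r}: missing required column {column!r}"
        )
    return headers[column]


# ---------------------------------------------------------------------------
# reading


def read_template(
    source: Union[str, IO[bytes]],
    *,
    name: Optional[str] = None,
    namespace: str = "",
    hierarchy_depth: int = DEFAULT_HIERARCHY_DEPTH,
) -> DSON:
    """Parse a template workbook into an (ungenerated) :class:`DSON`.

    Facet order follows sheet order, concept order follows row order.
    Query maps are left empty; run :func:`sonq.query_gen.generate_all`
    afterwards.  The dSON name defaults to the workbook's title property,
    then to ``"dson"``.
    """
    wb = load_workbook(source, read_only=False, data_only=True)
    if name is None:
        name = (wb.properties.title or "").strip() or "dson"
    if not namespace:
        namespace = (wb.properties.subject or "").strip()

    dson = DSON(name=name, namespace=namespace)

    for sheet_name in wb.sheetnames:
        ws = wb[sheet_name]
        if ws.sheet_state != "visible" or sheet_name in RESERVED_SHEETS:
            continue
        dson.facets.append(_read_facet_sheet(ws, hierarchy_depth))

    for reserved in RESERVED_SHEETS:
        if reserved not in wb.sheetnames:
            raise TemplateFormatError(f"missing required sheet {reserved!r}")

    _read_negated_sheet(wb["Negated_Concept"], dson)
    _read_composite_sheet(wb["Composite_Term"], dson)
    _read_multiple_query_sheet(wb["Multiple_Concept_Query"], dson)

    # attach composite terms to their owning concepts, in sheet order
    for ct in dson.composite_terms:
        owner = dson.find_concept(ct.concept)
        if owner is not None and ct.name not in owner.composite_term_refs:
            owner.composite_term_refs.append(ct.name)

    return dson


def _read_facet_sheet(ws: Worksheet, hierarchy_depth: int) -> Facet:
    headers = _headers(ws)
    sheet = ws.title
    en_idx = _require(headers, sheet, TERM_COL_EN)
    de_idx = headers.get(TERM_COL_DE)
    depth_cols = min(hierarchy_depth, en_idx)
    if depth_cols < 1:
        raise TemplateFormatError(
            f"sheet {sheet!r}: no hierarchy columns before {TERM_COL_EN!r}"
        )

    facet = Facet(name=sheet)
    # stack of (depth, concept name) for parent resolution
    stack: list[tuple[int, str]] = []
    for row_no, row in enumerate(ws.iter_rows(min_row=2), start=2):
        depth, cell_text = None, ""
        for d in range(depth_cols):
            text = _cell(row, d)
            if text:
                depth, cell_text = d, text
                break
        if depth is None:
            continue  # blank row
        location = f"{sheet}!row {row_no}"
        concept_name = normalize_identifier(cell_text)
        while stack and stack[-1][0] >= depth:
            stack.pop()
        parent = stack[-1][1] if stack else None
        if depth > 0 and parent is None:
            raise TemplateFormatError(
                f"{location}: concept {concept_name!r} at depth {depth} "
                "has no preceding shallower concept"
            )
        concept = SearchConcept(
            name=concept_name,
            facet=sheet,
            parent=parent,
            origin=location,
        )
        concept.simple_terms.extend(
            parse_term_cell(_cell(row, en_idx), "en", location)
        )
        if de_idx is not None:
            concept.simple_terms.extend(
                parse_term_cell(_cell(row, de_idx), "de", location)
            )
        facet.concepts.append(concept)
        stack.append((depth, concept_name))
    return facet


def _read_negated_sheet(ws: Worksheet, dson: DSON) -> None:
    headers = _headers(ws)
    if not headers:
        return
    concept_idx = _require(headers, ws.title, "Concept")
    en_idx = headers.get(EXCL_COL_EN, headers.get(EXCL_COL_LEGACY))
    de_idx = headers.get(EXCL_COL_DE)
    refs_idx = headers.get(EXCL_CONCEPTS_COL)
    for row_no, row in enumerate(ws.iter_rows(min_row=2), start=2):
        cell_text = _cell(row, concept_idx)
        if not cell_text:
            continue
        location = f"{ws.title}!row {row_no}"
        concept = SearchConcept(
            name=normalize_identifier(cell_text),
            is_negated=True,
            origin=location,
        )
        if en_idx is not None:
            concept.simple_terms.extend(
                parse_term_cell(_cell(row, en_idx), "en", location)
            )
        if de_idx is not None:
            concept.simple_terms.extend(
                parse_term_cell(_cell(row, de_idx), "de", location)
            )
        if refs_idx is not None:
            concept.excluded_concept_refs.extend(
                normalize_identifier(part)
                for part in _cell(row, refs_idx).split(";")
                if part.strip()
            )
        dson.negated_concepts.append(concept)


def _read_composite_sheet(ws: Worksheet, dson: DSON) -> None:
    headers = _headers(ws)
    if not headers:
        return
    sheet = ws.title
    concept_idx = _require(headers, sheet, "Concept")
    p1_idx = _require(headers, sheet, "part1")
    p2_idx = _require(headers, sheet, "part2")
    mode_idx = headers.get("MODE")
    near_idx = headers.get("NEAR")
    for row_no, row in enumerate(ws.iter_rows(min_row=2), start=2):
        owner = _cell(row, concept_idx)
        if not owner and not _cell(row, p1_idx):
            continue
        location = f"{sheet}!row {row_no}"
        part1 = normalize_identifier(_cell(row, p1_idx))
        part2 = normalize_identifier(_cell(row, p2_idx))
        mode = _cell(row, mode_idx) or None
        near_cell = _cell(row, near_idx)
        near = parse_near_cell(near_cell, location) if near_cell else None
        dson.composite_terms.append(
            CompositeTermSpec(
                name=CompositeTermSpec.canonical_name(part1, part2),
                concept=normalize_identifier(owner),
                part1=part1,
                part2=part2,
                mode=mode,
                near=near,
                origin=location,
            )
        )


def _read_multiple_query_sheet(ws: Worksheet, dson: DSON) -> None:
    headers = _headers(ws)
    if not headers:
        return
    sheet = ws.title
    query_idx = _require(headers, sheet, "Query")
    mode_idx = headers.get("MODE")
    near_idx = headers.get("NEAR")
    # all columns headed "Concept" (repeated header)
    concept_idxs = [
        idx
        for idx, cell in enumerate(next(ws.iter_rows(min_row=1, max_row=1), []))
        if cell.value is not None and str(cell.value).strip() == "Concept"
    ]
    if not concept_idxs:
        raise TemplateFormatError(
            f"sheet {sheet!r}: missing required column 'Concept'"
        )
    for row_no, row in enumerate(ws.iter_rows(min_row=2), start=2):
        name = _cell(row, query_idx)
        if not name:
            continue
        location = f"{sheet}!row {row_no}"
        mode = _cell(row, mode_idx) or None
        near_cell = _cell(row, near_idx)
        near = parse_near_cell(near_cell, location) if near_cell else None
        concepts = [
            normalize_identifier(_cell(row, idx))
            for idx in concept_idxs
            if _cell(row, idx)
        ]
        dson.multiple_queries.append(
            MultipleConceptQuerySpec(
                name=normalize_identifier(name),
                concepts=concepts,
                mode=mode,
                near=near,
                origin=location,
            )
        )


# ---------------------------------------------------------------------------
# writing


def write_template(
    dson: DSON,
    target: Union[str, IO[bytes], None] = None,
    *,
    hierarchy_depth: int = DEFAULT_HIERARCHY_DEPTH,
) -> Workbook:
    """Serialise a dSON to a template workbook.

    Returns the :class:`openpyxl.Workbook`; also saves it when ``target``
    is a path or stream.  ``read_template(write_template(d))`` recovers
    ``d`` up to term order within a cell.
    """
    wb = Workbook()
    wb.remove(wb.active)  # drop default sheet
    wb.properties.title = dson.name
    wb.properties.subject = dson.namespace

    for facet in dson.facets:
        ws = wb.create_sheet(facet.name)
        _write_facet_sheet(ws, facet, hierarchy_depth)

    ws = wb.create_sheet("Negated_Concept")
    ws.append(["Concept", EXCL_COL_EN, EXCL_COL_DE, EXCL_CONCEPTS_COL])
    for concept in dson.negated_concepts:
        ws.append([
            concept.name,
            _terms_cell(concept, "en"),
            _terms_cell(concept, "de"),
            "; ".join(concept.excluded_concept_refs),
        ])

    ws = wb.create_sheet("Composite_Term")
    ws.append(["Concept", "part1", "part2", "MODE", "NEAR"])
    for ct in dson.composite_terms:
        ws.append([ct.concept, ct.part1, ct.part2, ct.mode or "",
                   near_to_cell(ct.near) or ""])

    ws = wb.create_sheet("Multiple_Concept_Query")
    width = max((len(mq.concepts) for mq in dson.multiple_queries), default=1)
    ws.append(["Query", "MODE", "NEAR"] + ["Concept"] * width)
    for mq in dson.multiple_queries:
        ws.append([mq.name, mq.mode or "", near_to_cell(mq.near) or ""]
                  + mq.concepts)

    if target is not None:
        wb.save(target)
    return wb


def _depth_of(facet: Facet, concept: SearchConcept) -> int:
    by_name = {c.name: c for c in facet.concepts}
    depth, cur = 0, concept
    while cur.parent is not None:
        cur = by_name[cur.parent]
        depth += 1
    return depth


def _terms_cell(concept: SearchConcept, lang: str) -> str:
    return "; ".join(
        term_to_cell_fragment(t) for t in concept.terms_in(lang)
    )


def _preorder(facet: Facet) -> list[SearchConcept]:
    """Forest pre-order (roots and siblings keep list order).

    The indentation encoding can only express pre-ordered facets, so
    sheets are written in that order; facets read from a template are
    already pre-ordered.
    """
    children: dict[Optional[str], list[SearchConcept]] = {}
    for concept in facet.concepts:
        children.setdefault(concept.parent, []).append(concept)
    out: list[SearchConcept] = []

    def visit(concept: SearchConcept) -> None:
        out.append(concept)
        for child in children.get(concept.name, []):
            visit(child)

    for root in children.get(None, []):
        visit(root)
    return out


def _write_facet_sheet(
    ws: Worksheet, facet: Facet, hierarchy_depth: int
) -> None:
    header = ["Concept"] + [
        f"Subconcept (level {d})" for d in range(1, hierarchy_depth)
    ]
    ws.append(header + [TERM_COL_EN, TERM_COL_DE])
    for concept in _preorder(facet):
        depth = _depth_of(facet, concept)
        if depth >= hierarchy_depth:
            raise TemplateFormatError(
                f"facet {facet.name!r}: concept {concept.name!r} at depth "
                f"{depth} exceeds the {hierarchy_depth} hierarchy columns"
            )
        row = [""] * hierarchy_depth + [
            _terms_cell(concept, "en"),
            _terms_cell(concept, "de"),
        ]
        row[depth] = concept.name
        ws.append(row)
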