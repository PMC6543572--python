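"""Reference engine for the extended Lucene-style query syntax.

The syntax extends boolean Lucene queries with proximity and term-type
operators:

* ``NEAR/n`` — both operands within a token distance of ``n``
  (adjacent tokens are at distance 1);
* ``NEAR/S`` / ``NEAR/P`` — both operands within one sentence /
  paragraph;
* ``MODE/E|D|B|C`` — term-matching regime for the subtree: ``E`` exact
  surface, ``D`` case-folded and diacritics-normalized (the default),
  ``B`` lemmatized baseform, ``C`` compound parts;
* ``^k`` boosts and ``*``/``?`` wildcards on terms.

Operator precedence, loosest to tightest: ``OR`` < ``AND`` < ``NOT`` <
``NEAR`` < ``MODE`` < atom.  NEAR operators nest with the rest of the
grammar arbitrarily; a NEAR node's own span is the hull of the two
operand spans, which is what makes nesting meaningful.

Evaluation is span-based: every node reports the token spans it matched
so proximity operators can constrain their operands' positions, and the
score is the boost-sum over distinct matched term occurrences.

Lemmatization and compound splitting are driven by a pluggable
:class:`Lexicon` (tab-separated file: ``form<TAB>baseform<TAB>``
``part1|part2`` with the parts column optional); with an empty lexicon,
``B`` degrades to ``D`` matching and ``C`` to no splitting.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

# ---------------------------------------------------------------------------
# AST


@dataclass
class QueryNode:
    """Base query AST node.  ``group`` records explicit parentheses so
    that rendering reproduces the input string exactly."""

    group: bool = False


@dataclass
class Term(QueryNode):
    text: str = ""
    boost: Optional[float] = None

    @property
    def has_wildcard(self) -> bool:
        return "*" in self.text or "?" in self.text


@dataclass
class Phrase(QueryNode):
    text: str = ""
    boost: Optional[float] = None


@dataclass
class And(QueryNode):
    children: list[QueryNode] = field(default_factory=list)


@dataclass
class Or(QueryNode):
    children: list[QueryNode] = field(default_factory=list)


@dataclass
class Not(QueryNode):
    child: QueryNode = None  # type: ignore[assignment]


@dataclass
class Near(QueryNode):
    #: positive int token distance, or "S" (sentence) / "P" (paragraph)
    distance: Union[int, str] = 1
    left: QueryNode = None  # type: ignore[assignment]
    right: QueryNode = None  # type: ignore[assignment]


@dataclass
class Mode(QueryNode):
    mode: str = "D"  # E/D/B/C
    child: QueryNode = None  # type: ignore[assignment]


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedCombinationError(ValueError):
    """Raised for query shapes without defined semantics (NOT in NEAR)."""


# ---------------------------------------------------------------------------
# query parsing

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<phrase>"(?P<ptext>[^"]*)"(?:\^(?P<pboost>[0-9.]+))?)
  | (?P<badphrase>")
  | (?P<word>[^\s()"]+)
    """,
    re.X,
)

_MODE_OP_RE = re.compile(r"^MODE/([EDBC])$")
_NEAR_OP_RE = re.compile(r"^NEAR/([1-9][0-9]*|S|P)$")
_BOOST_SUFFIX_RE = re.compile(r"^(.*[^^])\^([0-9.]+)$")


@dataclass
class _Tok:
    kind: str  # "(" ")" "word" "phrase" "op"
    value: str
    offset: int
    boost: Optional[float] = None


def _lex(text: str) -> list[_Tok]:
    toks: list[_Tok] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # pragma: no cover - regex covers all chars
            raise QuerySyntaxError("unexpected character", pos)
        if m.lastgroup != "ws":
            if m.group("badphrase"):
                raise QuerySyntaxError("unterminated quote", pos)
            if m.group("lparen"):
                toks.append(_Tok("(", "(", pos))
            elif m.group("rparen"):
                toks.append(_Tok(")", ")", pos))
            elif m.group("phrase") is not None:
                boost = m.group("pboost")
                toks.append(
                    _Tok("phrase", m.group("ptext"), pos,
                         float(boost) if boost else None)
                )
            else:
                toks.append(_Tok("word", m.group("word"), pos))
        pos = m.end()
    return toks


class _Parser:
    """Recursive-descent parser, precedence OR < AND < NOT < NEAR < MODE."""

    def __init__(self, text: str):
        self.text = text
        self.toks = _lex(text)
        self.i = 0

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> QueryNode:
        if not self.toks:
            raise QuerySyntaxError("empty query", 0)
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise QuerySyntaxError(f"unexpected {tok.value!r}", tok.offset)
        return node

    def _at_word(self, value: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "word" and tok.value == value

    def or_expr(self) -> QueryNode:
        children = [self.and_expr()]
        while self._at_word("OR"):
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(children=children)

    def and_expr(self) -> QueryNode:
        children = [self.not_expr()]
        while self._at_word("AND"):
            self.next()
            children.append(self.not_expr())
        return children[0] if len(children) == 1 else And(children=children)

    def not_expr(self) -> QueryNode:
        if self._at_word("NOT"):
            self.next()
            return Not(child=self.not_expr())
        return self.near_expr()

    def near_expr(self) -> QueryNode:
        node = self.mode_expr()
        while True:
            tok = self.peek()
            if tok is None or tok.kind != "word":
                return node
            m = _NEAR_OP_RE.match(tok.value)
            if not m:
                return node
            self.next()
            dist: Union[int, str] = (
                m.group(1) if m.group(1) in ("S", "P") else int(m.group(1))
            )
            node = Near(distance=dist, left=node, right=self.mode_expr())

    def mode_expr(self) -> QueryNode:
        tok = self.peek()
        if tok is not None and tok.kind == "word":
            m = _MODE_OP_RE.match(tok.value)
            if m:
                self.next()
                return Mode(mode=m.group(1), child=self.mode_expr())
        return self.atom()

    def atom(self) -> QueryNode:
        tok = self.next()
        if tok.kind == "(":
            inner = self.or_expr()
            closing = self.peek()
            if closing is None or closing.kind != ")":
                raise QuerySyntaxError("unbalanced parenthesis", tok.offset)
            self.next()
            inner.group = True
            return inner
        if tok.kind == "phrase":
            return Phrase(text=tok.value, boost=tok.boost)
        if tok.kind == "word":
            if tok.value in ("AND", "OR", "NOT") or _NEAR_OP_RE.match(tok.value):
                raise QuerySyntaxError(
                    f"operator {tok.value!r} where a term was expected",
                    tok.offset,
                )
            text, boost = tok.value, None
            m = _BOOST_SUFFIX_RE.match(text)
            if m:
                try:
                    boost = float(m.group(2))
                except ValueError:
                    raise QuerySyntaxError("malformed boost", tok.offset)
                text = m.group(1)
            return Term(text=text, boost=boost)
        raise QuerySyntaxError(f"unexpected {tok.value!r}", tok.offset)


def parse_query(text: str) -> QueryNode:
    """Parse a query string into an AST; raise :class:`QuerySyntaxError`
    with a character offset on malformed input."""
    return _Parser(text).parse()


def _format_boost(boost: float) -> str:
    return str(int(boost)) if float(boost).is_integer() else str(boost)


def render_query(node: QueryNode) -> str:
    """Inverse of :func:`parse_query`: ``render(parse(s)) == s`` for
    strings with single-space operator separation."""
    out = _render(node)
    return out


def _render(node: QueryNode) -> str:
    if isinstance(node, Term):
        body = node.text
        if node.boost is not None:
            body += f"^{_format_boost(node.boost)}"
    elif isinstance(node, Phrase):
        body = f'"{node.text}"'
        if node.boost is not None:
            body += f"^{_format_boost(node.boost)}"
    elif isinstance(node, Or):
        body = " OR ".join(_render(c) for c in node.children)
    elif isinstance(node, And):
        body = " AND ".join(_render(c) for c in node.children)
    elif isinstance(node, Not):
        body = f"NOT {_render(node.child)}"
    elif isinstance(node, Near):
        body = f"{_render(node.left)} NEAR/{node.distance} {_render(node.right)}"
    elif isinstance(node, Mode):
        body = f"MODE/{node.mode} {_render(node.child)}"
    else:  # pragma: no cover
        raise TypeError(f"unknown node {node!r}")
    if node.group:
        body = f"({body})"
    return body


# ---------------------------------------------------------------------------
# documents


@dataclass
class Token:
    surface: str
    normalized: str
    baseforms: tuple[str, ...]
    compound_parts: tuple[str, ...]
    position: int
    sentence_index: int
    paragraph_index: int


@dataclass
class TokenizedDocument:
    tokens: list[Token]
    text: str

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Lexicon:
    """Surface→baseform and compound→parts maps (case-folded keys).

    With empty maps, baseform matching falls back to the normalized
    form and compound splitting is disabled.
    """

    baseform_map: dict[str, str] = field(default_factory=dict)
    compound_map: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, source: Union[str, IO[str]]) -> "Lexicon":
        """Load ``form<TAB>baseform<TAB>part1|part2`` lines (parts
        optional; blank lines and ``#`` comments skipped)."""
        lex = cls()
        if isinstance(source, str):
            with open(source, encoding="utf-8") as fh:
                lines = fh.readlines()
        else:
            lines = source.readlines()
        for line in lines:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            form = fields[0].strip().casefold()
            if not form:
                continue
            if len(fields) > 1 and fields[1].strip():
                lex.baseform_map[form] = fields[1].strip().casefold()
            if len(fields) > 2 and fields[2].strip():
                parts = [p.strip() for p in fields[2].split("|") if p.strip()]
                if parts:
                    lex.compound_map[form] = parts
        return lex


def normalize_word(word: str) -> str:
    """Case-fold and strip diacritics (NFKD, combining marks removed)."""
    folded = word.casefold()
    decomposed = unicodedata.normalize("NFKD", folded)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


_PARAGRAPH_RE = re.compile(r"\n\s*\n")
_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")
# words keep intra-word hyphens; everything else is a separator
_WORD_RE = re.compile(r"[\w]+(?:-[\w]+)*", re.UNICODE)


def tokenize(text: str, lexicon: Optional[Lexicon] = None) -> TokenizedDocument:
    """Segment text into paragraphs (blank lines), sentences (./!/?
    followed by whitespace) and word tokens, with normalized, baseform
    and compound-part annotations."""
    lexicon = lexicon or Lexicon()
    tokens: list[Token] = []
    position = 0
    sentence_index = 0
    for para_idx, paragraph in enumerate(_PARAGRAPH_RE.split(text)):
        if not paragraph.strip():
            continue
        for sentence in _SENTENCE_RE.split(paragraph):
            words = _WORD_RE.findall(sentence)
            if not words:
                continue
            for word in words:
                key = word.casefold()
                normalized = normalize_word(word)
                baseform = lexicon.baseform_map.get(key)
                baseforms = (baseform,) if baseform else (normalized,)
                parts = tuple(
                    normalize_word(p) for p in lexicon.compound_map.get(key, ())
                )
                tokens.append(
                    Token(
                        surface=word,
                        normalized=normalized,
                        baseforms=baseforms,
                        compound_parts=parts,
                        position=position,
                        sentence_index=sentence_index,
                        paragraph_index=para_idx,
                    )
                )
                position += 1
            sentence_index += 1
    return TokenizedDocument(tokens=tokens, text=text)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MatchResult:
    matched: bool
    score: float
    spans: list[tuple[int, int]]  # half-open token intervals


DEFAULT_MODE = "D"


def _wildcard_regex(pattern: str) -> re.Pattern:
    out = []
    for ch in pattern:
        if ch == "*":
            out.append(".*")
        elif ch == "?":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return re.compile("^" + "".join(out) + "$")


def _token_representations(token: Token, mode: str) -> tuple[str, ...]:
    if mode == "E":
        return (token.surface,)
    if mode == "D":
        return (token.normalized,)
    if mode == "B":
        return token.baseforms
    if mode == "C":
        return (token.surface, token.normalized) + token.compound_parts
    raise ValueError(f"unknown mode {mode!r}")


def _term_matches_token(
    text: str, token: Token, mode: str, lexicon: Lexicon
) -> bool:
    wildcard = "*" in text or "?" in text
    if mode == "E":
        query_reprs = (text,)
    elif mode in ("D", "C"):
        query_reprs = (normalize_word(text),)
    else:  # B: lemmatize the query word through the lexicon too
        normalized = normalize_word(text)
        query_reprs = (lexicon.baseform_map.get(text.casefold(), normalized),)
    reprs = _token_representations(token, mode)
    if mode == "C":
        # surface comparison stays case-insensitive: compare normalized
        reprs = (token.normalized,) + token.compound_parts
    if wildcard:
        regexes = [_wildcard_regex(q) for q in query_reprs]
        return any(rx.match(r) for rx in regexes for r in reprs)
    return any(q == r for q in query_reprs for r in reprs)


def _merge_spans(span_lists: Iterable[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    seen = set()
    out = []
    for spans in span_lists:
        for span in spans:
            if span not in seen:
                seen.add(span)
                out.append(span)
    return sorted(out)


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Token distance between the nearest endpoints of two spans;
    adjacent tokens are at distance 1, overlapping spans at <= 0."""
    (s1, e1), (s2, e2) = a, b
    if e1 <= s2:
        return s2 - e1 + 1
    if e2 <= s1:
        return s1 - e2 + 1
    return 0  # overlap


def _contains_not(node: QueryNode) -> bool:
    if isinstance(node, Not):
        return True
    if isinstance(node, (And, Or)):
        return any(_contains_not(c) for c in node.children)
    if isinstance(node, Near):
        return _contains_not(node.left) or _contains_not(node.right)
    if isinstance(node, Mode):
        return _contains_not(node.child)
    return False


def evaluate(
    ast: QueryNode,
    doc: TokenizedDocument,
    default_mode: str = DEFAULT_MODE,
    lexicon: Optional[Lexicon] = None,
) -> MatchResult:
    """Evaluate a query AST against one tokenized document.

    Returns the boolean match, the boost-sum score (0 when unmatched)
    and the matched token spans.  ``default_mode`` is the term-matching
    regime outside any ``MODE`` operator.
    """
    lexicon = lexicon or Lexicon()
    return _eval(ast, doc, default_mode, lexicon)


def _eval(
    node: QueryNode, doc: TokenizedDocument, mode: str, lexicon: Lexicon
) -> MatchResult:
    if isinstance(node, Term):
        spans = [
            (t.position, t.position + 1)
            for t in doc.tokens
            if _term_matches_token(node.text, t, mode, lexicon)
        ]
        boost = node.boost if node.boost is not None else 1.0
        return MatchResult(bool(spans), boost * len(spans), spans)

    if isinstance(node, Phrase):
        words = node.text.split()
        spans = []
        for start in range(len(doc.tokens) - len(words) + 1):
            window = doc.tokens[start : start + len(words)]
            if all(
                _term_matches_token(w, t, mode, lexicon)
                for w, t in zip(words, window)
            ):
                spans.append((window[0].position, window[-1].position + 1))
        boost = node.boost if node.boost is not None else 1.0
        return MatchResult(bool(spans), boost * len(spans), spans)

    if isinstance(node, And):
        results = [_eval(c, doc, mode, lexicon) for c in node.children]
        matched = all(r.matched for r in results)
        if not matched:
            return MatchResult(False, 0.0, [])
        return MatchResult(
            True,
            sum(r.score for r in results),
            _merge_spans(r.spans for r in results),
        )

    if isinstance(node, Or):
        results = [_eval(c, doc, mode, lexicon) for c in node.children]
        matching = [r for r in results if r.matched]
        if not matching:
            return MatchResult(False, 0.0, [])
        return MatchResult(
            True,
            sum(r.score for r in matching),
            _merge_spans(r.spans for r in matching),
        )

    if isinstance(node, Not):
        inner = _eval(node.child, doc, mode, lexicon)
        return MatchResult(not inner.matched, 0.0, [])

    if isinstance(node, Near):
        if _contains_not(node.left) or _contains_not(node.right):
            raise UnsupportedCombinationError(
                "NOT is not supported as a NEAR operand"
            )
        left = _eval(node.left, doc, mode, lexicon)
        right = _eval(node.right, doc, mode, lexicon)
        if not (left.matched and right.matched):
            return MatchResult(False, 0.0, [])
        hulls = []
        for a in left.spans:
            for b in right.spans:
                if _near_pair_ok(node.distance, a, b, doc):
                    hulls.append((min(a[0], b[0]), max(a[1], b[1])))
        if not hulls:
            return MatchResult(False, 0.0, [])
        return MatchResult(
            True, left.score + right.score, _merge_spans([hulls])
        )

    if isinstance(node, Mode):
        return _eval(node.child, doc, node.mode, lexicon)

    raise TypeError(f"unknown node {node!r}")  # pragma: no cover


def _near_pair_ok(
    distance: Union[int, str],
    a: tuple[int, int],
    b: tuple[int, int],
    doc: TokenizedDocument,
) -> bool:
    if isinstance(distance, int):
        return _span_gap(a, b) <= distance
    attr = "sentence_index" if distance == "S" else "paragraph_index"
    units_a = {getattr(doc.tokens[p], attr) for p in range(a[0], a[1])}
    units_b = {getattr(doc.tokens[p], attr) for p in range(b[0], b[1])}
    # both spans inside one and the same sentence/paragraph
    return len(units_a) == 1 and units_a == units_b


def search(
    ast: QueryNode,
    corpus: list[TokenizedDocument],
    default_mode: str = DEFAULT_MODE,
    lexicon: Optional[Lexicon] = None,
) -> list[tuple[int, MatchResult]]:
    """Evaluate over a corpus; return matched documents ranked by score
    descending, ties broken by document index ascending."""
    hits = []
    for idx, doc in enumerate(corpus):
        result = evaluate(ast, doc, default_mode, lexicon)
        if result.matched:
            hits.append((idx, result))
    hits.sort(key=lambda pair: (-pair[1].score, pair[0]))
    return hits
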