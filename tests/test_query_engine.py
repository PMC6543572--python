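"""Parser, tokenizer and span evaluator, with brute-force oracles."""

import io
import random

import pytest
from hypothesis import given, settings, strategies as st

from sonq.query_engine import (
    And,
    Lexicon,
    Mode,
    Near,
    Not,
    Or,
    Phrase,
    QuerySyntaxError,
    Term,
    UnsupportedCombinationError,
    evaluate,
    normalize_word,
    parse_query,
    render_query,
    search,
    tokenize,
)
from sonq.fixtures import demo_lexicon


# -- tokenizer --------------------------------------------------------------


def test_tokenize_sentences_and_positions():
    doc = tokenize("Nitinol clip. Unexpected failure.")
    assert [t.surface for t in doc.tokens] == [
        "Nitinol", "clip", "Unexpected", "failure",
    ]
    assert [t.position for t in doc.tokens] == [0, 1, 2, 3]
    assert [t.sentence_index for t in doc.tokens] == [0, 0, 1, 1]
    assert {t.paragraph_index for t in doc.tokens} == {0}


def test_tokenize_paragraphs_split_on_blank_lines():
    doc = tokenize("one two.\n\nthree four.")
    assert [t.paragraph_index for t in doc.tokens] == [0, 0, 1, 1]
    assert [t.sentence_index for t in doc.tokens] == [0, 0, 1, 1]


def test_tokenize_normalizes_case_and_diacritics():
    doc = tokenize("Qualität GERÄT")
    assert [t.normalized for t in doc.tokens] == ["qualitat", "gerat"]


def test_tokenize_keeps_intraword_hyphens():
    doc = tokenize("state-of-the-art clip")
    assert [t.surface for t in doc.tokens] == ["state-of-the-art", "clip"]


def test_tokenize_compound_lookup():
    lex = Lexicon(compound_map={"qualitätskontrolle": ["Qualität", "Kontrolle"]})
    doc = tokenize("Qualitätskontrolle", lex)
    (token,) = doc.tokens
    assert token.compound_parts == ("qualitat", "kontrolle")


def test_tokenize_empty_text():
    assert tokenize("").tokens == []


def test_lexicon_file_parsing():
    lex = Lexicon.from_file(io.StringIO(
        "# comment\nfailures\tfailure\nmagenclip\tmagenclip\tmagen|clip\n"
    ))
    assert lex.baseform_map["failures"] == "failure"
    assert lex.compound_map["magenclip"] == ["magen", "clip"]


# -- parser -----------------------------------------------------------------


def test_parse_mode_wrapper():
    ast = parse_query("MODE/E (SafeSet)")
    assert isinstance(ast, Mode) and ast.mode == "E"
    assert isinstance(ast.child, Term) and ast.child.text == "SafeSet"


def test_parse_printed_composite_example():
    ast = parse_query(
        "(unexpected OR unforeseeable OR unknown) "
        "AND (complication OR failure OR incident)"
    )
    assert isinstance(ast, And) and len(ast.children) == 2
    for side in ast.children:
        assert isinstance(side, Or) and len(side.children) == 3


def test_parse_unbalanced_paren_reports_offset():
    with pytest.raises(QuerySyntaxError) as exc:
        parse_query("a AND (b")
    assert exc.value.offset == 6


def test_parse_precedence_or_and_not_near_mode():
    ast = parse_query("a OR b AND NOT c NEAR/2 MODE/E d")
    assert isinstance(ast, Or)
    a, rest = ast.children
    assert isinstance(a, Term)
    assert isinstance(rest, And)
    assert isinstance(rest.children[1], Not)
    near = rest.children[1].child
    assert isinstance(near, Near) and near.distance == 2
    assert isinstance(near.right, Mode)


def test_parse_boost_and_wildcard_atoms():
    ast = parse_query('incident^5 AND "nickel titanium"^2 AND unexp*')
    t, p, w = ast.children
    assert t.boost == 5 and p.boost == 2 and w.has_wildcard


def test_parse_near_left_associates():
    ast = parse_query("a NEAR/1 b NEAR/2 c")
    assert isinstance(ast, Near) and ast.distance == 2
    assert isinstance(ast.left, Near) and ast.left.distance == 1


@pytest.mark.parametrize(
    "text",
    ["", "AND", "a OR", '"unterminated', "a b)", "(a))"],
)
def test_parse_rejects_malformed(text):
    with pytest.raises(QuerySyntaxError):
        parse_query(text)


@pytest.mark.parametrize(
    "text",
    [
        "MODE/E (SafeSet)",
        "(a) NEAR/3 (b)",
        '(Nitinol OR "Nickel Titanium" OR NiTi)',
        "NOT (animal OR study OR preclinical)",
        "((a) AND (b)) AND (c) AND NOT (d)",
    ],
)
def test_render_parse_identity(text):
    assert render_query(parse_query(text)) == text


# -- evaluator --------------------------------------------------------------


def test_mode_e_is_case_sensitive():
    ast = parse_query("MODE/E (SafeSet)")
    assert evaluate(ast, tokenize("the SafeSet failed")).matched
    assert not evaluate(ast, tokenize("the safeset failed")).matched
    assert not evaluate(ast, tokenize("the SAFESET failed")).matched


def test_default_mode_d_folds_case_and_diacritics():
    ast = parse_query("gerat")
    assert evaluate(ast, tokenize("Das Gerät brennt")).matched


def test_mode_refinement_e_subset_of_d():
    # whatever MODE/E matches, the default D matches too
    docs = [tokenize(t) for t in ("SafeSet on", "safeset off", "nothing")]
    e_hits = {
        i for i, d in enumerate(docs)
        if evaluate(parse_query("MODE/E (SafeSet)"), d).matched
    }
    d_hits = {
        i for i, d in enumerate(docs)
        if evaluate(parse_query("SafeSet"), d).matched
    }
    assert e_hits <= d_hits


def test_mode_b_matches_lemmatized_forms():
    lex = demo_lexicon()
    doc = tokenize("several failures were reported", lex)
    assert evaluate(parse_query("MODE/B (failure)"), doc, lexicon=lex).matched
    assert not evaluate(parse_query("failure"), doc, lexicon=lex).matched


def test_mode_c_matches_compound_parts():
    lex = demo_lexicon()
    doc = tokenize("Die Qualitätskontrolle versagte", lex)
    assert evaluate(parse_query("MODE/C (Kontrolle)"), doc, lexicon=lex).matched
    assert not evaluate(parse_query("Kontrolle"), doc, lexicon=lex).matched


def test_empty_lexicon_degrades_gracefully():
    doc = tokenize("failures happen")
    assert evaluate(parse_query("MODE/B (failures)"), doc).matched
    assert not evaluate(parse_query("MODE/B (failure)"), doc).matched


def test_wildcard_matching():
    doc = tokenize("unforeseeable risks")
    assert evaluate(parse_query("unfor*"), doc).matched
    assert evaluate(parse_query("risk?"), doc).matched
    assert not evaluate(parse_query("unfor?"), doc).matched


def test_phrase_matches_consecutive_tokens():
    doc = tokenize("an endoscopic clipping system failed")
    assert evaluate(parse_query('"endoscopic clipping system"'), doc).matched
    assert not evaluate(
        parse_query('"endoscopic system"'), doc
    ).matched


def test_near_token_distance():
    ast = parse_query("a NEAR/1 b")
    assert evaluate(ast, tokenize("a b")).matched
    assert not evaluate(ast, tokenize("a x b")).matched
    assert evaluate(parse_query("a NEAR/2 b"), tokenize("a x b")).matched


def test_near_is_symmetric_in_order():
    ast = parse_query("a NEAR/2 b")
    assert evaluate(ast, tokenize("b x a")).matched


def test_near_sentence_and_paragraph():
    same = tokenize("alpha beta here.")
    cross_sentence = tokenize("alpha here. beta there.")
    cross_para = tokenize("alpha here.\n\nbeta there.")
    s_ast = parse_query("alpha NEAR/S beta")
    p_ast = parse_query("alpha NEAR/P beta")
    assert evaluate(s_ast, same).matched
    assert not evaluate(s_ast, cross_sentence).matched
    assert evaluate(p_ast, cross_sentence).matched
    assert not evaluate(p_ast, cross_para).matched


def test_near_spans_are_hulls_enabling_nesting():
    doc = tokenize("a b x x x c")
    inner_then_c = parse_query("(a NEAR/1 b) NEAR/4 c")
    assert evaluate(inner_then_c, doc).matched
    result = evaluate(parse_query("a NEAR/1 b"), doc)
    assert result.spans == [(0, 2)]


def test_not_inside_near_is_rejected():
    ast = parse_query("(NOT a) NEAR/2 b")
    with pytest.raises(UnsupportedCombinationError):
        evaluate(ast, tokenize("a b"))


def test_score_sums_boosts_over_occurrences():
    doc = tokenize("incident then another incident")
    assert evaluate(parse_query("incident^5"), doc).score == 10
    assert evaluate(parse_query("incident"), doc).score == 2
    assert evaluate(parse_query("missing"), doc).score == 0


def test_search_ranks_by_score_then_index():
    docs = [tokenize("incident"), tokenize("incident incident"),
            tokenize("nothing"), tokenize("incident")]
    hits = search(parse_query("incident^5"), docs)
    assert [(i, r.score) for i, r in hits] == [(1, 10.0), (0, 5.0), (3, 5.0)]


def test_search_empty_corpus():
    assert search(parse_query("a"), []) == []


# -- brute-force boolean oracle ---------------------------------------------


def _oracle_matched(node, doc, mode="D", lexicon=None):
    """Independent truth-table evaluation of the matched flag."""
    from sonq.query_engine import _term_matches_token

    lexicon = lexicon or Lexicon()
    if isinstance(node, Term):
        return any(
            _term_matches_token(node.text, t, mode, lexicon)
            for t in doc.tokens
        )
    if isinstance(node, Phrase):
        words = node.text.split()
        return any(
            all(
                _term_matches_token(w, t, mode, lexicon)
                for w, t in zip(words, doc.tokens[i : i + len(words)])
            )
            for i in range(len(doc.tokens) - len(words) + 1)
        )
    if isinstance(node, And):
        return all(_oracle_matched(c, doc, mode, lexicon) for c in node.children)
    if isinstance(node, Or):
        return any(_oracle_matched(c, doc, mode, lexicon) for c in node.children)
    if isinstance(node, Not):
        return not _oracle_matched(node.child, doc, mode, lexicon)
    if isinstance(node, Mode):
        return _oracle_matched(node.child, doc, node.mode, lexicon)
    raise TypeError(node)


_WORDS = ["alpha", "beta", "gamma", "delta"]


def random_boolean_ast(rng, depth=0):
    if depth >= 3 or rng.random() < 0.4:
        return Term(text=rng.choice(_WORDS))
    kind = rng.choice(["and", "or", "not", "mode"])
    if kind == "and":
        return And(children=[random_boolean_ast(rng, depth + 1)
                             for _ in range(rng.randint(2, 3))])
    if kind == "or":
        return Or(children=[random_boolean_ast(rng, depth + 1)
                            for _ in range(rng.randint(2, 3))])
    if kind == "not":
        return Not(child=random_boolean_ast(rng, depth + 1))
    return Mode(mode=rng.choice("EDBC"),
                child=random_boolean_ast(rng, depth + 1))


def test_boolean_laws_against_truth_table_oracle():
    rng = random.Random(2024)
    for _ in range(300):
        ast = random_boolean_ast(rng)
        words = [rng.choice(_WORDS + ["filler"]) for _ in range(rng.randint(0, 6))]
        doc = tokenize(" ".join(words))
        assert evaluate(ast, doc).matched == _oracle_matched(ast, doc)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.sampled_from(_WORDS + ["filler"]), max_size=6),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_and_or_not_compose_pointwise(words, seed):
    rng = random.Random(seed)
    a = random_boolean_ast(rng, depth=2)
    b = random_boolean_ast(rng, depth=2)
    doc = tokenize(" ".join(words))
    ma = evaluate(a, doc).matched
    mb = evaluate(b, doc).matched
    assert evaluate(And(children=[a, b]), doc).matched == (ma and mb)
    assert evaluate(Or(children=[a, b]), doc).matched == (ma or mb)
    assert evaluate(Not(child=a), doc).matched == (not ma)


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_near_monotone_in_k(seed):
    from sonq.fixtures import proximity_corpus

    docs, _ = proximity_corpus(3, seed=seed)
    tokenized = [tokenize(d.text) for d in docs]
    for doc in tokenized:
        previous = False
        for k in range(1, 10):
            ast = parse_query(f"(unexpected) NEAR/{k} (complication)")
            matched = evaluate(ast, doc).matched
            assert matched or not previous  # once true, stays true
            previous = matched


def test_appending_and_not_never_enlarges_matches():
    from sonq.fixtures import niti_corpus

    docs, _ = niti_corpus(40, seed=11)
    tokenized = [tokenize(d.text) for d in docs]
    base = parse_query("(unexpected) AND (complication)")
    narrowed = parse_query("(unexpected) AND (complication) AND NOT (animal)")
    base_hits = {i for i, d in enumerate(tokenized) if evaluate(base, d).matched}
    narrowed_hits = {
        i for i, d in enumerate(tokenized) if evaluate(narrowed, d).matched
    }
    assert narrowed_hits <= base_hits


def test_normalize_word_examples():
    assert normalize_word("Gerät") == "gerat"
    assert normalize_word("NiTi") == "niti"
    assert normalize_word("naïve") == "naive"
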