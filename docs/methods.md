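# Methods

## The model

A domain-specific search ontology (dSON) is a forest of *search
concepts* organised into facets, plus three auxiliary collections:
negated concepts, composite-term specifications and multiple-concept
query specifications. Concepts carry per-language (en/de) *simple
terms*: single words or fixed phrases, each optionally boosted (`^k`,
k > 0) or — for single words only — wildcarded (`*`, `?`). Term text
may not contain `;`, `^` or `"`; those characters are structural in
the template cells and the query syntax. Duplicate terms within a
concept are rejected: serialized OWL annotations are set-valued, so a
duplicate could not survive a round-trip, and it never changes a
query's semantics.

Query strings are generated bottom-up and stored on the model:

1. **composite term** `P1__P2` — `(<OR-join of P1 terms>) AND
   (<OR-join of P2 terms>)`, with the `AND` joiner replaced by
   `NEAR/k`, `NEAR/S` or `NEAR/P` when a proximity setting is present,
   and the whole expression wrapped `MODE/X ( … )` when a term-type
   mode is set;
2. **single-concept query** — parenthesized OR-join of the concept's
   rendered simple terms and its composite-term strings; composite
   strings are appended without extra parentheses because `AND`/`NEAR`
   bind tighter than the surrounding `OR`, keeping the printed form
   `((…) AND (…))` for a composite-only concept. Negated concepts
   yield `NOT ( … )` over their excluded terms plus the terms of any
   referenced excluded concepts;
3. **multiple-concept query** — AND-join of the member single-concept
   queries. A NEAR setting joins only the standard-concept
   sub-queries; negated members always attach with `AND`, since
   proximity to an absent term has no meaning. A mode wraps the whole
   expression.

Operand order follows specification (spreadsheet) order everywhere,
operators are uppercase with single spaces, and negation is spelled
`NOT ( … )` rather than a `-` prefix so that it composes under the
grammar. This makes generation deterministic to the byte and
idempotent, which the tests rely on.

## Template encoding

Facet sheets devote their first four columns (configurable) to
hierarchy depth: a concept's name sits in exactly one depth column and
its parent is the nearest preceding row in a shallower column — the
common spreadsheet-taxonomy dialect. This encoding can only express a
facet in forest pre-order, so the writer emits pre-order (stable in
roots and siblings) and the reader always produces it; the random
ontology generator used in round-trip tests generates pre-ordered
facets directly. Term cells are `;`-separated; `NEAR` cells accept
`5`, `S`, `P` or the spelled-out `NEAR/5` forms. The dSON's name and
namespace live in the workbook's title/subject document properties,
the only workbook-level slots that survive a round-trip without a
dedicated config sheet. The `Negated_Concept` sheet accepts a legacy
single `Excluded Simple Terms` column (read as English) and an
optional `Excluded Concepts` column so that concept-level exclusions
round-trip.

## OWL and JSON

The upper vocabulary — 9 classes (`Search_Concept` with
`Standard_Concept`/`Negated_Concept`, `Search_Term` with
`Simple_Term`/`Composite_Term`, `Search_Query` with
`Single_Concept_Query`/`Multiple_Concept_Query`) and 13 annotation
properties — is emitted into every document in its own namespace;
`described_by`, `has_part` and `has_terms_of_concept_as_part` are
declared for compatibility with the older instance-based modelling
style but not instantiated, terms and queries being plain annotations.
Domain classes specialise the vocabulary: facet hierarchies become
subclass axioms, simple terms language-tagged `simple_term` (or
`excluded_simple_term`) literals, generated queries language-tagged
`query` literals, composite terms classes with `part_1`/`part_2`/
`mode`/`near` annotations.

RDF graphs are unordered, but operand and term order matter here, so
ordered collections carry OWL axiom reifications holding an `index`
annotation, and facet order an RDF Seq, all in a small auxiliary
namespace separate from the vocabulary. Reification nodes are named
IRIs (`Axiom_<n>`), never blank nodes, which keeps the RDF/XML output
byte-deterministic — `generate` twice gives identical files. JSON
output is a fixed-key-order tree per facet (composite terms appear as
children of their owning concept) plus negated and multiple-query
sections, validated against the schema shipped in
`src/sonq/data/dson.schema.json`.

## Query engine

Precedence, loosest to tightest: `OR` < `AND` < `NOT` < `NEAR` <
`MODE` < atom; `NEAR` is binary and left-associates. Parsed trees
record explicit parentheses, so rendering reproduces generated strings
exactly (`render ∘ parse = id` on them) — the grammar-closure property
the generator's output is tested against.

Tokenization splits paragraphs on blank lines, sentences on `./!/?`
followed by whitespace (regex-based; abbreviation handling is out of
scope), and words on whitespace/punctuation with intra-word hyphens
kept. Each token carries its surface, a normalized form (case-folded,
diacritics stripped via NFKD), lexicon-derived baseforms and compound
parts. The lexicon is a pluggable tab-separated table
(`form<TAB>baseform<TAB>part1|part2`); with an empty lexicon, baseform
matching (`B`) degrades to normalized matching and compound matching
(`C`) to no splitting. A ~50-entry en/de demo lexicon ships with the
package for tests and demos.

Evaluation is span-based. A term matches per the active mode — `E`
exact surface, `D` normalized (the default: exact matching is the
restrictive opt-in), `B` baseform, `C` surface/normalized or any
compound part — wildcards matching against the mode's representation.
`AND`/`OR` take span unions; `NOT` yields no spans; `NEAR/k` accepts a
pair of operand spans whose nearest endpoints are at token distance
≤ k (adjacent tokens are at distance 1, overlapping spans ≤ 0), and
its own span is the hull of the pair, which is what makes nested
proximity meaningful; `NEAR/S`/`NEAR/P` require both spans inside one
and the same sentence/paragraph. `NOT` as a NEAR operand is rejected
as semantically undefined. The score is the boost-sum (default 1)
over distinct matched term/phrase occurrences — deliberately minimal
so boosts are observable; relevance modelling (BM25 etc.) is out of
scope. `search` ranks matched documents by score, ties by index.

## Synthetic data

The corpus builder emits filler sentences from a 20-word vocabulary
disjoint from every fixture term, and plants requested terms at exact
filler gaps with optional sentence/paragraph breaks between them. It
records each planted term's token span and sentence/paragraph index
*as it writes them*, so ground-truth labels (token distance = gap + 1,
same-sentence, same-paragraph, term presence) come from independent
arithmetic, not from the engine under test. Convenience corpora:

* `proximity_corpus` — one term pair per document, gap 0–6, boundary
  drawn uniformly from none/sentence/paragraph; used to check NEAR
  monotonicity and the exact `NEAR/S`/`NEAR/P` match sets (250
  documents in the acceptance test);
* `niti_corpus` — random subsets of the example query's features
  (unexpected-pair, material term, device phrase each with probability
  0.8; a negated term with probability 0.3, chosen so both outcomes
  are well represented), labelled positive exactly when all required
  features are present and no negated term is;
* `random_dson` — random structurally valid ontologies (hierarchies,
  both languages, phrases, boosts, wildcards, negated concepts,
  composite terms, proximity settings) for round-trip and
  grammar-closure testing; 100 are exercised per run.

What these corpora do not emulate: real clinical prose (morphology
beyond the demo lexicon, abbreviations, punctuation-heavy text),
ambiguous term senses, or retrieval at index scale. Passing tests
therefore demonstrate the correctness of query generation and of the
reference semantics, not retrieval quality on real literature — the
human-evaluation side of the original application is not computable
here and is out of scope.

## Problem sizes and numerics

Round-trip checks run on 100 random ontologies, proximity checks on
250 planted documents, the boolean truth-table oracle on 1,000 random
AST/document pairs — sizes at which every property is exhaustively
checkable in seconds. Boosts are stored as floats and rendered
integer-compact (`^5` not `^5.0`). All randomness flows through
explicit seeds; regenerating with the same seed reproduces inputs byte
for byte.

## Known limitations

* The exact identities of two vocabulary members are an interpretation
  (`Standard_Concept`, `excluded_simple_term`) chosen to reach the
  published 9-class/13-property totals with the names the modelling
  style implies.
* Hierarchies beneath negated concepts are unsupported (flat list),
  matching the template's single concept column.
* `from_owl` recovers ordering only from documents written by
  `to_owl`; foreign OWL is supported through
  `import_external_ontology`, which imports classes, labels and
  subclass links (first parent wins on diamonds, with a warning).
* The engine is a reference implementation over in-memory token
  streams; it does no indexing and is not meant for large corpora.
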