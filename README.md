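# sonq

Ontology-driven search-query generation for systematic literature
screening — e.g. post-market surveillance (PMS) of medical devices,
where analysts must repeatedly run complex, carefully negated boolean
queries against publication and incident databases.

Domain experts describe *what to search for* in a plain Excel workbook:
one sheet per facet of the question (Material, Medical_Device,
Incident, …), each holding a hierarchy of **search concepts** with
their per-language **simple terms** (single words or fixed phrases,
optionally boosted `incident^5` or wildcarded `unexp*`). Three reserved
sheets add **negated concepts** (terms that must *not* occur),
**composite terms** (pairs of concepts whose terms are combined), and
**multiple-concept queries** (conjunctions of several concepts). `sonq`
compiles this workbook into a domain-specific search ontology (dSON) in
OWL and JSON, generating for every item an executable query string in
an extended Lucene-style syntax:

* a composite term of concepts `Unexpected` × `Complication` becomes
  the AND-connection of their OR-linked terms —
  `(unexpected OR unforeseeable OR unknown) AND (complication OR failure OR incident)`;
* a single-concept query OR-joins all of a concept's terms, or negates
  them (`NOT (animal OR study OR preclinical)`) for a negated concept;
* a multiple-concept query AND-joins the single-concept queries.

The syntax extends boolean Lucene with proximity and term-type
operators: `NEAR/n` (token distance ≤ n), `NEAR/S` / `NEAR/P` (same
sentence / paragraph), and `MODE/E|D|B|C` selecting exact-surface,
diacritics-normalized, lemmatized-baseform, or compound-part matching.
A reference query engine (grammar, parser, tokenizer with sentence and
paragraph segmentation, span-based evaluator) executes these queries
over plain-text documents, so generated queries can be tested offline
before being forwarded to a production search engine.

## Worked example

```sh
sonq build-fixture -o niti.xlsx        # the example workbook
sonq generate -i niti.xlsx -o out/ --lang en
```

```
wrote out/dSON-Niti.owl and out/dSON-Niti.json
0 error(s), 0 warning(s)
```

The example models a PMS question: *unexpected complications of the
metal alloy Nitinol in endoscopic clipping systems, excluding
preclinical studies*. The generated multiple-concept query (stored as
a `query` annotation in the OWL file and under
`multiple_concept_queries` in the JSON) is

```
((unexpected OR unforeseeable OR unknown) AND (complication OR failure
OR incident)) AND (Nitinol OR "Nickel Titanium" OR NiTi) AND
("endoscopic clipping system") AND NOT (animal OR study OR preclinical)
```

Running it over a small corpus:

```sh
mkdir corpus
printf 'An unexpected complication. The Nitinol endoscopic clipping system failed.' > corpus/match.txt
printf 'lorem ipsum dolor.' > corpus/nomatch.txt
sonq search --query-name Niti_Query -i out/dSON-Niti.owl --corpus corpus --jsonl
```

```
{"path": "corpus/match.txt", "score": 4.0, "spans": [[1, 2], [2, 3], [4, 5], [5, 8]], "context": "unexpected"}
```

Only the planted document matches; the score is the boost-sum over the
four distinct matched term occurrences (`unexpected`, `complication`,
`Nitinol`, the device phrase), and the spans are the matched token
intervals. `sonq add-query` appends a new multiple-concept query to a
generated ontology, and `sonq run-url` prints a search-engine URL with
the percent-encoded query substituted for a `{query}` placeholder.

The same functionality is available as a library
(`sonq.read_template`, `sonq.generate_all`, `sonq.to_owl`,
`sonq.parse_query`, `sonq.evaluate`, …); `sonq.fixtures` builds the
example workbook, random valid ontologies, and synthetic corpora with
planted term occurrences and arithmetic ground-truth labels.

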