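# polymine

Co-occurrence association mining over local biomedical document
collections. polymine answers **"given X, find all associated Ys"**
queries — all diseases associated with a toxin, all genes associated with
a drug, all adverse effects associated with a chemical — by tagging
dictionary mentions in a corpus, scoring every co-occurrence sentence, and
ranking candidate targets by a standardized relevancy score, with the
supporting evidence sentences attached to each hit.

It is a library plus a `polymine` command-line tool, aimed at
bioinformaticians and cheminformaticians who keep a local corpus (for
example abstracts plus curated database records) and want ranked,
evidence-backed association candidates without a hosted search service.

## The method

Mentions of the query entity and of candidate targets are found by
dictionary matching against category thesauri (leftmost-longest, on word
boundaries; terms of ≤ 4 characters such as *BPA* or *p53* are matched
case-sensitively). Each candidate sentence is assigned a relevancy tier:

| Tier | Pattern |
|------|---------|
| R1 (best) | query + target + an association *filter word* in one sentence ("Enzyme X **catalyzes** reaction Y") |
| R2 | query + target in one sentence, no filter word |
| R3 | target + filter word in the sentence, query elsewhere in the document |
| R4 (worst) | target in the sentence, query elsewhere in the document |

The sentence score is

```
score = w(tier) · 1/(1 + α·s) [R1, R2 only] · b(record kind)
```

with default tier weights `w = 50 / 25 / 5 / 1`, tightness decay
`α = 0.02` applied to the token span `s` between the two mentions (tight
co-occurrence patterns are stronger evidence than distant ones), and a
weight boost `b = 2.0` for curated **database records** versus free-text
articles. Sentences containing a negation word ("X is **not** associated
with Y") contribute nothing.

Per-target sentence scores are summed into the raw relevancy score
(R-score) and standardized across all co-occurring candidates of the
query:

```
z_i = (s_i − mean(s)) / sd(s)        (population sd)
```

Candidates at or below the candidate-set average (`z ≤ 0`) are borderline
associations and removed by default, trading a little recall for
precision; `--include-borderline` keeps them.

## Worked example

polymine ships a seeded generator that emits a thesaurus, a corpus with
planted toxin–disease associations, and a matching gold standard:

```
$ polymine synth --seed 42 --out-dir demo
fobamu0

$ polymine query --term fobamu0 --query-category toxin \
    --target-category disease \
    --thesaurus demo/thesaurus.tsv --corpus demo/corpus.jsonl \
    --out demo/result.json
```

`demo/result.json` ranks 10 disease candidates. The top entry is

```
target_id  name      raw_score  z_score
T0004      kixesu4   268.2462   2.3784
```

i.e. the disease `kixesu4` accumulated an R-score of 268.25 over 5
evidence sentences and sits 2.38 standard deviations above the average
candidate. Its best evidence sentence is

```json
{"doc_id": "syn00019", "category": "R1", "span": 1, "score": 98.0392,
 "text": "Fobamu0 induces kixesu4."}
```

— an R1 co-occurrence (filter word "induces", span 1 token) in a database
record: 50 × 1/1.02 × 2.0 = 98.0392. Scoring the prediction set against
the planted gold standard:

```
$ polymine eval --predictions demo/result.json --gold demo/gold.tsv
{"tp": 10, "fp": 0, "fn": 0, "tn": 40,
 "precision": 1.0, "recall": 1.0, "f_measure": 1.0, "accuracy": 1.0}
```

All 10 planted associations are recovered and all 40 decoy diseases are
rejected by the borderline-association filter.

## File formats

* **Thesaurus** — TSV: `category  entry_id  canonical_name  syn1|syn2|…`
* **Corpus** — JSON-lines: `{"doc_id", "source", "record_kind", "title", "body"}`
  with `record_kind` ∈ {`free_text`, `database_record`}
* **Gold standard** — TSV: `query_term  entry_id  positive|negative`
* **Word lists** (filter words, negation words, custom synonyms) — one
  term per line, `#` comments
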