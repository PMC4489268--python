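# Methods

## Model

polymine treats association discovery as frequency-weighted co-occurrence
mining: the more often — and the more tightly and explicitly — a query
entity X and a candidate target Y are co-mentioned across a document
collection, the more likely their association is genuine. The unit of
evidence is the sentence. Every sentence that mentions a candidate target
in a retrieved document is assigned one of four relevancy tiers (R1–R4,
best to worst; see the README table), scored, summed per target into a raw
relevancy score, and the per-target scores are standardized into Z-scores
across the candidate set of that query.

The method assumes (a) dictionary matching is an adequate named-entity
recognizer given a good thesaurus — there is no statistical NER or
disambiguation; (b) sentence-level co-occurrence approximates assertion of
a relationship, with filter words separating asserted relations from
incidental co-mention; (c) the candidate set of a single query is large
enough for its score distribution to make standardization meaningful.

## Parameters

| Parameter | Default | Units / range | Role |
|---|---|---|---|
| `base_weights` | 50 / 25 / 5 / 1 | score units | Tier weights R1–R4. The normative contract is the ordering R1 ≥ R2 ≥ R3 ≥ R4 (enforced at construction), not the specific values; the defaults put a same-sentence co-occurrence (R2) an order of magnitude above a document-level one (R4) and double it again when an association word is present. |
| `tightness_alpha` | 0.02 | per token | Decay rate of the tightness factor `1/(1+αs)`. At the default, 10 intervening tokens cost ~17% of the score, 50 cost half. |
| `db_boost` | 2.0 | multiplier ≥ 1 | Weight boost for curated database records over free-text articles, reflecting their higher credibility. |
| `doc_limit` | 2000 | documents | Retrieval cap: only the top-ranked documents are mined. |
| `include_borderline` | false | — | Keep candidates with z ≤ 0. |
| `filter_words` | ~100 terms | — | Words/phrases signifying a strong association ("catalyzes", "increases the risk of"). A curated seed list ships as package data; users supply their own with `--filter-words`. |
| `negation_words` | ~24 terms | — | Words/bigrams marking negative assertions; one hit anywhere in a sentence zeroes that sentence's contribution. |

## Procedure and numerical choices

1. **Query expansion.** The query term is resolved in the query category;
   its synonym list drives retrieval and tagging. An unresolvable term is
   used verbatim (keyword mode); a term matching several entries is an
   error (the caller must disambiguate). User-supplied synonyms replace
   the automatic list.
2. **Retrieval.** Documents are ranked by raw synonym occurrence count
   (not TF-IDF/BM25 — counting is deterministic, oracle-checkable, and
   the cap is what matters), ties broken by doc id, truncated to
   `doc_limit`.
3. **Tagging.** Leftmost-longest dictionary matching on token boundaries.
   Terms ≤ 4 characters are matched case-sensitively (protects "ATP",
   "p53" against lowercase false positives); longer terms case-folded. An
   ambiguous surface form credits every entry that owns it — no
   disambiguation is attempted, so distinct mentions have disjoint token
   spans while ambiguous readings share one span.
4. **Classification and scoring.** Tier rules as in the README. The span
   for R1/R2 counts tokens strictly between the *nearest* query/target
   mention pair (minimum over pairs; the minimizing pair supplies the
   highlight offsets). Tightness applies only to the co-occurrence tiers
   R1/R2 — a document-level tier has no meaningful span. Negation anywhere
   in the sentence (token or bigram) zeroes the sentence. Negated
   sentences stay in the evidence list, flagged, but never enter
   aggregation.
5. **Ranking.** Z-scores use the population standard deviation, computed
   over co-occurring candidates only, before any filtering: the population
   form keeps one- and two-candidate sets well defined (sd of a single
   candidate is 0, hence z = 0 — a lone candidate is by construction
   "average" and is hidden unless borderline cases are included; this is
   deliberate and surfaced in the CLI help). The zero-variance case yields
   all-zero z. The borderline filter removes z ≤ 0 (at-or-below-average
   candidates). ALL-target queries compute one Z-score universe per target
   category, because score scales differ across categories. Ties in the
   final ordering break by raw score, then entry id — fully deterministic.
6. **Sentence splitting** is rule-based (split after `.!?` + whitespace +
   uppercase/digit, a fixed abbreviation stop-list shipped as data), with
   the title as sentence 0 so title co-occurrences score. Rule-based
   splitting keeps runs byte-reproducible with no model downloads; it will
   mis-split prose the stop-list does not anticipate, which shifts
   R1/R2 ↔ R3/R4 assignments in rare cases but never invents mentions.

## Synthetic benchmark

The `synthdata` module emulates the structure the scorer consumes, not
natural language: templated sentences over a synthesized vocabulary. A
query entity and two disjoint pools of disease targets are generated —
*true targets* each co-mentioned with the query in `docs_per_true_pair`
documents (a `r1_fraction` share with a filter verb, the rest with a
controlled token gap), and *decoys* that co-occur only by chance at
`decoy_cooccur_prob` per document. A `negation_prob` share of planted
sentences is negated; a `db_record_fraction` share of documents is
flagged as database records. Entity names are unique synthesized tokens,
so decoys share no synonyms with true targets and ranking behaviour is
isolated from dictionary ambiguity (ambiguity is exercised separately in
the thesaurus tests). Everything derives from one integer seed;
regeneration is byte-identical.

What passing the recovery benchmark shows: the pipeline separates planted
from chance co-occurrence at the configured rates, end to end, and the
borderline filter moves precision and recall in the documented directions.
What it does not show: performance on real prose (no anaphora, paraphrase,
nested entities or real negation scope), real thesaurus scale, or
calibration of the default weights against curated gold standards.

The benchmark conditions used by the acceptance script and tests are 10
true targets, 40 decoys, 5 documents per true pair, decoy co-occurrence
0.02, negation 0.1 — 50 documents per run, which keeps a full recovery
sweep (20 seeds × 2 configurations) in the order of seconds.

## Known limitations

- Dictionary NER only: spelling variants outside the synonym list are
  missed; ambiguous surface forms credit every owner.
- The shipped filter-word list is a small curated seed (~100 terms), far
  smaller than a production association-verb lexicon; R1/R2 assignment is
  only as good as this list.
- Negation is sentence-scoped, not mention-scoped: a negation word
  anywhere in the sentence suppresses all of its evidence, including
  genuinely positive clauses.
- Retrieval ranking by raw term frequency favours long documents; the
  config exposes the cap but not alternative rankers.
- Single-candidate queries return nothing under default settings (z = 0
  is borderline by definition); use `--include-borderline`.
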