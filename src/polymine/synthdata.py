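"""Seeded synthetic fixtures: thesauri, corpora with planted associations,
and matching gold standards.

The generator builds one query entity (a toxin) and two disjoint pools of
disease entities: *true targets*, each co-mentioned with the query in a
configurable number of documents, and *decoys*, which co-occur with the
query only by chance at a configurable probability. Planted sentences are
templated — a fraction carry a filter verb (top-tier co-occurrences), the
rest separate query and target by a controlled run of neutral tokens, and
a configurable fraction are negated. Entity names are synthesized unique
tokens, so decoys share no synonyms with true targets and ranking behavior
is isolated from dictionary ambiguity.

Everything is driven by one integer seed; the emitted files are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from random import Random

from .corpus import build_index, read_corpus
from .evaluation import EvalReport, evaluate, load_gold_standard
from .scoring import ScoringConfig
from .thesaurus import load_thesaurus

__all__ = ["SynthConfig", "SynthPaths", "generate", "end_to_end_recovery"]

QUERY_CATEGORY = "toxin"
TARGET_CATEGORY = "disease"

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "pa", "qui", "ro", "su", "ti", "vo", "wa", "xe", "yo", "zu",
)

# Single-token filter verbs drawn from the packaged default list.
_R1_VERBS = ("causes", "induces", "triggers", "exacerbates", "aggravates")

# Neutral connective/filler vocabulary: none of these tokens appear in the
# default filter-word or negation-word lists.
_NEUTRAL = (
    "patients", "samples", "cohort", "tissue", "serum", "plasma",
    "baseline", "exposure", "profile", "measurement", "subjects",
    "survey", "records", "datasets", "archive", "registry",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic benchmark.

    Defaults mirror a small but non-trivial desk-scale recovery task: a
    handful of genuine associations embedded among four times as many
    decoys, with occasional chance co-mentions and a 10% negation rate.
    """

    seed: int = 0
    n_true_targets: int = 10
    n_decoy_targets: int = 40
    docs_per_true_pair: int = 5
    r1_fraction: float = 0.6
    decoy_cooccur_prob: float = 0.02
    negation_prob: float = 0.1
    db_record_fraction: float = 0.2
    filler_sentences_per_doc: int = 2

    def __post_init__(self) -> None:
        for name in ("r1_fraction", "decoy_cooccur_prob", "negation_prob",
                     "db_record_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_true_targets", "n_decoy_targets", "docs_per_true_pair",
                     "filler_sentences_per_doc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_true_targets + self.n_decoy_targets < 1:
            raise ValueError("need at least one target entity")

    def with_options(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SynthPaths:
    thesaurus: Path
    corpus: Path
    gold: Path
    query_term: str = ""


def _name(rng: Random, used: set[str], suffix: int) -> str:
    """A unique pronounceable token; the numeric suffix guarantees global
    uniqueness and keeps names disjoint from the neutral vocabulary."""
    while True:
        base = "".join(rng.choice(_SYLLABLES) for _ in range(3)) + str(suffix)
        if base not in used:
            used.add(base)
            return base


def _entity(rng: Random, used: set[str], suffix: int, kind: str) -> dict:
    base = _name(rng, used, suffix)
    variants = [f"{base} {kind}", f"chronic {base}", f"{base} complex"]
    n_syn = rng.randint(2, 4)
    synonyms = [base] + rng.sample(variants, n_syn - 1)
    return {"canonical": base, "synonyms": synonyms}


def _capitalize(sentence: str) -> str:
    return sentence[0].upper() + sentence[1:]


def _planted_sentence(rng: Random, cfg: SynthConfig, q: str, t: str) -> str:
    if rng.random() < cfg.r1_fraction:
        verb = rng.choice(_R1_VERBS)
        body = f"{q} {verb} {t}"
    else:
        gap = " ".join(rng.choice(_NEUTRAL) for _ in range(rng.randint(1, 6)))
        body = f"{q} appeared with {gap} near {t}"
    if rng.random() < cfg.negation_prob:
        body += " although the effect was not confirmed"
    return _capitalize(body) + "."


def _filler_sentence(rng: Random) -> str:
    words = " ".join(rng.choice(_NEUTRAL) for _ in range(rng.randint(4, 8)))
    return _capitalize(words) + "."


def generate(config: SynthConfig, out_dir: str | Path) -> SynthPaths:
    """Emit thesaurus TSV, corpus JSON-lines and gold TSV into *out_dir*."""
    rng = Random(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used: set[str] = set()

    query = _entity(rng, used, 0, "toxin")
    trues = [
        _entity(rng, used, i + 1, "disease")
        for i in range(config.n_true_targets)
    ]
    decoys = [
        _entity(rng, used, i + 1 + config.n_true_targets, "disease")
        for i in range(config.n_decoy_targets)
    ]

    thesaurus_path = out / "thesaurus.tsv"
    with open(thesaurus_path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic thesaurus\n")
        fh.write(
            f"{QUERY_CATEGORY}\tQ0001\t{query['canonical']}\t"
            + "|".join(query["synonyms"])
            + "\n"
        )
        for i, ent in enumerate(trues):
            fh.write(
                f"{TARGET_CATEGORY}\tT{i + 1:04d}\t{ent['canonical']}\t"
                + "|".join(ent["synonyms"])
                + "\n"
            )
        for i, ent in enumerate(decoys):
            fh.write(
                f"{TARGET_CATEGORY}\tD{i + 1:04d}\t{ent['canonical']}\t"
                + "|".join(ent["synonyms"])
                + "\n"
            )

    q = query["canonical"]
    corpus_path = out / "corpus.jsonl"
    with open(corpus_path, "w", encoding="utf-8") as fh:
        doc_no = 0
        for t_idx, ent in enumerate(trues):
            for _ in range(config.docs_per_true_pair):
                doc_no += 1
                sentences = [
                    _filler_sentence(rng)
                    for _ in range(config.filler_sentences_per_doc)
                ]
                sentences.insert(
                    rng.randint(0, len(sentences)),
                    _planted_sentence(rng, config, q, ent["canonical"]),
                )
                for decoy in decoys:
                    if rng.random() < config.decoy_cooccur_prob:
                        sentences.append(
                            _capitalize(
                                f"{q} appeared alongside {decoy['canonical']}"
                            )
                            + "."
                        )
                is_db = rng.random() < config.db_record_fraction
                rec = {
                    "doc_id": f"syn{doc_no:05d}",
                    "source": "syndb" if is_db else "synmed",
                    "record_kind": "database_record" if is_db else "free_text",
                    "title": f"Observation report {doc_no}",
                    "body": " ".join(sentences),
                }
                fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True))
                fh.write("\n")

    gold_path = out / "gold.tsv"
    with open(gold_path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic gold standard\n")
        for i in range(len(trues)):
            fh.write(f"{q}\tT{i + 1:04d}\tpositive\n")
        for i in range(len(decoys)):
            fh.write(f"{q}\tD{i + 1:04d}\tnegative\n")

    return SynthPaths(thesaurus_path, corpus_path, gold_path, query_term=q)


def end_to_end_recovery(
    config: SynthConfig, scoring_config: ScoringConfig | None = None
) -> EvalReport:
    """Generate fixtures, run the full engine, score against the gold.

    Uses a temporary directory for the emitted files; returns the
    contingency report of predicted vs planted associations.
    """
    from .engine import QuerySpec, run_query

    scoring_config = scoring_config or ScoringConfig()
    with tempfile.TemporaryDirectory() as tmp:
        paths = generate(config, tmp)
        thesaurus = load_thesaurus(paths.thesaurus)
        documents = read_corpus(paths.corpus)
        index = build_index(documents)
        spec = QuerySpec(
            query_term=paths.query_term,
            query_category=QUERY_CATEGORY,
            target_category=TARGET_CATEGORY,
            config=scoring_config,
        )
        result = run_query(spec, thesaurus, index, documents)
        predicted = {r.target_entry_id for r in result.results}
        gold = load_gold_standard(paths.gold)
        return evaluate(predicted, gold)
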