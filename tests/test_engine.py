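"""Query expansion and end-to-end pipeline orchestration."""

import json

import pytest

from polymine.corpus import Document, build_index
from polymine.engine import QuerySpec, expand_query, run_query
from polymine.errors import CorpusError, QueryError
from polymine.ranking import result_to_json
from polymine.scoring import ScoringConfig
from polymine.thesaurus import Thesaurus

from conftest import make_entry


def _spec(**kwargs):
    kwargs.setdefault("query_term", "breast cancer")
    kwargs.setdefault("query_category", "disease")
    kwargs.setdefault("target_category", "disease")
    return QuerySpec(**kwargs)


class TestExpandQuery:
    def test_resolves_entry_synonyms(self, bpa_thesaurus):
        spec = _spec(query_term="breast cancer", target_category="toxin")
        syns, entry_id = expand_query(spec, bpa_thesaurus)
        assert set(syns) == {"breast neoplasms", "breast cancer"}
        assert entry_id == "D0001"

    def test_keyword_fallback(self, bpa_thesaurus):
        spec = _spec(query_term="zzz-Compound")
        syns, entry_id = expand_query(spec, bpa_thesaurus)
        assert syns == ["zzz-compound"] and entry_id is None

    def test_custom_synonyms_override(self, bpa_thesaurus):
        spec = _spec(query_term="breast cancer", custom_synonyms=["bpa"])
        syns, _ = expand_query(spec, bpa_thesaurus)
        assert syns == ["bpa"]

    def test_ambiguous_term_lists_candidates(self):
        th = Thesaurus(
            {
                "disease": [
                    make_entry("D1", "disease", "first gout", ["gout", "first gout"]),
                    make_entry("D2", "disease", "other gout", ["gout", "other gout"]),
                ]
            }
        )
        with pytest.raises(QueryError, match="D1.*D2"):
            expand_query(_spec(query_term="gout"), th)

    def test_empty_query_term_rejected(self):
        with pytest.raises(QueryError):
            _spec(query_term="  ")


def _toxin_thesaurus(n_targets=3):
    return Thesaurus(
        {
            "toxin": [make_entry("X1", "toxin", "querol")],
            "disease": [
                make_entry(f"D{i}", "disease", f"malady{i} syndrome")
                for i in range(1, n_targets + 1)
            ],
        }
    )


def _docs_with_counts(counts):
    """One R2 co-occurrence sentence per unit of count for each target."""
    docs = []
    n = 0
    for target_idx, count in enumerate(counts, start=1):
        for _ in range(count):
            n += 1
            docs.append(
                Document(
                    doc_id=f"d{n:03d}",
                    body=f"Querol appeared near malady{target_idx} syndrome.",
                )
            )
    return docs


def run(spec, th, docs):
    return run_query(spec, th, build_index(docs), docs)


class TestRunQuery:
    def test_single_candidate_hidden_unless_borderline_included(self):
        th = _toxin_thesaurus(1)
        docs = _docs_with_counts([2])
        spec = _spec(query_term="querol", query_category="toxin")
        assert run(spec, th, docs).results == []
        spec_inc = _spec(
            query_term="querol",
            query_category="toxin",
            config=ScoringConfig(include_borderline=True),
        )
        (only,) = run(spec_inc, th, docs).results
        assert only.target_entry_id == "D1" and only.z_score == 0.0

    def test_order_follows_raw_evidence(self):
        th = _toxin_thesaurus(3)
        docs = _docs_with_counts([1, 5, 3])
        spec = _spec(
            query_term="querol",
            query_category="toxin",
            config=ScoringConfig(include_borderline=True),
        )
        result = run(spec, th, docs)
        assert [r.target_entry_id for r in result.results] == ["D2", "D3", "D1"]
        raws = [r.raw_score for r in result.results]
        assert raws == sorted(raws, reverse=True)

    def test_doc_limit_caps_evidence(self):
        th = _toxin_thesaurus(1)
        docs = [
            Document(doc_id="a", body="Querol near malady1 syndrome. Querol again."),
            Document(doc_id="b", body="Querol near malady1 syndrome."),
        ]
        spec = _spec(
            query_term="querol",
            query_category="toxin",
            config=ScoringConfig(doc_limit=1, include_borderline=True),
        )
        result = run(spec, th, docs)
        (only,) = result.results
        assert {e.doc_id for e in only.evidence} == {"a"}

    def test_doc_limit_at_corpus_size_matches_unlimited(self):
        th = _toxin_thesaurus(3)
        docs = _docs_with_counts([2, 1, 4])
        base = dict(query_term="querol", query_category="toxin")
        exact = run(
            _spec(**base, config=ScoringConfig(doc_limit=len(docs))), th, docs
        )
        unlimited = run(
            _spec(**base, config=ScoringConfig(doc_limit=10**9)), th, docs
        )
        a = json.loads(result_to_json(exact))
        b = json.loads(result_to_json(unlimited))
        assert a["results"] == b["results"]

    def test_custom_targets_restrict_candidates(self):
        th = _toxin_thesaurus(3)
        docs = _docs_with_counts([2, 2, 2])
        spec = _spec(
            query_term="querol",
            query_category="toxin",
            custom_targets=["D1", "D3"],
            config=ScoringConfig(include_borderline=True),
        )
        result = run(spec, th, docs)
        assert {r.target_entry_id for r in result.results} == {"D1", "D3"}

    def test_unknown_custom_target_rejected(self):
        th = _toxin_thesaurus(1)
        spec = _spec(
            query_term="querol", query_category="toxin", custom_targets=["NOPE"]
        )
        with pytest.raises(QueryError, match="NOPE"):
            run(spec, th, _docs_with_counts([1]))

    def test_empty_corpus_is_error(self):
        with pytest.raises(CorpusError):
            run_query(
                _spec(query_term="querol", query_category="toxin"),
                _toxin_thesaurus(1),
                build_index([]),
                [],
            )

    def test_no_retrieved_documents_gives_empty_result(self):
        th = _toxin_thesaurus(1)
        docs = [Document(doc_id="a", body="Nothing relevant here.")]
        spec = _spec(query_term="querol", query_category="toxin")
        assert run(spec, th, docs).results == []

    def test_keyword_and_thesaurus_mode_agree_on_single_synonym_entry(self):
        docs = _docs_with_counts([2])
        th_with = Thesaurus(
            {
                "toxin": [make_entry("X1", "toxin", "querol")],
                "disease": [make_entry("D1", "disease", "malady1 syndrome")],
            }
        )
        th_without = Thesaurus(
            {
                "toxin": [],
                "disease": [make_entry("D1", "disease", "malady1 syndrome")],
            }
        )
        cfg = ScoringConfig(include_borderline=True)
        spec = _spec(query_term="querol", query_category="toxin", config=cfg)
        a = run(spec, th_with, docs)
        b = run(spec, th_without, docs)
        assert [(r.target_entry_id, r.raw_score) for r in a.results] == [
            (r.target_entry_id, r.raw_score) for r in b.results
        ]

    def test_all_target_mode_uses_per_category_universes(self):
        th = Thesaurus(
            {
                "toxin": [make_entry("X1", "toxin", "querol")],
                "disease": [
                    make_entry("D1", "disease", "malady1 syndrome"),
                    make_entry("D2", "disease", "malady2 syndrome"),
                ],
                "gene": [
                    make_entry("G1", "gene", "genex protein"),
                    make_entry("G2", "gene", "geney protein"),
                ],
            }
        )
        docs = [
            Document(doc_id="d1", body="Querol near malady1 syndrome. Querol near malady1 syndrome."),
            Document(doc_id="d2", body="Querol near malady2 syndrome."),
            Document(doc_id="d3", body="Querol near genex protein. Querol near genex protein."),
            Document(doc_id="d4", body="Querol near geney protein."),
        ]
        spec = _spec(
            query_term="querol", query_category="toxin", target_category="ALL"
        )
        result = run(spec, th, docs)
        # with default borderline filtering, only the above-average
        # candidate of each category survives
        assert {r.target_entry_id for r in result.results} == {"D1", "G1"}

    def test_determinism_byte_identical_json(self):
        th = _toxin_thesaurus(3)
        docs = _docs_with_counts([3, 1, 2])
        spec = _spec(
            query_term="querol",
            query_category="toxin",
            config=ScoringConfig(include_borderline=True),
        )
        a = result_to_json(run(spec, th, docs))
        b = result_to_json(run(spec, th, docs))
        assert a == b
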