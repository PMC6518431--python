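"""Ordered-source evidence collection, dedup, and incremental yield."""

import datetime as dt

import pytest

from tt_testutil import d, make_evidence, make_record

from trialtrack import (
    ContractError,
    EvidenceFormat,
    EvidenceSource,
    SearchConfig,
    collect_evidence,
    earliest_dissemination,
    incremental_yield,
)


class TestCollectEvidence:
    def test_summary_results_synthesized_from_record(self):
        record = make_record(summary="2013-04-01")
        es = collect_evidence(record, [], SearchConfig())
        assert len(es.evidence) == 1
        assert es.evidence[0].source is EvidenceSource.registry_summary
        assert es.evidence[0].format is EvidenceFormat.summary_result
        assert es.first_found_source is EvidenceSource.registry_summary
        assert es.earliest_dissemination_date == d("2013-04-01")

    def test_duplicate_doi_attributed_to_earlier_source(self):
        record = make_record()
        corpus = [
            make_evidence(source="manual_search", identifier="10.1/x", rater="rater_a"),
            make_evidence(source="pubmed_id_search", identifier="10.1/x", rater="auto"),
        ]
        es = collect_evidence(record, corpus, SearchConfig())
        assert len(es.evidence) == 1
        assert es.evidence[0].source is EvidenceSource.pubmed_id_search
        assert es.first_found_source is EvidenceSource.pubmed_id_search

    def test_linked_identifier_joined_to_corpus_as_registry_indexed(self):
        record = make_record(linked=("10.1/x",))
        corpus = [make_evidence(source="pubmed_id_search", identifier="10.1/x")]
        es = collect_evidence(record, corpus, SearchConfig())
        assert es.evidence[0].source is EvidenceSource.registry_indexed
        assert es.first_found_source is EvidenceSource.registry_indexed

    def test_no_evidence_anywhere(self):
        es = collect_evidence(make_record(), [], SearchConfig())
        assert es.evidence == ()
        assert es.earliest_dissemination_date is None
        assert es.first_found_source is None

    def test_dedup_idempotence(self):
        record = make_record(summary="2013-04-01", linked=("10.1/x",))
        corpus = [
            make_evidence(identifier="10.1/x"),
            make_evidence(identifier="10.1/y", source="pubmed_id_search"),
        ]
        config = SearchConfig()
        once = collect_evidence(record, corpus, config)
        twice = collect_evidence(record, list(once.evidence) + corpus, config)
        assert {e.identifier for e in twice.evidence} == {e.identifier for e in once.evidence}
        assert twice.earliest_dissemination_date == once.earliest_dissemination_date

    def test_adding_a_source_never_removes_evidence_or_delays_earliest(self):
        record = make_record(summary="2014-06-01")
        corpus = [make_evidence(identifier="10.1/x", date="2014-02-01")]
        short = SearchConfig(source_order=["registry_summary"])
        full = SearchConfig(source_order=["registry_summary", "manual_search"])
        es_short = collect_evidence(record, corpus, short)
        es_full = collect_evidence(record, corpus, full)
        ids_short = {e.identifier for e in es_short.evidence}
        ids_full = {e.identifier for e in es_full.evidence}
        assert ids_short <= ids_full
        assert es_full.earliest_dissemination_date <= es_short.earliest_dissemination_date


class TestEarliestDissemination:
    def test_min_date_wins_and_format_reported(self):
        record = make_record(summary="2014-06-01")
        corpus = [make_evidence(identifier="10.1/x", date="2014-02-01")]
        es = collect_evidence(record, corpus, SearchConfig())
        date, fmt = earliest_dissemination(es, {"journal_article", "summary_result"})
        assert (date, fmt) == (d("2014-02-01"), EvidenceFormat.journal_article)

    def test_format_restriction_can_empty_the_result(self):
        record = make_record(summary="2014-06-01")
        es = collect_evidence(record, [], SearchConfig())
        assert earliest_dissemination(es, {EvidenceFormat.journal_article}) is None

    def test_tie_broken_by_format_priority(self):
        record = make_record(summary="2014-02-01")
        corpus = [make_evidence(identifier="10.1/x", date="2014-02-01")]
        es = collect_evidence(record, corpus, SearchConfig())
        _, fmt = earliest_dissemination(es, {"journal_article", "summary_result"})
        assert fmt is EvidenceFormat.journal_article

    def test_enlarging_accepted_formats_never_delays(self):
        record = make_record(summary="2013-01-01")
        corpus = [make_evidence(identifier="10.1/x", date="2014-02-01")]
        es = collect_evidence(record, corpus, SearchConfig())
        narrow = earliest_dissemination(es, {EvidenceFormat.journal_article})
        wide = earliest_dissemination(
            es, {EvidenceFormat.journal_article, EvidenceFormat.summary_result}
        )
        assert wide[0] <= narrow[0]


class TestIncrementalYield:
    def test_registry_plus_manual_pattern(self):
        """48 of 100 trials found by registry/PubMed steps, 27 only manually."""
        config = SearchConfig()
        records, corpus = [], []
        for i in range(100):
            tid = f"NCT{i:08d}"
            if i < 48:
                records.append(make_record(trial_id=tid, summary="2013-04-01"))
            else:
                records.append(make_record(trial_id=tid))
                if i < 75:
                    corpus.append(make_evidence(trial_id=tid, source="manual_search",
                                                identifier=f"10.1/{i}"))
        sets = [collect_evidence(r, corpus, config) for r in records]
        table = incremental_yield(sets, config)
        by_source = table.set_index("source")
        assert by_source.loc["registry_summary", "n_new"] == 48
        assert by_source.loc["manual_search", "n_new"] == 27
        assert by_source.loc["pubmed_id_search", "cumulative_proportion"] == pytest.approx(0.48)
        assert by_source.loc["manual_search", "cumulative_proportion"] == pytest.approx(0.75)
        assert by_source["cumulative_proportion"].is_monotonic_increasing

    def test_nothing_found(self):
        config = SearchConfig()
        sets = [collect_evidence(make_record(trial_id=f"NCT{i:08d}"), [], config) for i in range(5)]
        table = incremental_yield(sets, config)
        assert (table["n_new"] == 0).all()
        assert (table["cumulative_proportion"] == 0.0).all()

    def test_single_source_row_equals_overall_proportion(self):
        config = SearchConfig(source_order=["registry_summary"])
        records = [make_record(trial_id="NCT00000001", summary="2013-01-01"),
                   make_record(trial_id="NCT00000002")]
        sets = [collect_evidence(r, [], config) for r in records]
        table = incremental_yield(sets, config)
        assert len(table) == 1
        assert table.loc[0, "cumulative_proportion"] == pytest.approx(0.5)

    def test_mixed_source_orders_rejected(self):
        a = collect_evidence(make_record(trial_id="NCT00000001"), [], SearchConfig())
        b = collect_evidence(
            make_record(trial_id="NCT00000002"), [],
            SearchConfig(source_order=["manual_search"]),
        )
        with pytest.raises(ContractError):
            incremental_yield([a, b], SearchConfig())
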