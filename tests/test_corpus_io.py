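"""Corpus I/O: round-trips, validation, sample trimming, descriptives."""

from __future__ import annotations

import json

import pytest

from lexkey import (
    SchemaError,
    filter_participants,
    read_narrative_table,
    read_token_table,
    summarize_corpus,
    write_exclusion_log,
    write_narrative_table,
    write_token_table,
)
from lexkey.corpus_io import parse_doc_id


class TestNarrativeTable:
    def test_round_trip_identity(self, tmp_path, participant_factory,
                                 narrative_factory):
        pairs = [
            (participant_factory(doc_id=1),
             narrative_factory(doc_id=1, text="перший текст, з комою")),
            (participant_factory(doc_id=2, age=55, pcl5_total=None,
                                 miss_total=None, displaced=True,
                                 gender="man"),
             narrative_factory(doc_id=2, text='другий "текст"\nз рядком',
                               original_language="ru")),
        ]
        path = tmp_path / "narratives.csv"
        write_narrative_table(pairs, path)
        assert read_narrative_table(path) == pairs

    def test_header_only_file_reads_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_narrative_table([], path)
        assert read_narrative_table(path) == []

    @pytest.mark.parametrize(
        "raw,expected", [("doc1", 1), ("7", 7), ("doc042", 42)]
    )
    def test_doc_ordinal_spellings(self, raw, expected):
        assert parse_doc_id(raw) == expected

    @pytest.mark.parametrize("raw", ["docx", "", "doc0", "-3"])
    def test_invalid_doc_ordinal(self, raw):
        with pytest.raises(ValueError):
            parse_doc_id(raw)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("doc_id,gender\ndoc1,woman\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="age"):
            read_narrative_table(path)

    def test_bad_rows_are_quarantined_not_fatal(self, tmp_path,
                                                participant_factory,
                                                narrative_factory):
        path = tmp_path / "narratives.csv"
        write_narrative_table(
            [(participant_factory(doc_id=1), narrative_factory(doc_id=1)),
             (participant_factory(doc_id=2), narrative_factory(doc_id=2))],
            path,
        )
        rows = path.read_text(encoding="utf-8").splitlines()
        rows[1] = rows[1].replace("30", "thirty", 1)  # unparseable age
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        quarantine: list = []
        pairs = read_narrative_table(path, quarantine=quarantine)
        assert [r.doc_id for r, _ in pairs] == [2]
        assert len(quarantine) == 1 and quarantine[0].row_number == 2

    def test_out_of_range_score_is_quarantined(self, tmp_path,
                                               participant_factory,
                                               narrative_factory):
        path = tmp_path / "narratives.csv"
        write_narrative_table(
            [(participant_factory(doc_id=1), narrative_factory(doc_id=1))],
            path,
        )
        text = path.read_text(encoding="utf-8").replace(",40,", ",90,")
        path.write_text(text, encoding="utf-8")
        quarantine: list = []
        assert read_narrative_table(path, quarantine=quarantine) == []
        assert "pcl5" in str(quarantine[0])

    def test_unknown_categorical_preserved_with_warning(self, tmp_path,
                                                        participant_factory,
                                                        narrative_factory):
        path = tmp_path / "narratives.csv"
        write_narrative_table(
            [(participant_factory(doc_id=1, gender="nonbinary"),
              narrative_factory(doc_id=1))],
            path,
        )
        (record, _), = read_narrative_table(path)
        assert record.gender == "nonbinary"
        assert any("gender" in w for w in record.warnings)


class TestTokenTable:
    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "empty.conllu"
        path.write_text("", encoding="utf-8")
        assert list(read_token_table(path)) == []

    def test_three_token_sentence_indexing(self, tmp_path, token_factory):
        tokens = [
            token_factory(token_index=i, form=f, sentence_text="а б в")
            for i, f in enumerate(["а", "б", "в"], start=1)
        ]
        path = tmp_path / "one.conllu"
        write_token_table(tokens, path)
        read_back = list(read_token_table(path))
        assert [t.token_index for t in read_back] == [1, 2, 3]
        assert read_back == tokens

    def test_round_trip_multi_document(self, tmp_path, token_factory):
        tokens = [
            token_factory(doc_id=1, sentence_index=1, token_index=1),
            token_factory(doc_id=1, sentence_index=1, token_index=2,
                          form="мир"),
            token_factory(doc_id=1, sentence_index=2, token_index=1,
                          form="дім"),
            token_factory(doc_id=3, sentence_index=1, token_index=1,
                          form="ніч"),
        ]
        path = tmp_path / "multi.conllu"
        write_token_table(tokens, path)
        assert list(read_token_table(path)) == tokens

    def test_multiword_range_line_skipped_and_counted(self, tmp_path):
        path = tmp_path / "mwt.conllu"
        path.write_text(
            "# newdoc id = doc1\n"
            "# newpar\n"
            "# sent_id = doc1.p1.s1\n"
            "# text = у домі\n"
            "2-3\tудомі\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tу\tу\tADP\t_\t_\t2\tcase\t_\t_\n"
            "2\tдомі\tдім\tNOUN\t_\t_\t0\troot\t_\t_\n\n",
            encoding="utf-8",
        )
        counters: dict = {}
        tokens = list(read_token_table(path, counters))
        assert [t.form for t in tokens] == ["у", "домі"]
        assert counters["multiword_ranges"] == 1


class TestFilterParticipants:
    def test_empty_input(self):
        assert filter_participants([]) == ([], [])

    def test_trimming_rules_and_reasons(self, participant_factory,
                                        narrative_factory):
        records = [
            (participant_factory(doc_id=1, consent=False),
             narrative_factory(doc_id=1, text="текст один")),
            (participant_factory(doc_id=2, age=17),
             narrative_factory(doc_id=2, text="текст два")),
            (participant_factory(doc_id=3),
             narrative_factory(doc_id=3, text="однаковий текст тут")),
            (participant_factory(doc_id=4),
             narrative_factory(doc_id=4, text="Однаковий  текст тут")),
            (participant_factory(doc_id=5),
             narrative_factory(doc_id=5, text="цілком інша розповідь")),
        ]
        retained, log = filter_participants(records)
        assert [r.doc_id for r, _ in retained] == [3, 5]
        assert {e.reason for e in log} == {"consent", "underage", "duplicate"}
        assert len(retained) + len(log) == len(records)

    def test_consent_outranks_other_reasons(self, participant_factory,
                                            narrative_factory):
        records = [(participant_factory(doc_id=1, consent=False, age=15),
                    narrative_factory(doc_id=1))]
        _, log = filter_participants(records)
        assert [e.reason for e in log] == ["consent"]

    @pytest.mark.parametrize("age", [None, 11, 121])
    def test_age_sanity_band(self, age, participant_factory,
                             narrative_factory):
        _, log = filter_participants(
            [(participant_factory(doc_id=1, age=age),
              narrative_factory(doc_id=1))]
        )
        assert [e.reason for e in log] == ["invalid-age"]

    def test_near_duplicate_detection_is_configurable(self, participant_factory,
                                                      narrative_factory):
        base = ("ранок почався з сирени і ми побігли в укриття "
                "разом з дітьми і сусідами з нашого будинку") * 3
        variant = base.replace("сусідами", "котами", 1)
        records = [
            (participant_factory(doc_id=1), narrative_factory(doc_id=1, text=base)),
            (participant_factory(doc_id=2),
             narrative_factory(doc_id=2, text=variant)),
        ]
        retained, log = filter_participants(records)
        assert [e.reason for e in log] == ["duplicate"]
        retained_off, log_off = filter_participants(
            records, near_duplicate_threshold=None
        )
        assert len(retained_off) == 2 and not log_off

    def test_filtering_is_idempotent(self, participant_factory,
                                     narrative_factory):
        records = [
            (participant_factory(doc_id=1, consent=False),
             narrative_factory(doc_id=1)),
            (participant_factory(doc_id=2),
             narrative_factory(doc_id=2, text="щось своє")),
            (participant_factory(doc_id=3),
             narrative_factory(doc_id=3, text="інше зовсім")),
        ]
        retained, _ = filter_participants(records)
        again, log_again = filter_participants(retained)
        assert again == retained and log_again == []

    def test_exclusion_log_json_lines(self, tmp_path, participant_factory,
                                      narrative_factory):
        _, log = filter_participants(
            [(participant_factory(doc_id=9, consent=False),
              narrative_factory(doc_id=9))]
        )
        path = tmp_path / "exclusions.jsonl"
        write_exclusion_log(log, path)
        lines = path.read_text(encoding="utf-8").splitlines()
        assert json.loads(lines[0]) == {
            "doc_id": 9, "reason": "consent", "detail": "",
        }


class TestSummarizeCorpus:
    def test_hand_arithmetic_lengths(self, participant_factory,
                                     narrative_factory):
        narratives = [
            narrative_factory(doc_id=i, text=" ".join(["слово"] * n))
            for i, n in enumerate([2, 4, 6], start=1)
        ]
        records = [participant_factory(doc_id=i) for i in (1, 2, 3)]
        summary = summarize_corpus(records, narratives, [], set())
        assert summary.length_mean == 4.0
        assert summary.length_sd == 2.0  # sample SD, n-1 denominator
        assert (summary.length_min, summary.length_max) == (2, 6)
        assert not summary.length_sd_degenerate

    def test_single_narrative_sd_convention(self, participant_factory,
                                            narrative_factory):
        summary = summarize_corpus(
            [participant_factory()], [narrative_factory(text="一 two three")],
            [], set(),
        )
        assert summary.length_sd == 0.0
        assert summary.length_sd_degenerate

    def test_token_counts_sum_over_narratives(self, participant_factory,
                                              narrative_factory,
                                              token_factory):
        per_doc = {1: 3, 2: 5}
        tokens = [
            token_factory(doc_id=doc, token_index=i + 1, form=f"w{doc}x{i}")
            for doc, n in per_doc.items() for i in range(n)
        ]
        summary = summarize_corpus(
            [participant_factory(doc_id=d) for d in per_doc],
            [narrative_factory(doc_id=d, text="x") for d in per_doc],
            tokens, set(),
        )
        assert summary.n_tokens == sum(per_doc.values())

    def test_stopword_sensitive_counts(self, participant_factory,
                                       narrative_factory, token_factory):
        tokens = [
            token_factory(token_index=1, form="війна", upos="NOUN"),
            token_factory(token_index=2, form="у", upos="ADP"),
            token_factory(token_index=3, form="місті", lemma="місто",
                          upos="NOUN"),
            token_factory(token_index=4, form=".", upos="PUNCT"),
        ]
        summary = summarize_corpus(
            [participant_factory()], [narrative_factory()], tokens,
            {"місто"},
        )
        assert summary.n_tokens == 4
        assert summary.n_tokens_no_stopwords == 1  # ADP, PUNCT, stopword out
        assert summary.n_lemmas == 4
        assert summary.n_lemmas_no_stopwords == 1

    def test_psychometrics_over_completers_only(self, participant_factory,
                                                narrative_factory):
        records = [
            participant_factory(doc_id=1, pcl5_total=20, miss_total=None),
            participant_factory(doc_id=2, pcl5_total=60, miss_total=50),
            participant_factory(doc_id=3, pcl5_total=None, miss_total=None),
        ]
        summary = summarize_corpus(
            records, [narrative_factory(doc_id=i) for i in (1, 2, 3)],
            [], set(),
        )
        assert summary.pcl5.n == 2 and summary.pcl5.mean == 40.0
        assert summary.miss.n == 1 and summary.miss.sd == 0.0
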