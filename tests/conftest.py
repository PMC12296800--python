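"""Shared factories for corpus records used across the test modules."""

from __future__ import annotations

import datetime as dt

import pytest

from lexkey import Narrative, ParticipantRecord, TokenRecord


def _participant(doc_id: int = 1, **overrides) -> ParticipantRecord:
    fields = dict(
        doc_id=doc_id,
        age=30,
        gender="woman",
        marital_status="married",
        education="bachelor",
        region="Волинська",
        occupation_status="never-occupied",
        displaced=False,
        trauma_history="none",
        submission_date=dt.date(2022, 6, 1),
        pcl5_total=40,
        miss_total=45,
        consent=True,
    )
    fields.update(overrides)
    return ParticipantRecord(**fields)


def _narrative(doc_id: int = 1, text: str = "страх і надія", **overrides) -> Narrative:
    fields = dict(
        doc_id=doc_id,
        text_original=text,
        text_translation=None,
        original_language="uk",
    )
    fields.update(overrides)
    return Narrative(**fields)


def _token(
    doc_id: int = 1,
    sentence_index: int = 1,
    token_index: int = 1,
    form: str = "війна",
    lemma: str | None = None,
    upos: str = "NOUN",
    **overrides,
) -> TokenRecord:
    fields = dict(
        doc_id=doc_id,
        paragraph_index=1,
        sentence_index=sentence_index,
        sentence_text="",
        token_index=token_index,
        form=form,
        lemma=form if lemma is None else lemma,
        upos=upos,
        morph="_",
        dep_relation="root" if token_index == 1 else "dep",
        head_index=0 if token_index == 1 else 1,
    )
    fields.update(overrides)
    return TokenRecord(**fields)


@pytest.fixture
def participant_factory():
    return _participant


@pytest.fixture
def narrative_factory():
    return _narrative


@pytest.fixture
def token_factory():
    return _token
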