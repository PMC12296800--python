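"""Read, validate, filter and write the two release formats of a testimony corpus.

A corpus release has two linked tables:

* a *narrative-level* CSV — one row per respondent, carrying demographics,
  displacement/occupation status, collective-trauma history, two psychometric
  totals (PCL-5, range 0–80; MISS, range 10–100), a submission date, and the
  narrative text (original plus optional translation);
* a *token-level* CoNLL-U file — one row per token with lemma, universal POS
  tag, morphological features and a dependency edge, organized into
  ``# newdoc`` / ``# newpar`` / ``# sent_id`` blocks.

The two formats are linked by the document ordinal (``doc7`` <-> ``7``); the
reader accepts either spelling.  This module also implements the sample
trimming rules (consent, age validity, adulthood, duplicate narratives) and a
descriptive summary of the corpus and sample.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import json
import logging
import re
from collections import Counter
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConlluParseError, RowValidationError, SchemaError
from .textnorm import (
    DEFAULT_CLOSED_CLASS_UPOS,
    char_ngrams,
    is_function_token,
    jaccard,
    normalize_lemma,
    normalize_text_for_dedup,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

GENDER_LEVELS = ("man", "woman", "other")
MARITAL_LEVELS = ("single", "married", "in-a-relationship")
EDUCATION_LEVELS = ("secondary", "college", "bachelor", "master-or-phd")
OCCUPATION_LEVELS = ("never-occupied", "occupied", "de-occupied")
TRAUMA_LEVELS = ("holocaust", "holodomor", "none", "other")

PCL5_RANGE = (0, 80)
MISS_RANGE = (10, 100)


@dataclass
class ParticipantRecord:
    """One respondent's demographics, status flags and psychometric totals."""

    doc_id: int
    age: int | None
    gender: str
    marital_status: str
    education: str
    region: str
    occupation_status: str
    displaced: bool | None
    trauma_history: str
    submission_date: _dt.date | None
    pcl5_total: int | None
    miss_total: int | None
    consent: bool
    warnings: tuple[str, ...] = ()


@dataclass
class Narrative:
    """The text of one narrative, original and (optionally) translated."""

    doc_id: int
    text_original: str
    text_translation: str | None = None
    original_language: str | None = None  # "uk" or "ru" when known


@dataclass
class TokenRecord:
    """One token of one narrative in the word-level release format."""

    doc_id: int
    paragraph_index: int
    sentence_index: int
    sentence_text: str
    token_index: int
    form: str
    lemma: str
    upos: str
    morph: str
    dep_relation: str
    head_index: int


# ---------------------------------------------------------------------------
# Categorical canonicalization (editable configuration)
# ---------------------------------------------------------------------------

def _level_map(levels: Sequence[str], extra: dict[str, str]) -> dict[str, str]:
    out = {lvl: lvl for lvl in levels}
    out.update(extra)
    return out


#: Default canonicalization tables: raw (case-folded) value -> canonical level.
#: Pass a modified copy to ``TableDialect`` to extend them.
DEFAULT_CATEGORY_MAPS: dict[str, dict[str, str]] = {
    "gender": _level_map(
        GENDER_LEVELS,
        {"male": "man", "чоловік": "man", "female": "woman", "жінка": "woman",
         "інше": "other"},
    ),
    "marital_status": _level_map(
        MARITAL_LEVELS,
        {"in a relationship": "in-a-relationship",
         "неодружений": "single", "неодружена": "single",
         "одружений": "married", "одружена": "married",
         "у стосунках": "in-a-relationship"},
    ),
    "education": _level_map(
        EDUCATION_LEVELS,
        {"master or phd": "master-or-phd", "master": "master-or-phd",
         "phd": "master-or-phd", "higher": "master-or-phd"},
    ),
    "occupation_status": _level_map(
        OCCUPATION_LEVELS,
        {"never occupied": "never-occupied", "not occupied": "never-occupied",
         "occupied at the time of writing": "occupied",
         "de-occupied at the time of writing": "de-occupied",
         "deoccupied": "de-occupied",
         "previously occupied but liberated": "de-occupied"},
    ),
    "trauma_history": _level_map(
        TRAUMA_LEVELS,
        {"no": "none", "немає": "none", "голодомор": "holodomor",
         "голокост": "holocaust"},
    ),
}

NARRATIVE_COLUMNS = (
    "doc_id", "age", "gender", "marital_status", "education", "region",
    "occupation_status", "displaced", "trauma_history", "submission_date",
    "pcl5_total", "miss_total", "consent", "text_original",
    "text_translation", "original_language",
)

_TRUE_STRINGS = frozenset({"true", "yes", "y", "1", "так"})
_FALSE_STRINGS = frozenset({"false", "no", "n", "0", "ні"})


@dataclass
class TableDialect:
    """Dialect of the narrative-level table.

    UTF-8, comma-separated, quoted fields and a header row by default; the
    delimiter and the categorical canonicalization tables are configurable.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    category_maps: dict[str, dict[str, str]] = field(
        default_factory=lambda: DEFAULT_CATEGORY_MAPS
    )


def parse_doc_id(raw: str) -> int:
    """Parse a document ordinal: ``doc7`` or ``7`` -> 7 (must be positive)."""
    text = raw.strip()
    m = re.fullmatch(r"(?:doc)?(\d+)", text, flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"not a document ordinal: {raw!r}")
    value = int(m.group(1))
    if value < 1:
        raise ValueError(f"document ordinal must be positive: {raw!r}")
    return value


def _parse_bool(raw: str, column: str) -> bool | None:
    text = raw.strip().casefold()
    if not text:
        return None
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"not a boolean in column {column}: {raw!r}")


def _parse_optional_int(raw: str, column: str) -> int | None:
    text = raw.strip()
    if not text:
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"not an integer in column {column}: {raw!r}") from exc


def _canonical(
    raw: str, column: str, maps: dict[str, dict[str, str]], warnings: list[str]
) -> str:
    text = raw.strip()
    mapped = maps.get(column, {}).get(text.casefold())
    if mapped is None and text:
        warnings.append(f"unknown {column} value: {text!r}")
        return text
    return mapped if mapped is not None else text


# ---------------------------------------------------------------------------
# Narrative-level CSV
# ---------------------------------------------------------------------------

def read_narrative_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    quarantine: list[RowValidationError] | None = None,
) -> list[tuple[ParticipantRecord, Narrative]]:
    """Read the narrative-level CSV into (participant, narrative) pairs.

    Rows whose age or psychometric totals cannot be parsed, or whose totals
    fall outside the instruments' score ranges, are quarantined: skipped and
    collected into *quarantine* (when a list is supplied) rather than raised,
    so one bad row never aborts an ingest.  A missing required column raises
    :class:`SchemaError` naming the column.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    pairs: list[tuple[ParticipantRecord, Narrative]] = []
    with path.open(newline="", encoding=dialect.encoding) as handle:
        reader = csv.DictReader(handle, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [c for c in NARRATIVE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for row_number, row in enumerate(reader, start=2):
            try:
                pairs.append(_parse_narrative_row(row, dialect))
            except (ValueError, KeyError) as exc:
                err = RowValidationError(row_number, str(exc))
                logger.warning("quarantined %s", err)
                if quarantine is not None:
                    quarantine.append(err)
    return pairs


def _parse_narrative_row(
    row: dict[str, str], dialect: TableDialect
) -> tuple[ParticipantRecord, Narrative]:
    warnings: list[str] = []
    doc_id = parse_doc_id(row["doc_id"])
    age = _parse_optional_int(row["age"], "age")

    pcl5 = _parse_optional_int(row["pcl5_total"], "pcl5_total")
    if pcl5 is not None and not PCL5_RANGE[0] <= pcl5 <= PCL5_RANGE[1]:
        raise ValueError(f"pcl5_total {pcl5} outside range {PCL5_RANGE}")
    miss = _parse_optional_int(row["miss_total"], "miss_total")
    if miss is not None and not MISS_RANGE[0] <= miss <= MISS_RANGE[1]:
        raise ValueError(f"miss_total {miss} outside range {MISS_RANGE}")

    date_text = row["submission_date"].strip()
    submission_date: _dt.date | None = None
    if date_text:
        try:
            submission_date = _dt.date.fromisoformat(date_text)
        except ValueError:
            warnings.append(f"unparseable submission_date: {date_text!r}")

    maps = dialect.category_maps
    record = ParticipantRecord(
        doc_id=doc_id,
        age=age,
        gender=_canonical(row["gender"], "gender", maps, warnings),
        marital_status=_canonical(
            row["marital_status"], "marital_status", maps, warnings
        ),
        education=_canonical(row["education"], "education", maps, warnings),
        region=row["region"].strip(),
        occupation_status=_canonical(
            row["occupation_status"], "occupation_status", maps, warnings
        ),
        displaced=_parse_bool(row["displaced"], "displaced"),
        trauma_history=_canonical(
            row["trauma_history"], "trauma_history", maps, warnings
        ),
        submission_date=submission_date,
        pcl5_total=pcl5,
        miss_total=miss,
        consent=bool(_parse_bool(row["consent"], "consent")),
        warnings=tuple(warnings),
    )
    language = row["original_language"].strip().casefold() or None
    narrative = Narrative(
        doc_id=doc_id,
        text_original=row["text_original"],
        text_translation=row["text_translation"] or None,
        original_language=language,
    )
    return record, narrative


def write_narrative_table(
    pairs: Iterable[tuple[ParticipantRecord, Narrative]],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> None:
    """Write (participant, narrative) pairs back to the narrative-level CSV.

    Round-trips losslessly with :func:`read_narrative_table` on valid records.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with path.open("w", newline="", encoding=dialect.encoding) as handle:
        writer = csv.writer(handle, delimiter=dialect.delimiter,
                            quoting=csv.QUOTE_MINIMAL)
        writer.writerow(NARRATIVE_COLUMNS)
        for record, narrative in pairs:
            if record.doc_id != narrative.doc_id:
                raise ValueError(
                    f"participant doc_id {record.doc_id} does not match "
                    f"narrative doc_id {narrative.doc_id}"
                )
            writer.writerow([
                f"doc{record.doc_id}",
                "" if record.age is None else record.age,
                record.gender,
                record.marital_status,
                record.education,
                record.region,
                record.occupation_status,
                _bool_to_str(record.displaced),
                record.trauma_history,
                "" if record.submission_date is None
                else record.submission_date.isoformat(),
                "" if record.pcl5_total is None else record.pcl5_total,
                "" if record.miss_total is None else record.miss_total,
                _bool_to_str(record.consent),
                narrative.text_original,
                narrative.text_translation or "",
                narrative.original_language or "",
            ])


def _bool_to_str(value: bool | None) -> str:
    if value is None:
        return ""
    return "yes" if value else "no"


# ---------------------------------------------------------------------------
# Token-level CoNLL-U
# ---------------------------------------------------------------------------

def read_token_table(
    path: str | Path,
    counters: dict[str, int] | None = None,
) -> Iterator[TokenRecord]:
    """Stream :class:`TokenRecord` rows from a CoNLL-U token table.

    Document, paragraph and sentence indices are carried by ``# newdoc id``,
    ``# newpar`` and ``# sent_id`` comment lines.  Multiword-token range lines
    (``2-3``) and empty nodes (``1.1``) are skipped; when *counters* is given,
    the number of skipped lines is accumulated under ``"multiword_ranges"``
    and ``"empty_nodes"``.
    """
    path = Path(path)
    doc_id: int | None = None
    paragraph_index = 0
    sentence_index = 0
    sentence_text = ""
    in_sentence = False
    n_tokens_in_sentence = 0

    with path.open(encoding="utf-8") as handle:
        for line_number, raw_line in enumerate(handle, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip():
                in_sentence = False
                continue
            if line.startswith("#"):
                comment = line[1:].strip()
                if comment.startswith("newdoc"):
                    _, _, value = comment.partition("=")
                    try:
                        doc_id = parse_doc_id(value)
                    except ValueError as exc:
                        raise ConlluParseError(line_number, str(exc)) from exc
                    paragraph_index = 0
                    sentence_index = 0
                elif comment.startswith("newpar"):
                    paragraph_index += 1
                elif comment.startswith("sent_id"):
                    pass  # sentence boundary is detected from token id 1
                elif comment.startswith("text"):
                    _, _, value = comment.partition("=")
                    sentence_text = value.strip()
                continue

            fields = line.split("\t")
            if len(fields) != 10:
                raise ConlluParseError(
                    line_number, f"expected 10 columns, found {len(fields)}"
                )
            token_id = fields[0]
            if "-" in token_id:
                if counters is not None:
                    counters["multiword_ranges"] = (
                        counters.get("multiword_ranges", 0) + 1
                    )
                continue
            if "." in token_id:
                if counters is not None:
                    counters["empty_nodes"] = counters.get("empty_nodes", 0) + 1
                continue
            if doc_id is None:
                raise ConlluParseError(
                    line_number, "token line before any '# newdoc id' comment"
                )
            try:
                token_index = int(token_id)
                head_index = 0 if fields[6] == "_" else int(fields[6])
            except ValueError as exc:
                raise ConlluParseError(line_number, str(exc)) from exc

            if token_index == 1 and not in_sentence:
                sentence_index += 1
                in_sentence = True
                n_tokens_in_sentence = 0
            n_tokens_in_sentence += 1
            if token_index != n_tokens_in_sentence:
                raise ConlluParseError(
                    line_number,
                    f"token index {token_index} breaks the 1..n sequence "
                    f"(expected {n_tokens_in_sentence})",
                )

            yield TokenRecord(
                doc_id=doc_id,
                paragraph_index=max(paragraph_index, 1),
                sentence_index=sentence_index,
                sentence_text=sentence_text,
                token_index=token_index,
                form=fields[1],
                lemma=fields[2],
                upos=fields[3],
                morph=fields[5],
                dep_relation=fields[7],
                head_index=head_index,
            )


def write_token_table(tokens: Iterable[TokenRecord], path: str | Path) -> None:
    """Write tokens as CoNLL-U, emitting newdoc/newpar/sent_id/text comments."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        current: tuple[int, int, int] | None = None  # (doc, par, sent)
        current_doc: int | None = None
        current_par: tuple[int, int] | None = None
        for token in tokens:
            key = (token.doc_id, token.paragraph_index, token.sentence_index)
            if key != current:
                if current is not None:
                    handle.write("\n")
                if token.doc_id != current_doc:
                    handle.write(f"# newdoc id = doc{token.doc_id}\n")
                    current_doc = token.doc_id
                    current_par = None
                par_key = (token.doc_id, token.paragraph_index)
                if par_key != current_par:
                    handle.write("# newpar\n")
                    current_par = par_key
                handle.write(
                    f"# sent_id = doc{token.doc_id}.p{token.paragraph_index}"
                    f".s{token.sentence_index}\n"
                )
                handle.write(f"# text = {token.sentence_text}\n")
                current = key
            head = str(token.head_index)
            handle.write(
                "\t".join([
                    str(token.token_index), token.form, token.lemma,
                    token.upos, "_", token.morph or "_", head,
                    token.dep_relation or "_", "_", "_",
                ]) + "\n"
            )
        if current is not None:
            handle.write("\n")


# ---------------------------------------------------------------------------
# Sample trimming
# ---------------------------------------------------------------------------

AGE_SANITY_BAND = (12, 120)
ADULT_AGE = 18

#: Exclusion reasons in the order they are checked for each record.
EXCLUSION_REASONS = ("consent", "invalid-age", "underage", "duplicate")


@dataclass
class Exclusion:
    doc_id: int
    reason: str
    detail: str = ""


def filter_participants(
    records: Sequence[tuple[ParticipantRecord, Narrative]],
    near_duplicate_threshold: float | None = 0.9,
    ngram_size: int = 5,
) -> tuple[list[tuple[ParticipantRecord, Narrative]], list[Exclusion]]:
    """Apply the sample trimming rules; return (retained, exclusion log).

    A record is retained iff, checked in this order, it (1) carries consent,
    (2) has a parseable age inside the sanity band ``[12, 120]``, (3) is an
    adult (age >= 18), and (4) its narrative is not a duplicate of an
    earlier-numbered retained narrative.  Duplicates are exact matches after
    NFC normalization, case folding and whitespace collapse; when
    *near_duplicate_threshold* is not ``None``, narratives whose character
    n-gram Jaccard similarity to an earlier retained narrative reaches the
    threshold are excluded as duplicates too.  Each excluded record gets
    exactly one (primary) reason.
    """
    ordered = sorted(records, key=lambda pair: pair[0].doc_id)
    retained: list[tuple[ParticipantRecord, Narrative]] = []
    exclusions: list[Exclusion] = []
    seen_exact: dict[str, int] = {}
    # (shingle set, size, doc_id) of retained narratives, for the near-dup scan
    seen_shingles: list[tuple[set[str], int, int]] = []

    for record, narrative in ordered:
        if not record.consent:
            exclusions.append(Exclusion(record.doc_id, "consent"))
            continue
        if record.age is None or not (
            AGE_SANITY_BAND[0] <= record.age <= AGE_SANITY_BAND[1]
        ):
            exclusions.append(
                Exclusion(record.doc_id, "invalid-age", f"age={record.age}")
            )
            continue
        if record.age < ADULT_AGE:
            exclusions.append(
                Exclusion(record.doc_id, "underage", f"age={record.age}")
            )
            continue

        canon = normalize_text_for_dedup(narrative.text_original)
        if canon in seen_exact:
            exclusions.append(Exclusion(
                record.doc_id, "duplicate",
                f"exact match of doc{seen_exact[canon]}",
            ))
            continue
        near_of = None
        if near_duplicate_threshold is not None:
            shingles = char_ngrams(narrative.text_original, ngram_size)
            size = len(shingles)
            for other, other_size, other_doc in seen_shingles:
                # Jaccard >= t forces the smaller set to be >= t of the larger.
                if min(size, other_size) < near_duplicate_threshold * max(
                    size, other_size
                ):
                    continue
                if jaccard(shingles, other) >= near_duplicate_threshold:
                    near_of = other_doc
                    break
            if near_of is not None:
                exclusions.append(Exclusion(
                    record.doc_id, "duplicate",
                    f"near-duplicate of doc{near_of} "
                    f"(jaccard>={near_duplicate_threshold})",
                ))
                continue
            seen_shingles.append((shingles, size, record.doc_id))
        seen_exact[canon] = record.doc_id
        retained.append((record, narrative))

    logger.info(
        "filter_participants: %d in, %d retained, %d excluded",
        len(ordered), len(retained), len(exclusions),
    )
    return retained, exclusions


def write_exclusion_log(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    """Write the exclusion log as JSON-lines, one object per excluded record."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for exclusion in exclusions:
            handle.write(json.dumps(dataclasses.asdict(exclusion),
                                    ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

@dataclass
class ScoreSummary:
    n: int
    minimum: int | None
    maximum: int | None
    mean: float | None
    sd: float | None


@dataclass
class DescriptiveSummary:
    """Corpus and sample descriptives in the style of a data-release summary."""

    n_participants: int
    n_tokens: int
    n_tokens_no_stopwords: int
    n_types: int
    n_types_no_stopwords: int
    n_lemmas: int
    n_lemmas_no_stopwords: int
    length_mean: float
    length_sd: float
    length_min: int
    length_max: int
    length_sd_degenerate: bool
    categorical_tabulations: dict[str, dict[str, int]]
    pcl5: ScoreSummary
    miss: ScoreSummary

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sample_sd(values: np.ndarray) -> tuple[float, bool]:
    """Sample SD (n-1 denominator); a single observation reports 0, flagged."""
    if values.size <= 1:
        return 0.0, values.size == 1
    return float(np.std(values, ddof=1)), False


def _score_summary(values: list[int]) -> ScoreSummary:
    if not values:
        return ScoreSummary(0, None, None, None, None)
    arr = np.asarray(values, dtype=float)
    sd, _ = _sample_sd(arr)
    return ScoreSummary(
        n=len(values), minimum=int(arr.min()), maximum=int(arr.max()),
        mean=float(arr.mean()), sd=sd,
    )


def summarize_corpus(
    records: Sequence[ParticipantRecord],
    narratives: Sequence[Narrative],
    tokens: Sequence[TokenRecord],
    stopword_lemmas: set[str] | frozenset[str],
    closed_class_pos: Iterable[str] = DEFAULT_CLOSED_CLASS_UPOS,
) -> DescriptiveSummary:
    """Compute the corpus/sample descriptive summary.

    Token, type and lemma counts are reported both with and without the
    stopword filter (stopword lemma list plus closed-class POS plus
    punctuation).  Narrative length is the whitespace word count of the
    original text; its SD uses the n-1 denominator, with a single narrative
    reported as SD 0 and flagged degenerate.  Psychometric summaries are
    computed over respondents who completed the respective instrument.
    """
    stop = frozenset(stopword_lemmas)
    closed = frozenset(closed_class_pos)

    n_tokens = len(tokens)
    kept = [t for t in tokens
            if not is_function_token(t.upos, t.lemma, stop, closed)]
    types_all = {normalize_lemma(t.form) for t in tokens}
    types_kept = {normalize_lemma(t.form) for t in kept}
    lemmas_all = {normalize_lemma(t.lemma) for t in tokens if t.lemma}
    lemmas_kept = {normalize_lemma(t.lemma) for t in kept if t.lemma}

    lengths = np.asarray(
        [len(n.text_original.split()) for n in narratives], dtype=float
    )
    if lengths.size:
        length_mean = float(lengths.mean())
        length_sd, degenerate = _sample_sd(lengths)
        length_min, length_max = int(lengths.min()), int(lengths.max())
    else:
        length_mean, length_sd, degenerate = 0.0, 0.0, False
        length_min = length_max = 0

    tabulations: dict[str, dict[str, int]] = {}
    for column in ("gender", "marital_status", "education",
                   "occupation_status", "trauma_history"):
        tabulations[column] = dict(Counter(
            getattr(r, column) for r in records
        ))
    tabulations["displaced"] = dict(Counter(
        {True: "yes", False: "no", None: "unknown"}[r.displaced]
        for r in records
    ))

    return DescriptiveSummary(
        n_participants=len(records),
        n_tokens=n_tokens,
        n_tokens_no_stopwords=len(kept),
        n_types=len(types_all),
        n_types_no_stopwords=len(types_kept),
        n_lemmas=len(lemmas_all),
        n_lemmas_no_stopwords=len(lemmas_kept),
        length_mean=length_mean,
        length_sd=length_sd,
        length_min=length_min,
        length_max=length_max,
        length_sd_degenerate=degenerate,
        categorical_tabulations=tabulations,
        pcl5=_score_summary(
            [r.pcl5_total for r in records if r.pcl5_total is not None]
        ),
        miss=_score_summary(
            [r.miss_total for r in records if r.miss_total is not None]
        ),
    )
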