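"""De-identification, stopword removal and lemma frequency tables.

This stage turns token streams into the zero-filled combined lemma table that
the keyness statistic consumes: drop punctuation and function words, count
lemmas per corpus, and merge the target and reference frequency lists over
the union of their vocabularies.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import TokenRecord
from .errors import AmbiguousAliasError
from .textnorm import (
    DEFAULT_CLOSED_CLASS_UPOS,
    is_function_token,
    normalize_lemma,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# De-identification
# ---------------------------------------------------------------------------

_KIND_TAGS = {"person": "NAME", "place": "CITY"}


@dataclass
class Entity:
    """A person or place to de-identify, with the surface forms it takes.

    Alias lists must cover the inflected forms that occur in the text;
    matching is whole-word and case-sensitive.
    """

    entity_id: str
    kind: str  # "person" | "place"
    aliases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_TAGS:
            raise ValueError(f"unknown entity kind: {self.kind!r}")
        if not self.aliases:
            raise ValueError(f"entity {self.entity_id!r} has no aliases")


@dataclass
class Replacement:
    position: int
    alias: str
    entity_id: str
    tag: str


def deidentify(
    text: str, entities: Sequence[Entity]
) -> tuple[str, list[Replacement]]:
    """Replace every alias occurrence with a [NAME]/[CITY] style tag.

    If exactly one distinct entity of a kind occurs in the text its tag is
    unindexed (``[NAME]``); when several occur, tags are indexed ``1..k`` in
    order of first appearance and reused consistently throughout the
    narrative (``[CITY1]``, ``[CITY2]``).  Aliases shared between two
    entities raise :class:`AmbiguousAliasError` listing the collisions.
    """
    if not entities:
        return text, []

    alias_owner: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    for entity in entities:
        for alias in entity.aliases:
            owner = alias_owner.get(alias)
            if owner is not None and owner != entity.entity_id:
                collisions.setdefault(alias, [owner]).append(entity.entity_id)
            else:
                alias_owner[alias] = entity.entity_id
    if collisions:
        raise AmbiguousAliasError(collisions)

    by_id = {e.entity_id: e for e in entities}
    ordered_aliases = sorted(alias_owner, key=len, reverse=True)
    pattern = re.compile(
        r"(?<!\w)(?:" + "|".join(map(re.escape, ordered_aliases)) + r")(?!\w)"
    )

    # Pass 1: order of first appearance per entity, per kind.
    appearance: dict[str, list[str]] = {kind: [] for kind in _KIND_TAGS}
    for match in pattern.finditer(text):
        entity = by_id[alias_owner[match.group(0)]]
        seen = appearance[entity.kind]
        if entity.entity_id not in seen:
            seen.append(entity.entity_id)

    tags: dict[str, str] = {}
    for kind, base in _KIND_TAGS.items():
        present = appearance[kind]
        for index, entity_id in enumerate(present, start=1):
            suffix = "" if len(present) == 1 else str(index)
            tags[entity_id] = f"[{base}{suffix}]"

    replacements: list[Replacement] = []

    def _substitute(match: re.Match[str]) -> str:
        alias = match.group(0)
        entity_id = alias_owner[alias]
        tag = tags[entity_id]
        replacements.append(Replacement(match.start(), alias, entity_id, tag))
        return tag

    return pattern.sub(_substitute, text), replacements


# ---------------------------------------------------------------------------
# Stopwords
# ---------------------------------------------------------------------------

DEFAULT_STOPWORD_PATH = Path(__file__).parent / "data" / "stopwords_uk.txt"


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stopword file: UTF-8, one lemma per line, ``#`` comments."""
    lemmas = set()
    with Path(path).open(encoding="utf-8") as handle:
        for line in handle:
            entry = line.split("#", 1)[0].strip()
            if entry:
                lemmas.add(normalize_lemma(entry))
    return frozenset(lemmas)


def remove_stopwords(
    tokens: Iterable[TokenRecord],
    stopword_lemmas: set[str] | frozenset[str],
    closed_class_pos: Iterable[str] = DEFAULT_CLOSED_CLASS_UPOS,
) -> list[TokenRecord]:
    """Drop punctuation, closed-class POS and listed stopword lemmas.

    Order is preserved; the number of dropped tokens is logged.  Applying the
    filter twice is a no-op (idempotent).
    """
    stop = frozenset(stopword_lemmas)
    closed = frozenset(closed_class_pos)
    all_tokens = list(tokens)
    kept = [
        t for t in all_tokens
        if not is_function_token(t.upos, t.lemma, stop, closed)
    ]
    logger.info("remove_stopwords: dropped %d of %d tokens",
                len(all_tokens) - len(kept), len(all_tokens))
    return kept


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Lemma -> count map for one corpus plus its total token count.

    Counts are keyed by NFC-normalized, case-folded lemmas; a lemma that is
    absent has count zero (no explicit zero entries are stored), and
    ``total_tokens`` always equals the sum of the counts.
    """

    corpus_label: str
    counts: dict[str, int]
    total_tokens: int
    empty_lemma_fallbacks: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("frequency table entries must be positive")
        if self.total_tokens != sum(self.counts.values()):
            raise ValueError(
                "total_tokens must equal the sum of the counts "
                f"({self.total_tokens} != {sum(self.counts.values())})"
            )

    @property
    def n_lemmas(self) -> int:
        return len(self.counts)


def count_lemmas(
    tokens: Iterable[TokenRecord], label: str
) -> FrequencyTable:
    """Count normalized lemmas over a token stream.

    A token with an empty lemma is counted under its case-folded surface form
    instead, and the number of such fallbacks is recorded on the table.
    """
    counter: Counter[str] = Counter()
    total = 0
    fallbacks = 0
    for token in tokens:
        total += 1
        if token.lemma:
            counter[normalize_lemma(token.lemma)] += 1
        else:
            fallbacks += 1
            counter[normalize_lemma(token.form)] += 1
    if fallbacks:
        logger.warning("count_lemmas(%s): %d empty lemmas counted by surface "
                       "form", label, fallbacks)
    return FrequencyTable(
        corpus_label=label, counts=dict(counter), total_tokens=total,
        empty_lemma_fallbacks=fallbacks,
    )


def read_frequency_list(path: str | Path, label: str) -> FrequencyTable:
    """Read a two-column (lemma TAB count) frequency-list export.

    The format emulates what corpus query interfaces provide for reference
    corpora: one lemma per line, UTF-8, tab-separated, ``#`` comments and
    blank lines ignored.  Repeated lemmas (e.g. case variants that normalize
    to the same key) are summed.
    """
    counter: Counter[str] = Counter()
    with Path(path).open(encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            entry = line.rstrip("\n")
            if not entry.strip() or entry.lstrip().startswith("#"):
                continue
            parts = entry.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{line_number}: expected 'lemma<TAB>count', "
                    f"got {entry!r}"
                )
            lemma, count_text = parts
            count = int(count_text)
            if count < 0:
                raise ValueError(f"{path}:{line_number}: negative count")
            if count > 0:
                counter[normalize_lemma(lemma)] += count
    counts = dict(counter)
    return FrequencyTable(
        corpus_label=label, counts=counts, total_tokens=sum(counts.values())
    )


def write_frequency_list(table: FrequencyTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for lemma in sorted(table.counts,
                            key=lambda w: (-table.counts[w], w)):
            handle.write(f"{lemma}\t{table.counts[lemma]}\n")


def filter_frequency_table(
    table: FrequencyTable, stopword_lemmas: set[str] | frozenset[str]
) -> FrequencyTable:
    """Drop stopword lemmas from a frequency list (lemma-level only).

    Used for reference lists that arrive without POS information, so only the
    lemma list — not the closed-class POS rule — can be applied.
    """
    stop = frozenset(stopword_lemmas)
    counts = {w: c for w, c in table.counts.items() if w not in stop}
    return FrequencyTable(
        corpus_label=table.corpus_label, counts=counts,
        total_tokens=sum(counts.values()),
    )


# ---------------------------------------------------------------------------
# Combined table
# ---------------------------------------------------------------------------

@dataclass
class CombinedLemmaTable:
    """Zero-filled union of a target and a reference frequency table.

    Rows cover exactly the union of the two lemma sets, ordered by descending
    pooled count with alphabetical tie-break.  The informative Dirichlet
    prior is read off this table: ``alpha_w`` (per-lemma pseudo-count) is the
    pooled count of the lemma in both corpora, and ``alpha_0`` is the pooled
    total token count.
    """

    lemmas: tuple[str, ...]
    y_target: np.ndarray  # int64, counts in the target corpus
    y_reference: np.ndarray  # int64, counts in the reference corpus
    n_target: int
    n_reference: int
    target_label: str = "target"
    reference_label: str = "reference"

    @property
    def n_rows(self) -> int:
        return len(self.lemmas)

    @property
    def alpha_w(self) -> np.ndarray:
        return self.y_target + self.y_reference

    @property
    def alpha_0(self) -> int:
        return self.n_target + self.n_reference

    def validate(self) -> None:
        if len(self.lemmas) != len(self.y_target) or len(self.lemmas) != len(
            self.y_reference
        ):
            raise ValueError("column lengths differ")
        if np.any(self.alpha_w < 1):
            raise ValueError("every row must have pooled count >= 1")
        if int(self.alpha_w.sum()) != self.alpha_0:
            raise ValueError("alpha_0 must equal the sum of alpha_w")

    def swapped(self) -> "CombinedLemmaTable":
        """The same table with the corpus roles exchanged."""
        return dataclasses.replace(
            self,
            y_target=self.y_reference.copy(),
            y_reference=self.y_target.copy(),
            n_target=self.n_reference,
            n_reference=self.n_target,
            target_label=self.reference_label,
            reference_label=self.target_label,
        )


def merge_tables(
    target: FrequencyTable, reference: FrequencyTable
) -> CombinedLemmaTable:
    """Merge two frequency tables over the union of their lemma sets.

    A lemma missing from one corpus is zero-filled on that side.  Raises
    ``ValueError`` when either table is empty (the keyness statistic is
    undefined without both corpora).
    """
    if not target.counts or not reference.counts:
        raise ValueError("cannot merge: both frequency tables must be non-empty")
    union = set(target.counts) | set(reference.counts)
    ordered = sorted(
        union,
        key=lambda w: (
            -(target.counts.get(w, 0) + reference.counts.get(w, 0)), w
        ),
    )
    y_t = np.fromiter(
        (target.counts.get(w, 0) for w in ordered), dtype=np.int64,
        count=len(ordered),
    )
    y_r = np.fromiter(
        (reference.counts.get(w, 0) for w in ordered), dtype=np.int64,
        count=len(ordered),
    )
    table = CombinedLemmaTable(
        lemmas=tuple(ordered),
        y_target=y_t,
        y_reference=y_r,
        n_target=target.total_tokens,
        n_reference=reference.total_tokens,
        target_label=target.corpus_label,
        reference_label=reference.corpus_label,
    )
    table.validate()
    return table
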