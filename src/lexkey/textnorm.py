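"""Unicode normalization helpers shared by the I/O and preprocessing layers.

All lemma/type counting in the pipeline operates on NFC-normalized,
case-folded strings with Ukrainian apostrophe variants unified, so that the
same word is never split across spelling variants when two frequency lists
are merged.
"""

from __future__ import annotations

import unicodedata
from collections.abc import Iterable

#: Apostrophe look-alikes folded to U+02BC MODIFIER LETTER APOSTROPHE, the
#: codepoint Ukrainian orthography standards recommend (м'ята == м’ята).
_APOSTROPHES = "'’ʼ‘`´"
_APOSTROPHE_TABLE = {ord(ch): "ʼ" for ch in _APOSTROPHES}

#: Universal POS tags treated as closed-class (function) words by default.
#: PUNCT is always removed regardless of this set.
DEFAULT_CLOSED_CLASS_UPOS = frozenset(
    {"ADP", "PRON", "CCONJ", "SCONJ", "PART", "DET", "AUX"}
)


def normalize_lemma(text: str) -> str:
    """NFC-normalize, unify apostrophes and case-fold a lemma or word form."""
    return (
        unicodedata.normalize("NFC", text).translate(_APOSTROPHE_TABLE).casefold()
    )


def normalize_text_for_dedup(text: str) -> str:
    """Canonical form used for exact-duplicate narrative detection.

    NFC + case-fold + collapse of all whitespace runs to single spaces.
    """
    folded = unicodedata.normalize("NFC", text).casefold()
    return " ".join(folded.split())


def char_ngrams(text: str, n: int = 5) -> set[str]:
    """Set of character n-gram shingles of the dedup-normalized text."""
    canon = normalize_text_for_dedup(text)
    if len(canon) <= n:
        return {canon} if canon else set()
    return {canon[i : i + n] for i in range(len(canon) - n + 1)}


def jaccard(a: set[str], b: set[str]) -> float:
    """Jaccard similarity of two shingle sets; 0.0 when both are empty."""
    if not a and not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def is_function_token(
    upos: str,
    lemma: str,
    stopword_lemmas: frozenset[str] | set[str],
    closed_class_pos: Iterable[str] = DEFAULT_CLOSED_CLASS_UPOS,
) -> bool:
    """True when a token should be dropped before frequency analysis.

    A token is dropped iff its POS is punctuation, or its POS is in the
    closed-class set, or its normalized lemma is on the stopword list.
    """
    if upos == "PUNCT":
        return True
    if upos in closed_class_pos:
        return True
    return normalize_lemma(lemma) in stopword_lemmas
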