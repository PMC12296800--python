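"""Seeded synthetic corpora with known statistical structure.

Three generators cover the testing needs of the pipeline:

* :func:`generate_corpus_pair` — a target/reference pair of lemma frequency
  tables drawn multinomially from a Zipf–Mandelbrot base distribution, with
  optional planted log-odds enrichments on designated lemmas and a truth
  record holding the exact post-normalization probabilities;
* :func:`generate_null_replicates` — independent null pairs (no enrichment)
  merged into combined tables, for family-wise error rate studies;
* :func:`generate_narratives` — narrative-level CSV and token-level CoNLL-U
  fixture files whose metadata marginals and length distribution emulate a
  wartime testimony sample (43% displaced, narrative length mean 333 /
  SD 237 words, PCL-5 mean 41 / SD 19, ...).

Everything is a pure function of its seed: the same seed replays the same
bytes.  The narrative "text" is a lemma sequence sampled from the lexicon —
a structural fixture, not grammatical language.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from collections.abc import Iterator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    Narrative,
    ParticipantRecord,
    TokenRecord,
    write_narrative_table,
    write_token_table,
)
from .preprocess import CombinedLemmaTable, FrequencyTable, merge_tables

# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


def generate_lexicon(
    vocab_size: int,
    zipf_exponent: float = 1.1,
    zipf_offset: float = 2.7,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Zipf–Mandelbrot base distribution p_r ∝ 1/(r+q)^s over ranks 1..V.

    Returns deterministic lemma labels (``w00001`` is the most frequent rank)
    and the normalized probability vector.  ``s = 0`` gives the uniform
    distribution.
    """
    if vocab_size < 2:
        raise ValueError(f"vocab_size must be >= 2, got {vocab_size}")
    if zipf_exponent < 0:
        raise ValueError(f"zipf_exponent must be >= 0, got {zipf_exponent}")
    if zipf_offset < 0:
        raise ValueError(f"zipf_offset must be >= 0, got {zipf_offset}")
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    weights = (ranks + zipf_offset) ** (-zipf_exponent)
    probs = weights / weights.sum()
    width = max(5, len(str(vocab_size)))
    labels = [f"w{r:0{width}d}" for r in range(1, vocab_size + 1)]
    return labels, probs


# ---------------------------------------------------------------------------
# Corpus pairs with planted effects
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic target/reference corpus pair."""

    vocab_size: int = 10_000
    zipf_exponent: float = 1.1
    zipf_offset: float = 2.7
    n_target: int = 100_000
    n_reference: int = 100_000
    #: lemma label -> planted log-odds shift (natural-log units)
    effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target < 1 or self.n_reference < 1:
            raise ValueError("token totals must be >= 1")


@dataclass
class TruthRecord:
    """Exact generating quantities of one synthetic pair.

    ``log_odds_shift`` is the population log-odds difference between the
    tilted (target) and base (reference) probabilities of each lemma.
    ``delta_loridp`` is the large-sample value of the smoothed log-odds
    statistic — expected counts substituted into its formula.  The prior's
    pseudo-counts grow with the corpora, so the statistic converges to this
    shrunken value, not to ``log_odds_shift``; recovery checks must compare
    against ``delta_loridp``.
    """

    labels: list[str]
    p_reference: np.ndarray
    p_target: np.ndarray
    log_odds_shift: np.ndarray
    delta_loridp: np.ndarray
    effects: dict[str, float]

    def index_of(self, lemma: str) -> int:
        return self.labels.index(lemma)

    def to_json_dict(self) -> dict:
        return {
            "effects": self.effects,
            "lemmas": {
                lemma: {
                    "p_reference": float(self.p_reference[i]),
                    "p_target": float(self.p_target[i]),
                    "log_odds_shift": float(self.log_odds_shift[i]),
                    "delta_loridp": float(self.delta_loridp[i]),
                }
                for lemma, i in (
                    (lemma, self.index_of(lemma)) for lemma in self.effects
                )
            },
        }


def implied_loridp_delta(
    p_target: np.ndarray,
    p_reference: np.ndarray,
    n_target: int,
    n_reference: int,
) -> np.ndarray:
    """Large-sample value of the smoothed log-odds statistic.

    Substitutes expected counts (n * p) into the delta formula, with the
    prior read off the pooled expected counts exactly as the estimator
    reads it off the pooled observed counts.
    """
    y_t = n_target * p_target
    y_r = n_reference * p_reference
    alpha_w = y_t + y_r
    alpha_0 = n_target + n_reference
    num_t = y_t + alpha_w
    num_r = y_r + alpha_w
    return np.log(num_t / (n_target + alpha_0 - num_t)) - np.log(
        num_r / (n_reference + alpha_0 - num_r)
    )


def generate_corpus_pair(
    spec: SyntheticSpec,
) -> tuple[FrequencyTable, FrequencyTable, TruthRecord]:
    """Draw one synthetic target/reference pair under *spec*.

    Reference counts are multinomial from the base Zipf–Mandelbrot
    distribution; target counts are multinomial from the base tilted by
    ``exp(shift)`` on each effect lemma and renormalized.  The truth record
    stores the exact tilted probabilities, so downstream checks never rely
    on the small-probability approximation ``shift ≈ delta``.
    """
    labels, base = generate_lexicon(
        spec.vocab_size, spec.zipf_exponent, spec.zipf_offset, spec.seed
    )
    index = {label: i for i, label in enumerate(labels)}
    unknown = [w for w in spec.effects if w not in index]
    if unknown:
        raise ValueError(f"effect lemmas outside the vocabulary: {unknown}")

    if spec.effects:
        shift = np.zeros(spec.vocab_size)
        for lemma, value in spec.effects.items():
            shift[index[lemma]] = value
        tilted = base * np.exp(shift)
        tilted /= tilted.sum()
    else:
        tilted = base  # null pair: exactly the base distribution

    rng = np.random.default_rng(spec.seed)
    counts_target = rng.multinomial(spec.n_target, tilted)
    counts_reference = rng.multinomial(spec.n_reference, base)

    # Exact population log-odds difference of tilted vs base probabilities.
    logit_tilted = np.log(tilted) - np.log1p(-tilted)
    logit_base = np.log(base) - np.log1p(-base)
    log_odds_shift = logit_tilted - logit_base
    truth = TruthRecord(
        labels=labels,
        p_reference=base,
        p_target=tilted,
        log_odds_shift=log_odds_shift,
        delta_loridp=implied_loridp_delta(
            tilted, base, spec.n_target, spec.n_reference
        ),
        effects=dict(spec.effects),
    )
    target = _table_from_counts(labels, counts_target, "synthetic-target")
    reference = _table_from_counts(
        labels, counts_reference, "synthetic-reference"
    )
    return target, reference, truth


def _table_from_counts(
    labels: list[str], counts: np.ndarray, label: str
) -> FrequencyTable:
    nonzero = {
        labels[i]: int(c) for i, c in enumerate(counts) if c > 0
    }
    return FrequencyTable(
        corpus_label=label, counts=nonzero, total_tokens=int(counts.sum())
    )


def generate_null_replicates(
    spec: SyntheticSpec, replicates: int
) -> Iterator[CombinedLemmaTable]:
    """Independent null pairs (effects stripped) merged into combined tables.

    Replicate seeds are derived deterministically from the master seed via
    ``numpy.random.SeedSequence`` spawning.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    null_spec = dataclasses.replace(spec, effects={})
    children = np.random.SeedSequence(spec.seed).spawn(replicates)
    for child in children:
        child_seed = int(child.generate_state(1)[0]) % (2**31)
        rep_spec = dataclasses.replace(null_spec, seed=child_seed)
        target, reference, _ = generate_corpus_pair(rep_spec)
        yield merge_tables(target, reference)


# ---------------------------------------------------------------------------
# Narrative/metadata fixture files
# ---------------------------------------------------------------------------

#: Emulated sample marginals (category -> weight); weights are the published
#: sample tallies and are normalized at sampling time.
DEFAULT_MARGINALS: dict[str, dict] = {
    "gender": {"man": 220, "woman": 1152, "other": 0},
    "marital_status": {"single": 1022, "married": 961, "in-a-relationship": 20},
    "education": {
        "secondary": 439, "college": 564, "bachelor": 314,
        "master-or-phd": 686,
    },
    "occupation_status": {
        "never-occupied": 703, "occupied": 976, "de-occupied": 324,
    },
    "trauma_history": {
        "holocaust": 22, "holodomor": 301, "none": 1220, "other": 470,
    },
    "displaced": {True: 858, False: 1146},
}

#: Fraction of respondents who completed both questionnaires (1225 of 2003).
DEFAULT_COMPLETION_RATE = 1225 / 2003
#: Fraction of narratives originally written in Russian (12 of 2003).
DEFAULT_RUSSIAN_RATE = 12 / 2003

_REGIONS = (
    "Волинська", "Київська", "Львівська", "Харківська", "Одеська",
    "Донецька", "Луганська", "Чернігівська", "Запорізька", "Херсонська",
    "Полтавська", "Вінницька",
)

_POS_LEVELS = ("NOUN", "VERB", "ADJ", "ADV", "ADP", "PART")
_POS_PROBS = (0.40, 0.25, 0.12, 0.08, 0.08, 0.07)

_DATE_START = _dt.date(2022, 5, 17)
_DATE_END = _dt.date(2024, 1, 14)


@dataclass
class GeneratedCorpus:
    narratives_path: Path
    tokens_path: Path
    truth_path: Path
    n_participants: int


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_narratives(
    n_participants: int,
    out_dir: str | Path,
    marginals: dict[str, dict] | None = None,
    length_mean: float = 333.0,
    length_sd: float = 237.0,
    completion_rate: float = DEFAULT_COMPLETION_RATE,
    lexicon: tuple[list[str], np.ndarray] | None = None,
    seed: int = 0,
) -> GeneratedCorpus:
    """Emit both release formats plus a truth-record JSON.

    Narrative lengths are log-normal, moment-matched to the requested
    mean/SD and truncated at one word.  Each "word" of a narrative is a
    lemma sampled from the lexicon and listed in the token table with itself
    as lemma, a sampled POS tag and a flat dependency (first token is the
    root); sentences close with a period token.  Metadata fields are sampled
    independently from the marginals.  All emitted records are valid: adult
    ages, consent given, scores in range.
    """
    marginals = marginals or DEFAULT_MARGINALS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if lexicon is None:
        lexicon = generate_lexicon(2000, seed=seed)
    labels, probs = lexicon
    label_array = np.asarray(labels, dtype=object)

    mu, sigma = _lognormal_params(length_mean, length_sd)
    lengths = np.maximum(
        1, np.rint(rng.lognormal(mu, sigma, size=n_participants)).astype(int)
    )
    age_mu, age_sigma = math.log(32.0), 0.35
    ages = np.clip(
        np.rint(rng.lognormal(age_mu, age_sigma, size=n_participants)),
        18, 86,
    ).astype(int)

    def _sample_categorical(column: str) -> np.ndarray:
        weights = marginals[column]
        levels = list(weights)
        p = np.asarray([weights[level] for level in levels], dtype=float)
        p /= p.sum()
        return rng.choice(len(levels), size=n_participants, p=p), levels

    categorical: dict[str, list] = {}
    for column in ("gender", "marital_status", "education",
                   "occupation_status", "trauma_history", "displaced"):
        indices, levels = _sample_categorical(column)
        categorical[column] = [levels[i] for i in indices]

    completed = rng.random(n_participants) < completion_rate
    pcl5 = np.clip(np.rint(rng.normal(41, 19, n_participants)), 0, 80)
    miss = np.clip(np.rint(rng.normal(42, 17, n_participants)), 10, 100)
    russian = rng.random(n_participants) < DEFAULT_RUSSIAN_RATE
    date_span = (_DATE_END - _DATE_START).days
    date_offsets = rng.integers(0, date_span + 1, size=n_participants)
    regions = rng.choice(len(_REGIONS), size=n_participants)

    pairs: list[tuple[ParticipantRecord, Narrative]] = []
    tokens: list[TokenRecord] = []
    for i in range(n_participants):
        doc_id = i + 1
        words = rng.choice(label_array, size=lengths[i], p=probs)
        sentences = _chunk_sentences(words, rng)
        text = " ".join(" ".join(s) + "." for s in sentences)
        tokens.extend(_tokenize_fixture(doc_id, sentences, rng))
        record = ParticipantRecord(
            doc_id=doc_id,
            age=int(ages[i]),
            gender=categorical["gender"][i],
            marital_status=categorical["marital_status"][i],
            education=categorical["education"][i],
            region=_REGIONS[regions[i]],
            occupation_status=categorical["occupation_status"][i],
            displaced=bool(categorical["displaced"][i]),
            trauma_history=categorical["trauma_history"][i],
            submission_date=_DATE_START + _dt.timedelta(
                days=int(date_offsets[i])
            ),
            pcl5_total=int(pcl5[i]) if completed[i] else None,
            miss_total=int(miss[i]) if completed[i] else None,
            consent=True,
        )
        narrative = Narrative(
            doc_id=doc_id,
            text_original=text,
            original_language="ru" if russian[i] else "uk",
        )
        pairs.append((record, narrative))

    narratives_path = out / "narratives.csv"
    tokens_path = out / "tokens.conllu"
    truth_path = out / "generation_truth.json"
    write_narrative_table(pairs, narratives_path)
    write_token_table(tokens, tokens_path)
    truth_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "n_participants": n_participants,
                "length_mean": length_mean,
                "length_sd": length_sd,
                "completion_rate": completion_rate,
                "marginals": {
                    column: {str(k): v for k, v in weights.items()}
                    for column, weights in marginals.items()
                },
            },
            ensure_ascii=False, indent=2,
        ) + "\n",
        encoding="utf-8",
    )
    return GeneratedCorpus(
        narratives_path=narratives_path,
        tokens_path=tokens_path,
        truth_path=truth_path,
        n_participants=n_participants,
    )


def _chunk_sentences(
    words: np.ndarray, rng: np.random.Generator
) -> list[list[str]]:
    sentences = []
    start = 0
    while start < len(words):
        size = int(rng.integers(6, 16))
        sentences.append([str(w) for w in words[start : start + size]])
        start += size
    return sentences


def _tokenize_fixture(
    doc_id: int, sentences: list[list[str]], rng: np.random.Generator
) -> list[TokenRecord]:
    records = []
    for sentence_index, sentence in enumerate(sentences, start=1):
        sentence_text = " ".join(sentence) + "."
        pos_draws = rng.choice(
            len(_POS_LEVELS), size=len(sentence), p=_POS_PROBS
        )
        for token_index, word in enumerate(sentence, start=1):
            records.append(TokenRecord(
                doc_id=doc_id,
                paragraph_index=1,
                sentence_index=sentence_index,
                sentence_text=sentence_text,
                token_index=token_index,
                form=word,
                lemma=word,
                upos=_POS_LEVELS[pos_draws[token_index - 1]],
                morph="_",
                dep_relation="root" if token_index == 1 else "dep",
                head_index=0 if token_index == 1 else 1,
            ))
        records.append(TokenRecord(
            doc_id=doc_id,
            paragraph_index=1,
            sentence_index=sentence_index,
            sentence_text=sentence_text,
            token_index=len(sentence) + 1,
            form=".",
            lemma=".",
            upos="PUNCT",
            morph="_",
            dep_relation="punct",
            head_index=1,
        ))
    return records
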