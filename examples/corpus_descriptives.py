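"""Generate a synthetic corpus release, validate it and summarize it.

Emits the two linked release formats (narrative-level CSV, token-level
CoNLL-U), reads them back with row-level validation, applies the sample
trimming rules, and prints the descriptive summary of the corpus and sample
(token/type/lemma counts with and without stopwords, narrative length
moments, categorical tabulations, psychometric score summaries).
"""

import tempfile

from lexkey import (
    filter_participants,
    generate_narratives,
    read_narrative_table,
    read_token_table,
    summarize_corpus,
)
from lexkey.preprocess import DEFAULT_STOPWORD_PATH, load_stopwords

with tempfile.TemporaryDirectory() as tmp:
    generated = generate_narratives(300, out_dir=tmp, seed=42)
    quarantine: list = []
    pairs = read_narrative_table(generated.narratives_path,
                                 quarantine=quarantine)
    tokens = list(read_token_table(generated.tokens_path))

retained, exclusions = filter_participants(pairs)
print(f"rows read: {len(pairs)}  quarantined: {len(quarantine)}  "
      f"excluded by trimming: {len(exclusions)}")

summary = summarize_corpus(
    [record for record, _ in retained],
    [narrative for _, narrative in retained],
    tokens,
    load_stopwords(DEFAULT_STOPWORD_PATH),
)
print(f"participants: {summary.n_participants}")
print(f"word tokens (minus stopwords): {summary.n_tokens} "
      f"({summary.n_tokens_no_stopwords})")
print(f"distinct lemmas (minus stopwords): {summary.n_lemmas} "
      f"({summary.n_lemmas_no_stopwords})")
print(f"narrative length, words: range = {summary.length_min}:"
      f"{summary.length_max}, M = {summary.length_mean:.0f}, "
      f"SD = {summary.length_sd:.0f}")
print(f"displaced: {summary.categorical_tabulations['displaced']}")
print(f"PCL-5 over {summary.pcl5.n} completers: "
      f"M = {summary.pcl5.mean:.1f}, SD = {summary.pcl5.sd:.1f}, "
      f"range = {summary.pcl5.minimum}:{summary.pcl5.maximum}")
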