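"""Score a toy two-corpus comparison with the smoothed log-odds statistic.

Builds two tiny lemma frequency tables, merges them over the union of their
vocabularies (zero-filling), scores every lemma, and applies a Bonferroni
threshold.  Positive z marks lemmas over-used in the target corpus.
"""

from lexkey import (
    FrequencyTable,
    bonferroni_threshold,
    compute_keyness,
    merge_tables,
    select_keys,
)

target = FrequencyTable(
    "wartime", {"тривога": 30, "укриття": 22, "ранок": 10, "рік": 3}, 65
)
reference = FrequencyTable(
    "prewar", {"рік": 28, "ранок": 12, "літо": 18, "тривога": 4}, 62
)

combined = merge_tables(target, reference)
print(f"merged lemmas: {combined.n_rows}  "
      f"(n_target={combined.n_target}, n_reference={combined.n_reference}, "
      f"alpha_0={combined.alpha_0})")

threshold = bonferroni_threshold(alpha=0.05, m=combined.n_rows)
results = compute_keyness(combined)
target_keys, reference_keys = select_keys(results, threshold)

print(f"Bonferroni |z| threshold at alpha=0.05 over m={combined.n_rows}: "
      f"{threshold:.3f}")
for r in sorted(results, key=lambda r: -r.z):
    flag = " *" if r.significant else ""
    print(f"  {r.lemma:<10} y_t={r.y_target:>2} y_r={r.y_reference:>2} "
          f"delta={r.delta:+.3f} z={r.z:+.3f}{flag}")
print("lemmas marked * are diagnostic: positive z of the wartime corpus, "
      "negative z of the pre-war one")
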