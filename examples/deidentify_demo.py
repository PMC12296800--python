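"""Tag personal and place names in a narrative before release.

Alias lists cover the inflected surface forms of each entity.  A single
entity of a kind gets an unindexed tag ([NAME]); several get indexed tags in
order of first appearance, reused consistently throughout the narrative.
"""

from lexkey import Entity, deidentify

text = ("Ми з Оксаною виїхали з Бучі до Ірпеня. "
        "В Ірпені Оксана знайшла житло, але Ірпінь теж обстрілювали.")

entities = [
    Entity("person-1", "person", ("Оксана", "Оксаною")),
    Entity("city-bucha", "place", ("Буча", "Бучі")),
    Entity("city-irpin", "place", ("Ірпінь", "Ірпеня", "Ірпені")),
]

tagged, log = deidentify(text, entities)
print("original :", text)
print("tagged   :", tagged)
print(f"replacements: {len(log)}")
for r in log:
    print(f"  pos {r.position:>3}: {r.alias!r} -> {r.tag} ({r.entity_id})")
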