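"""Build a bidirectional miRNA↔disease database from two mapping layers.

Generates a synthetic miRNA→gene and gene→disease fixture, merges the two
layers on the shared gene key, and queries the result by regex.
"""

from mirdmap import FixtureSpec, build_db, generate, merge_on_key, query

mg, gd, _ = generate(FixtureSpec(seed=1))
merged, dropped = merge_on_key(mg, gd)
db = build_db(merged)

print(f"miRNA→gene layer: {len(mg)} miRNAs, {mg.n_pairs()} target pairs")
print(f"gene→disease layer: {len(gd)} genes, {gd.n_pairs()} association pairs")
print(f"merged database: {db.n_mirnas} miRNAs ↔ {db.n_diseases} diseases")
print(f"{len(dropped)} miRNAs had no disease-annotated target gene and were dropped")

hits = query(db, r"disease [12]$", by="disease")
print("\nregex query 'disease [12]$' (case-insensitive, unanchored):")
for name, mirnas in hits:
    print(f"  {name}: associated with {len(mirnas)} miRNAs")
# Each hit is a disease name matching the pattern; the count is the size of
# its associated miRNA set in the merged database.
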