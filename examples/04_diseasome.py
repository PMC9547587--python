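"""Diseasome abundance profiling.

Selects a disease set by keyword regex, then counts in how many of those
diseases each miRNA occurs. miRNAs passing the count threshold are
candidate shared regulators of the disease family.
"""

from mirdmap import FixtureSpec, abundance, build_db, generate, merge_on_key, select_diseasome

mg, gd, _ = generate(FixtureSpec(seed=4))
merged, _ = merge_on_key(mg, gd)
db = build_db(merged)

diseasome = select_diseasome(db, keyword=r"disease [1-3][0-9]$")
print(f"keyword diseasome: {len(diseasome)} diseases")

records = abundance(db, diseasome, min_count=3)
print(f"{len(records)} miRNAs occur in at least 3 diseasome diseases\n")
print("rank\tmiRNA\toccurrence")
for rank, rec in enumerate(records[:10], start=1):
    print(f"{rank}\t{rec.mirna}\t{rec.occurrence}")
# occurrence = number of diseasome diseases whose miRNA set contains the
# miRNA; pure counting, no significance test.
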