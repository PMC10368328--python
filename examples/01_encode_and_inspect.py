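"""Ordinal encoding of alignment columns, and what key permutation means.

Each alignment column gets its own character -> integer key, with code 0
always the column's modal state.  The screen's conclusions should not depend
on which integer labels the states carry; `permute_keys` produces relabeled
keys so that claim can be tested.
"""

from convscreen import (
    LabeledAlignment,
    build_column_keys,
    decode_alignment,
    encode_alignment,
    permute_keys,
)

aln = LabeledAlignment(
    gene_name="demo",
    sample_ids=["sp1", "sp2", "sp3", "sp4", "sp5"],
    rows=[
        "MAKTE",
        "MAKSE",
        "MSK-E",
        "MSKSE",
        "MAKSE",
    ],
    labels={"sp1": "C3", "sp2": "C3", "sp3": "C4", "sp4": "C4", "sp5": "C4"},
)

keys = build_column_keys(aln)
print("per-column keys (character -> code):")
for ap, key in enumerate(keys.keys, start=1):
    print(f"  ap {ap}: {key}")

fm = encode_alignment(aln, keys)
print("\nfeature matrix (rows = samples):")
for sid, row in zip(fm.sample_ids, fm.values):
    print(f"  {sid}: {row.tolist()}")

y, positive = fm.y()
print(f"\nbinary labels (positive = {positive}): {y.tolist()}")

# encoding is invertible...
assert decode_alignment(fm, keys) == aln.rows

# ...and any relabeling of the codes still is
shuffled = permute_keys(keys, mode="full-shuffle", seed=7)
fm2 = encode_alignment(aln, shuffled)
assert decode_alignment(fm2, shuffled) == aln.rows
print("\nafter full-shuffle relabeling, column 2 becomes:",
      fm2.values[:, 1].tolist(), "with key", shuffled.keys[1])
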