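"""Dataset preparation: filtering, deduplication, cross-set cleaning, splitting.

Builds a synthetic positive (ACP-like) and negative (AMP-like) peptide set,
plants a duplicate and an invalid sequence, then runs the full hygiene
pipeline: length/alphabet filtering, exact dedup, cross-set identity
removal, and a seeded balanced train/test split.
"""

import acpsmo as a

pos, neg = a.make_benchmark("strong", 80, seed=4)
neg.peptides.append(a.Peptide("planted_dup", neg[0].sequence, label="negative"))
neg.peptides.append(a.Peptide("planted_bad", "KLXK", label="negative"))

pos = a.dedup_identical(a.filter_valid(pos))
neg = a.dedup_identical(a.filter_valid(neg))
# remove negatives similar to any positive; identity = matched positions of an
# optimal free-gap alignment over the shorter length (CD-HIT's denominator)
neg = a.cross_set_filter(pos, neg, a.IdentityParams(threshold=0.9))
train, test = a.balance_and_split(pos, neg, n_train=50, n_test=20, seed=4)

print("positive set provenance:")
for line in pos.provenance:
    print("  ", line)
print("negative set provenance:")
for line in neg.provenance:
    print("  ", line)
print(f"train: {len(train)} peptides, test: {len(test)} peptides")
# Each provenance line records one pipeline stage with before/after counts;
# the planted duplicate dies in dedup and the invalid peptide in filtering.
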