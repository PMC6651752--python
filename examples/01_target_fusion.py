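"""Fuse ranked target predictions from three target-fishing methods.

Builds a small prediction table by hand, fuses it, and prints the ranked
candidates.  A score of 1.0 means a target ranked first in every method;
targets returned by fewer methods or at worse ranks score lower.
"""

from targetid import PredictionTable, fusion_score

entries = [
    # (target, method, rank)
    ("MMP1", "moltarpred", 1), ("TRPV1", "moltarpred", 2), ("HDAC1", "moltarpred", 3),
    ("MMP1", "charite", 1), ("MMP2", "charite", 2),
    ("TRPV1", "sea", 1), ("MMP1", "sea", 2), ("MMP9", "sea", 3),
]
table = PredictionTable.from_records(entries, methods=["moltarpred", "charite", "sea"])

result = fusion_score(table, aggregation="product")
print(result.to_string(index=False))
# MMP1 tops the list: predicted by all three methods, twice at rank 1.
# Targets seen by a single method score at most (1/3)*(1/3) = 0.11.
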