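"""Quality-trim read pairs with the 3' partial-sum rule.

The rule removes the 3' tail that minimises the running sum of
(quality - cutoff); a pair is discarded when either mate ends up shorter
than 20 bp.
"""

import numpy as np

from provmap import ReadPair, TrimConfig, quality_trim, trim_fastq

# one read with a clean low-quality tail
seq, quals = quality_trim("ACGTACGT", [38, 38, 37, 36, 12, 9, 3, 2], cutoff=20)
print(f"trimmed read: {seq!r} (kept {len(seq)}/8 bases)")

pairs = [
    ReadPair("good", "ACGT" * 10, "ACGT" * 10, np.full(40, 38), np.full(40, 38)),
    ReadPair("bad_mate", "ACGT" * 10, "ACGT" * 10, np.full(40, 38), np.full(40, 3)),
]
kept, stats = trim_fastq(pairs, TrimConfig(quality_cutoff=20, min_len=20))
print(f"kept pairs: {[p.id for p in kept]}")
print(f"stats: {stats.to_dict()}")
# 'bad_mate' disappears because its second mate trims below 20 bp;
# bases_kept counts the bases surviving in kept pairs only.
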