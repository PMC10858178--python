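"""Align a junction-spanning chimeric read and inspect the split call.

A read whose prefix comes from a host chromosome and whose suffix comes
from the provirus is the direct evidence of an integration junction.
"""

import numpy as np

from provmap import Contig, KmerIndex, ProvirusAnnotation, ReferenceSet, align_read
from provmap.align import AlignParams
from provmap.dna import random_dna

rng = np.random.default_rng(42)
refset = ReferenceSet(
    [
        Contig("chr1", random_dna(rng, 10_000)),
        Contig("provirus", random_dna(rng, 5_000), placed=False, is_provirus=True),
    ],
    ProvirusAnnotation(utr5=(0, 400), utr3=(4600, 5000)),
)
index = KmerIndex(refset, k=21)

host = refset.get("chr1").sequence
pro = refset.get("provirus").sequence
# pick a junction with no microhomology (score-equal junctions are otherwise
# resolved by absorbing the ambiguous bases into the host segment)
p = next(p for p in range(4000, 4100) if host[p + 60] != pro[0])
read = host[p : p + 60] + pro[0:90]  # 60 bp host + 90 bp of the provirus 5' UTR

res = align_read(read, index, AlignParams(seed_stride=1))
sp = res.split
print(f"kind: {res.kind}, score {res.score}, unique: {res.unique}")
print(f"host segment starts at chr1:{p}")
print(f"seg_a: {sp.seg_a.contig}:{sp.seg_a.ref_start}-{sp.seg_a.ref_end} ({sp.seg_a.strand})")
print(f"seg_b: {sp.seg_b.contig}:{sp.seg_b.ref_start}-{sp.seg_b.ref_end} ({sp.seg_b.strand})")
print(f"junction at read offset {sp.junction_offset}")
# seg_a ends at the last host base before the provirus; because seg_b lies in
# the 5' UTR this split would count as UTR-supported evidence downstream.
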