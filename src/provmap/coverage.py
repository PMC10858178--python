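"""Per-base sequencing depth and coverage-breadth summaries.

Depth at a base is the number of aligned segments overlapping it; both mates
of a pair and both segments of a split alignment count.  The summary mean
and breadth are computed over the host genome only by default -- the
provirus contig is a transgene, not part of the genome the depth metrics
describe -- and duplicate reads are not removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentResult
from .simulate import ReferenceSet


@dataclass
class CoverageSummary:
    mean_depth: float
    breadth: dict[int, float]  # threshold -> fraction of bases covered >= threshold
    per_contig: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mean_depth": self.mean_depth,
            "breadth": {str(k): v for k, v in self.breadth.items()},
            "per_contig": self.per_contig,
        }


def iter_segments(results: Iterable[AlignmentResult]):
    """(contig, ref_start, ref_end) for every aligned segment in results."""
    for res in results:
        if res.kind == "full":
            seg = res.full
            yield seg.contig, seg.ref_start, seg.ref_end
        elif res.kind == "split":
            for seg in (res.split.seg_a, res.split.seg_b):
                yield seg.contig, seg.ref_start, seg.ref_end


def depth_profile(
    segments: Iterable, refset: ReferenceSet
) -> dict[str, np.ndarray]:
    """Per-contig per-base depth from an iterable of segments.

    Segments may be (contig, start, end) triples or objects with
    contig/ref_start/ref_end attributes; a segment outside its contig is an
    error.
    """
    lengths = {c.name: len(c) for c in refset.contigs}
    # difference arrays: depth = cumsum of (+1 at start, -1 at end)
    diffs = {name: np.zeros(n + 1, dtype=np.int64) for name, n in lengths.items()}
    for seg in segments:
        if isinstance(seg, tuple):
            contig, start, end = seg
        else:
            contig, start, end = seg.contig, seg.ref_start, seg.ref_end
        if contig not in lengths:
            raise KeyError(f"unknown contig {contig!r}")
        if not (0 <= start <= end <= lengths[contig]):
            raise ValueError(
                f"segment [{start}, {end}) outside contig {contig} (len {lengths[contig]})"
            )
        diffs[contig][start] += 1
        diffs[contig][end] -= 1
    return {name: np.cumsum(d[:-1]) for name, d in diffs.items()}


def summarize(
    profiles: dict[str, np.ndarray],
    refset: ReferenceSet,
    thresholds: Sequence[int] = (4,),
    include_provirus: bool = False,
) -> CoverageSummary:
    """Mean depth and breadth-at-threshold over the (host) genome."""
    names = [
        c.name for c in refset.contigs if include_provirus or not c.is_provirus
    ]
    names = [n for n in names if n in profiles]
    total_len = sum(profiles[n].size for n in names)
    if total_len == 0:
        raise ValueError("empty genome: no contigs to summarise")
    total_bases = sum(int(profiles[n].sum()) for n in names)
    per_contig = {
        n: float(profiles[n].mean()) if profiles[n].size else 0.0 for n in names
    }
    breadth = {}
    for t in sorted(set(int(t) for t in thresholds)):
        covered = sum(int((profiles[n] >= t).sum()) for n in names)
        breadth[t] = covered / total_len
    return CoverageSummary(
        mean_depth=total_bases / total_len,
        breadth=breadth,
        per_contig=per_contig,
    )
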