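"""Quality trimming and pair-length filtering.

Implements the standard 3' partial-sum trimming rule: with cutoff ``c`` and
suffix sums S(i) = sum_{j>=i} (q_j - c), the read is cut at the position i*
minimising S(i) (ties broken toward the smaller i, i.e. trimming more), and
only if S(i*) < 0.  Pairs in which either mate ends up shorter than
``min_len`` (default 20 bp, matching the study's filter) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import dna
from .simulate import ReadBatch, ReadPair

_BIG = np.int64(1) << 40


@dataclass(frozen=True)
class TrimConfig:
    quality_cutoff: int = 20
    min_len: int = 20
    adapter: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.quality_cutoff <= 41):
            raise ValueError("quality_cutoff must be in [0, 41]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class TrimStats:
    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_discarded: int = 0
    bases_in: int = 0
    bases_kept: int = 0

    def validate(self) -> None:
        assert self.pairs_kept + self.pairs_discarded == self.pairs_in
        assert self.bases_kept <= self.bases_in

    def to_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "pairs_kept": self.pairs_kept,
            "pairs_discarded": self.pairs_discarded,
            "bases_in": self.bases_in,
            "bases_kept": self.bases_kept,
        }


def quality_trim(
    seq: str, quals: Sequence[int], cutoff: int = 20
) -> tuple[str, np.ndarray]:
    """Trim the 3' end of one read by the partial-sum rule.

    Returns the kept prefix and its quality scores.  An empty read stays
    empty; a read whose suffix sums never go negative is returned unchanged.
    """
    if len(seq) != len(quals):
        raise ValueError("sequence and quality lengths differ")
    q = np.asarray(quals, dtype=np.int64)
    n = len(q)
    if n == 0:
        return seq, q
    s = 0
    best = 0
    cut = n
    for i in range(n - 1, -1, -1):
        s += int(q[i]) - cutoff
        if s <= best:  # <= : ties go to the smaller i (trim more)
            best = s
            cut = i
    if best >= 0:
        cut = n
    return seq[:cut], q[:cut]


def trimmed_lengths(
    quals: np.ndarray, lengths: np.ndarray, cutoff: int
) -> np.ndarray:
    """Vectorised partial-sum trimming: kept length per row.

    ``quals`` is an (N, W) matrix; entries at or beyond each row's length are
    ignored.  Equivalent to :func:`quality_trim` row by row.
    """
    n, w = quals.shape
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    cols = np.arange(w)
    valid = cols[None, :] < lengths[:, None]
    contrib = np.where(valid, quals.astype(np.int64) - cutoff, 0)
    # S(i) = suffix sum from i; computed via reversed cumulative sums
    suffix = np.cumsum(contrib[:, ::-1], axis=1)[:, ::-1]
    suffix = np.where(valid, suffix, _BIG)  # exclude i >= length from argmin
    cut = np.argmin(suffix, axis=1)  # first minimum -> smallest i
    best = np.take_along_axis(suffix, cut[:, None], axis=1)[:, 0]
    return np.where(best < 0, cut, lengths).astype(np.int64)


def filter_pair(r1: str, r2: str, min_len: int = 20) -> bool:
    """True (keep) unless either mate is shorter than ``min_len``."""
    return len(r1) >= min_len and len(r2) >= min_len


def clip_adapter(seq: str, quals: np.ndarray, adapter: str) -> tuple[str, np.ndarray]:
    """Exact-match adapter clipping.

    Removes everything from the first full occurrence of the adapter onward;
    failing that, clips a 3'-terminal exact prefix of the adapter (minimum
    overlap 3 bp).  Full error-tolerant adapter alignment is out of scope.
    """
    i = seq.find(adapter)
    if i >= 0:
        return seq[:i], quals[:i]
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, 2, -1):
        if seq.endswith(adapter[:ov]):
            return seq[:-ov], quals[:-ov]
    return seq, quals


def trim_pair(pair: ReadPair, config: TrimConfig) -> ReadPair:
    """Adapter-clip (optional) then quality-trim both mates of one pair."""
    s1, q1 = pair.seq1, np.asarray(pair.qual1)
    s2, q2 = pair.seq2, np.asarray(pair.qual2)
    if config.adapter:
        s1, q1 = clip_adapter(s1, q1, config.adapter)
        s2, q2 = clip_adapter(s2, q2, config.adapter)
    s1, q1 = quality_trim(s1, q1, config.quality_cutoff)
    s2, q2 = quality_trim(s2, q2, config.quality_cutoff)
    return ReadPair(pair.id, s1, s2, q1, q2, pair.truth_origin)


def trim_fastq(
    pairs: Iterable[ReadPair], config: TrimConfig | None = None
) -> tuple[list[ReadPair], TrimStats]:
    """Trim a stream of pairs and drop those failing the length filter."""
    config = config or TrimConfig()
    stats = TrimStats()
    kept: list[ReadPair] = []
    for pair in pairs:
        stats.pairs_in += 1
        stats.bases_in += len(pair.seq1) + len(pair.seq2)
        trimmed = trim_pair(pair, config)
        if filter_pair(trimmed.seq1, trimmed.seq2, config.min_len):
            stats.pairs_kept += 1
            stats.bases_kept += len(trimmed.seq1) + len(trimmed.seq2)
            kept.append(trimmed)
        else:
            stats.pairs_discarded += 1
    stats.validate()
    return kept, stats


def trim_batch(batch: ReadBatch, config: TrimConfig | None = None) -> tuple[ReadBatch, TrimStats]:
    """Vectorised trim + pair filter over a ReadBatch.

    Adapter clipping, when configured, falls back to the per-pair path.
    """
    config = config or TrimConfig()
    if config.adapter:
        kept, stats = trim_fastq(batch.pairs(), config)
        return ReadBatch.from_pairs(kept), stats
    new1 = trimmed_lengths(batch.qual1, batch.len1, config.quality_cutoff)
    new2 = trimmed_lengths(batch.qual2, batch.len2, config.quality_cutoff)
    keep = (new1 >= config.min_len) & (new2 >= config.min_len)
    stats = TrimStats(
        pairs_in=batch.n,
        pairs_kept=int(keep.sum()),
        pairs_discarded=int((~keep).sum()),
        bases_in=int(batch.len1.sum() + batch.len2.sum()),
        bases_kept=int(new1[keep].sum() + new2[keep].sum()),
    )
    stats.validate()
    idx = np.flatnonzero(keep)
    cols = np.arange(batch.seq1.shape[1])
    seq1 = batch.seq1[idx].copy()
    seq2 = batch.seq2[idx].copy()
    qual1 = batch.qual1[idx].copy()
    qual2 = batch.qual2[idx].copy()
    len1 = new1[idx]
    len2 = new2[idx]
    seq1[cols[None, :] >= len1[:, None]] = dna.N
    seq2[cols[None, :] >= len2[:, None]] = dna.N
    qual1[cols[None, :] >= len1[:, None]] = 0
    qual2[cols[None, :] >= len2[:, None]] = 0
    kept_batch = ReadBatch(
        [batch.ids[i] for i in idx], seq1, qual1, len1, seq2, qual2, len2
    )
    return kept_batch, stats
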