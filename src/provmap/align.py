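"""Seed-and-extend split-read alignment against a combined host+provirus reference.

The aligner is built for the evidence the integration caller needs: reads
that map in one piece (full alignments) and chimeric reads whose prefix and
suffix map to different loci (split alignments), the trans case joining a
host chromosome and the provirus.  Exact k-mer seeds are grouped per
(contig, strand, diagonal); because segments are ungapped (substitutions
only -- the simulated data contain no indels) every placement of a read is a
single diagonal, which keeps scoring fully vectorisable.

A full alignment is reported when the best single placement covers the read
with a mismatch rate at most ``max_mismatch_rate``; otherwise the best
prefix+suffix partition over all seeded placement pairs is reported as a
split (each segment at least ``min_seg`` bp and under the same mismatch-rate
bound).  Score-equal junctions are resolved to the largest junction offset,
i.e. microhomology is absorbed by the left segment.  A placement is
``unique`` when it beats the best competing placement by at least
``uniqueness_margin`` score units -- an explicit, testable stand-in for a
mapper's internal uniquely-mapped flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import dna
from .simulate import Contig, ReadBatch, ReferenceSet

PAD = 512  # inter-contig padding; also the maximum supported read length

NEG = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    k: int = 21
    min_seg: int = 25
    max_mismatch_rate: float = 0.05
    uniqueness_margin: int = 5
    match_score: int = 1
    mismatch_score: int = -1
    split_penalty: int = -2
    seed_stride: int = 5
    max_hits: int = 16

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("seed length k must be >= 11")
        if self.min_seg < self.k:
            raise ValueError("min_seg must be >= k")
        if self.seed_stride < 1 or self.max_hits < 1:
            raise ValueError("seed_stride and max_hits must be >= 1")


@dataclass(slots=True)
class SegmentAlignment:
    """One ungapped aligned segment; ref and read intervals have equal length."""

    contig: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int
    mismatches: int

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(slots=True)
class SplitAlignment:
    read_id: str
    seg_a: SegmentAlignment  # covers the read prefix
    seg_b: SegmentAlignment  # covers the read suffix
    junction_offset: int  # read coordinate where seg_a ends
    score: int
    unique: bool


@dataclass(slots=True)
class AlignmentResult:
    read_id: str
    kind: str  # 'full' | 'split' | 'unmapped'
    full: SegmentAlignment | None
    split: SplitAlignment | None
    score: int
    secondary_score: int | None
    unique: bool


class KmerIndex:
    """Exact k-mer position index over the concatenated reference.

    Contigs are concatenated with ``PAD`` bases of code 4 between them, so a
    read placement can never silently bridge two contigs: padding bases
    always score as mismatches.  Only the forward strand is indexed; reverse
    placements are found by querying the reverse complement of the read.
    """

    def __init__(self, refset: ReferenceSet, k: int = 21):
        if k < 1:
            raise ValueError("k must be positive")
        if not refset.contigs:
            raise ValueError("reference set has no contigs")
        if min(len(c) for c in refset.contigs) < k:
            raise ValueError("k exceeds the shortest contig length")
        self.refset = refset
        self.k = k
        self.names = [c.name for c in refset.contigs]
        parts = [np.full(PAD, dna.N, dtype=np.uint8)]
        starts, ends = [], []
        pos = PAD
        for c in refset.contigs:
            starts.append(pos)
            parts.append(dna.encode(c.sequence))
            pos += len(c)
            ends.append(pos)
            parts.append(np.full(PAD, dna.N, dtype=np.uint8))
            pos += PAD
        self.cat = np.concatenate(parts)
        self.starts = np.array(starts, dtype=np.int64)
        self.ends = np.array(ends, dtype=np.int64)

        m = len(self.cat) - k + 1
        codes = np.zeros(m, dtype=np.uint64)
        for t in range(k):
            codes = codes * np.uint64(4) + self.cat[t : t + m]
        bad = np.concatenate(([0], np.cumsum(self.cat >= dna.N)))
        valid = (bad[k:] - bad[:-k]) == 0
        positions = np.flatnonzero(valid).astype(np.int64)
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        self._pos = positions[order]
        # run-length encode: unique codes + start offsets into _pos
        if sorted_codes.size:
            newrun = np.concatenate(([True], sorted_codes[1:] != sorted_codes[:-1]))
            run_starts = np.flatnonzero(newrun)
            self._ucodes = sorted_codes[run_starts]
            self._ustart = np.concatenate((run_starts, [sorted_codes.size])).astype(np.int64)
        else:
            self._ucodes = sorted_codes
            self._ustart = np.zeros(1, dtype=np.int64)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (contig, position) occurrences of an exact k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        enc = dna.encode(kmer)
        if enc.max(initial=0) >= dna.N:
            return []
        code = np.uint64(0)
        for b in enc:
            code = code * np.uint64(4) + np.uint64(b)
        i = int(np.searchsorted(self._ucodes, code, side="left"))
        if i >= self._ucodes.size or self._ucodes[i] != code:
            return []
        out = []
        for p in self._pos[self._ustart[i] : self._ustart[i + 1]]:
            ci = int(np.searchsorted(self.starts, p, side="right") - 1)
            out.append((self.names[ci], int(p - self.starts[ci])))
        return sorted(out)

    def contig_index_of(self, cat_pos: int) -> int:
        return int(np.searchsorted(self.starts, cat_pos, side="right") - 1)


def _revcomp_rows(mat: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Per-row reverse complement respecting row lengths; padding stays 4."""
    n, w = mat.shape
    out = np.full_like(mat, dna.N)
    for l in np.unique(lens):  # few distinct lengths in practice
        l = int(l)
        if l == 0:
            continue
        rows = np.flatnonzero(lens == l)
        sub = mat[rows, :l][:, ::-1]
        real = sub < dna.N
        out[rows, :l] = np.where(real, 3 - sub, dna.N)
    return out


def _window_codes(mat: np.ndarray, col0: np.ndarray | int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer codes starting at column(s) col0, plus a validity mask."""
    n, w = mat.shape
    if np.isscalar(col0):
        win = mat[:, col0 : col0 + k]
    else:
        cols = np.asarray(col0)[:, None] + np.arange(k)[None, :]
        win = np.take_along_axis(mat, np.minimum(cols, w - 1), axis=1)
    ok = (win < dna.N).all(axis=1)
    codes = np.zeros(n, dtype=np.uint64)
    for t in range(k):
        codes = codes * np.uint64(4) + win[:, t]
    return codes, ok


def _collect_candidates(
    fwd: np.ndarray,
    rc: np.ndarray,
    lens: np.ndarray,
    index: KmerIndex,
    params: AlignParams,
    rows: np.ndarray | None = None,
    ends_only: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded placements as parallel arrays (read, strand, diagonal).

    Strand 0 queries the forward read, strand 1 the reverse complement; the
    diagonal is the concatenated-reference position of read offset 0 on the
    queried orientation.  With ``ends_only`` just the first and last valid
    offsets are seeded (the cheap first pass); otherwise offsets are strided
    plus the last offset, so both read ends are always covered.  ``rows``
    restricts seeding to a subset of reads.
    """
    k, stride = index.k, params.seed_stride
    n, w = fwd.shape
    if rows is None:
        rows = np.arange(n)
    sub_lens = lens[rows]
    q_code, q_read, q_off, q_strand = [], [], [], []
    for strand, mat in ((0, fwd), (1, rc)):
        sub = mat[rows]
        offsets: list[int] = [0] if ends_only else list(range(0, max(w - k, 0) + 1, stride))
        for off in offsets:
            codes, ok = _window_codes(sub, off, k)
            ok &= sub_lens >= off + k
            q_code.append(codes[ok])
            q_read.append(rows[ok])
            q_off.append(np.full(int(ok.sum()), off, dtype=np.int64))
            q_strand.append(np.full(int(ok.sum()), strand, dtype=np.int64))
        last = sub_lens - k
        codes, ok = _window_codes(sub, np.maximum(last, 0), k)
        ok &= last >= 0
        q_code.append(codes[ok])
        q_read.append(rows[ok])
        q_off.append(last[ok])
        q_strand.append(np.full(int(ok.sum()), strand, dtype=np.int64))
    code = np.concatenate(q_code)
    read = np.concatenate(q_read)
    off = np.concatenate(q_off)
    strand = np.concatenate(q_strand)

    if index._ucodes.size == 0 or code.size == 0:
        return (np.zeros(0, np.int64),) * 3
    ui = np.searchsorted(index._ucodes, code, side="left")
    ui = np.minimum(ui, index._ucodes.size - 1)
    hit = index._ucodes[ui] == code
    lo = index._ustart[ui]
    cnt = np.where(hit, index._ustart[ui + 1] - lo, 0)
    keep = (cnt > 0) & (cnt <= params.max_hits)
    lo, cnt = lo[keep], cnt[keep]
    total = int(cnt.sum())
    if total == 0:
        return (np.zeros(0, np.int64),) * 3
    base = np.repeat(lo, cnt)
    step = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    pos = index._pos[base + step]
    read_h = np.repeat(read[keep], cnt)
    off_h = np.repeat(off[keep], cnt)
    strand_h = np.repeat(strand[keep], cnt)
    diag = pos - off_h

    key = (read_h.astype(np.int64) << 33) | (strand_h << 32) | diag
    ukey = np.unique(key)
    return ukey >> 33, (ukey >> 32) & 1, ukey & ((1 << 32) - 1)


def _make_segment(
    index: KmerIndex,
    strand: int,
    diag: int,
    read_lo: int,
    read_hi: int,
    read_len: int,
    mismatches: int,
) -> SegmentAlignment | None:
    """Materialise one segment in contig-local coordinates, clamped to the contig."""
    if strand == 0:
        ref_lo, ref_hi = diag + read_lo, diag + read_hi
    else:
        ref_lo, ref_hi = diag + read_len - read_hi, diag + read_len - read_lo
    ci = index.contig_index_of((ref_lo + ref_hi) // 2)
    cstart, cend = int(index.starts[ci]), int(index.ends[ci])
    tl = max(0, cstart - ref_lo)
    tr = max(0, ref_hi - cend)
    if ref_hi - tr <= ref_lo + tl:
        return None
    ref_lo += tl
    ref_hi -= tr
    if strand == 0:
        read_lo += tl
        read_hi -= tr
    else:
        read_lo += tr
        read_hi -= tl
    return SegmentAlignment(
        contig=index.names[ci],
        ref_start=ref_lo - cstart,
        ref_end=ref_hi - cstart,
        strand="+" if strand == 0 else "-",
        read_start=read_lo,
        read_end=read_hi,
        mismatches=max(0, mismatches - tl - tr),
    )


def _split_search(
    read_id: str,
    L: int,
    cand: list[tuple[int, int, np.ndarray]],  # (strand, diag, profile in read orientation)
    index: KmerIndex,
    params: AlignParams,
) -> AlignmentResult:
    """Best prefix+suffix partition over all seeded placement pairs."""
    unmapped = AlignmentResult(read_id, "unmapped", None, None, 0, None, False)
    if L < 2 * params.min_seg or not cand:
        return unmapped
    C = len(cand)
    P = np.zeros((C, L + 1))
    M = np.zeros((C, L + 1))
    for c, (_, _, prof) in enumerate(cand):
        P[c, 1:] = np.cumsum(prof)
        M[c, 1:] = np.cumsum(prof == -1)
    totals = P[:, L]
    js = np.arange(params.min_seg, L - params.min_seg + 1)
    rate = params.max_mismatch_rate
    pref_ok = M[:, js] <= rate * js[None, :]
    suf_ok = (M[:, [L]] - M[:, js]) <= rate * (L - js)[None, :]
    Pm = np.where(pref_ok, P[:, js], NEG)
    Sm = np.where(suf_ok, totals[:, None] - P[:, js], NEG)
    T = Pm[:, None, :] + Sm[None, :, :] + params.split_penalty  # (C, C, J)
    best = T.max()
    if not np.isfinite(best):
        return unmapped
    ca_s, cb_s, jx = np.nonzero(T == best)
    # ties: largest junction offset (seg_a absorbs microhomology), then candidate order
    pick = np.lexsort((cb_s, ca_s, -jx))[0]
    ca, cb, j = int(ca_s[pick]), int(cb_s[pick]), int(js[jx[pick]])
    if ca == cb:
        return unmapped  # single placement dominates; not a genuine split
    sa_strand, sa_diag, sa_prof = cand[ca]
    sb_strand, sb_diag, sb_prof = cand[cb]
    seg_a = _make_segment(index, sa_strand, sa_diag, 0, j, L, int(M[ca, j]))
    seg_b = _make_segment(index, sb_strand, sb_diag, j, L, L, int(M[cb, L] - M[cb, j]))
    if seg_a is None or seg_b is None:
        return unmapped
    score = int(round(best))
    alt = T.copy()
    alt[ca, cb, :] = NEG
    alt_best = alt.max()
    competing = max(float(totals.max()), alt_best if np.isfinite(alt_best) else NEG)
    secondary = int(round(competing)) if np.isfinite(competing) else None
    unique = secondary is None or score - secondary >= params.uniqueness_margin
    split = SplitAlignment(read_id, seg_a, seg_b, j, score, unique)
    return AlignmentResult(read_id, "split", None, split, score, secondary, unique)


def align_batch(
    ids: Sequence[str],
    seqs: np.ndarray,
    lens: np.ndarray,
    index: KmerIndex,
    params: AlignParams | None = None,
) -> list[AlignmentResult]:
    """Align a batch of reads (rows of ``seqs``, padded with code 4)."""
    params = params or AlignParams()
    n, w = seqs.shape
    if w > PAD:
        raise ValueError(f"reads longer than {PAD} bp are not supported")
    results: list[AlignmentResult] = [
        AlignmentResult(ids[i], "unmapped", None, None, 0, None, False) for i in range(n)
    ]
    if n == 0:
        return results
    lens = np.asarray(lens, dtype=np.int64)
    rc = _revcomp_rows(seqs, lens)
    nosec = -(np.int64(1) << 40)  # "no competing placement" sentinel

    def score_candidates(read, strand, diag):
        windows = index.cat[diag[:, None] + np.arange(w)[None, :]]
        readmat = np.empty_like(windows)
        f = strand == 0
        readmat[f] = seqs[read[f]]
        readmat[~f] = rc[read[~f]]
        isbase = readmat < dna.N
        eqmat = (windows == readmat) & isbase
        nmatch = eqmat.sum(axis=1).astype(np.int64)
        L = lens[read]
        nmism = L - nmatch
        score = params.match_score * nmatch + params.mismatch_score * nmism
        rate = nmism / np.maximum(L, 1)
        return eqmat, isbase, nmism, score, rate

    def emit_fulls(read, strand, diag, nmism, score, best_of, second_score):
        """Vectorised materialisation of acceptable single placements."""
        fb = best_of
        fread = read[fb]
        fdiag = diag[fb]
        fstrand = strand[fb]
        flen = lens[fread]
        ci = np.searchsorted(index.starts, fdiag, side="right") - 1
        cstart = index.starts[ci]
        cend = index.ends[ci]
        tl = np.maximum(0, cstart - fdiag)
        tr = np.maximum(0, fdiag + flen - cend)
        ok_len = flen - tl - tr > 0
        ref_lo = fdiag + tl - cstart
        ref_hi = fdiag + flen - tr - cstart
        read_lo = np.where(fstrand == 0, tl, tr)
        read_hi = flen - np.where(fstrand == 0, tr, tl)
        fmism = np.maximum(0, nmism[fb] - tl - tr)
        fscore = score[fb]
        funiq = fscore - second_score >= params.uniqueness_margin
        for i in range(fb.size):
            if not ok_len[i]:
                continue
            r = int(fread[i])
            seg = SegmentAlignment(
                index.names[int(ci[i])],
                int(ref_lo[i]),
                int(ref_hi[i]),
                "+" if fstrand[i] == 0 else "-",
                int(read_lo[i]),
                int(read_hi[i]),
                int(fmism[i]),
            )
            sec = None if second_score[i] == nosec else int(second_score[i])
            results[r] = AlignmentResult(
                ids[r], "full", seg, None, int(fscore[i]), sec, bool(funiq[i])
            )

    def group(read):
        order = np.lexsort((diag, strand, -score, read))
        oread = read[order]
        firsts = np.flatnonzero(np.concatenate(([True], oread[1:] != oread[:-1])))
        group_end = np.concatenate((firsts[1:], [order.size]))
        best = order[firsts]
        has_second = group_end - firsts > 1
        second_score = np.where(
            has_second, score[order[np.minimum(firsts + 1, order.size - 1)]], nosec
        )
        return order, firsts, group_end, best, second_score

    # phase 1: seed only the two read ends -- resolves nearly every read
    read, strand, diag = _collect_candidates(seqs, rc, lens, index, params, ends_only=True)
    resolved = np.zeros(n, dtype=bool)
    if read.size:
        eqmat, isbase, nmism, score, rate = score_candidates(read, strand, diag)
        order, firsts, group_end, best, second_score = group(read)
        full_ok = rate[best] <= params.max_mismatch_rate
        emit_fulls(read, strand, diag, nmism, score, best[full_ok], second_score[full_ok])
        resolved[read[best[full_ok]]] = True

    # phase 2: full strided seeding for the remainder (junction-spanning
    # reads, high-error reads, reads whose end seeds were corrupted)
    todo = np.flatnonzero(~resolved)
    if todo.size:
        read, strand, diag = _collect_candidates(
            seqs, rc, lens, index, params, rows=todo, ends_only=False
        )
        if read.size:
            eqmat, isbase, nmism, score, rate = score_candidates(read, strand, diag)
            order, firsts, group_end, best, second_score = group(read)
            full_ok = rate[best] <= params.max_mismatch_rate
            emit_fulls(read, strand, diag, nmism, score, best[full_ok], second_score[full_ok])
            for gi in np.flatnonzero(~full_ok):
                lo, hi = firsts[gi], group_end[gi]
                r = int(read[order[lo]])
                rlen = int(lens[r])
                cand = []
                for ci2 in order[lo:hi]:
                    prof = np.where(
                        isbase[ci2, :rlen], np.where(eqmat[ci2, :rlen], 1, -1), 0
                    ).astype(np.int8)
                    if strand[ci2] == 1:
                        prof = prof[::-1].copy()
                    cand.append((int(strand[ci2]), int(diag[ci2]), prof))
                cand.sort(key=lambda c: (c[0], c[1]))
                results[r] = _split_search(ids[r], rlen, cand, index, params)
    return results


def align_read(
    read: str,
    index: KmerIndex,
    params: AlignParams | None = None,
    read_id: str = "read",
) -> AlignmentResult:
    """Align a single read; convenience wrapper over :func:`align_batch`."""
    enc = dna.encode(read)
    seqs = enc[None, :]
    return align_batch([read_id], seqs, np.array([len(read)]), index, params)[0]


def align_pairs(
    batch: ReadBatch, index: KmerIndex, params: AlignParams | None = None
) -> list[AlignmentResult]:
    """Align both mates of every pair independently (ids suffixed /1, /2)."""
    ids = [f"{i}/1" for i in batch.ids] + [f"{i}/2" for i in batch.ids]
    seqs = np.vstack([batch.seq1, batch.seq2])
    lens = np.concatenate([batch.len1, batch.len2])
    return align_batch(ids, seqs, lens, index, params)


def resolve_microhomology(
    split: SplitAlignment, read: str, refset: ReferenceSet
) -> SplitAlignment:
    """Shift the junction right through bases both loci explain equally.

    Ambiguous junction bases are assigned to seg_a: the junction offset is
    advanced while the next read base extends seg_a with a match *and*
    currently matches the first base of seg_b (so the move is score-neutral),
    stopping before seg_b would vanish.  Splits produced by the aligner are
    already in this convention; the function is idempotent on them.
    """
    a, b = split.seg_a, split.seg_b
    seq_a = refset.get(a.contig).sequence
    seq_b = refset.get(b.contig).sequence
    j = split.junction_offset
    while b.read_end - (j + 1) >= 1 and j < len(read):
        base = read[j]
        # next reference base continuing seg_a
        if a.strand == "+":
            if a.ref_end >= len(seq_a):
                break
            ext = seq_a[a.ref_end]
        else:
            if a.ref_start == 0:
                break
            ext = dna.revcomp(seq_a[a.ref_start - 1])
        # reference base of seg_b currently explaining read[j]
        if b.strand == "+":
            cur = seq_b[b.ref_start]
        else:
            cur = dna.revcomp(seq_b[b.ref_end - 1])
        if base != ext or base != cur:
            break
        j += 1
        if a.strand == "+":
            a = SegmentAlignment(
                a.contig, a.ref_start, a.ref_end + 1, a.strand, a.read_start, j, a.mismatches
            )
        else:
            a = SegmentAlignment(
                a.contig, a.ref_start - 1, a.ref_end, a.strand, a.read_start, j, a.mismatches
            )
        if b.strand == "+":
            b = SegmentAlignment(
                b.contig, b.ref_start + 1, b.ref_end, b.strand, j, b.read_end, b.mismatches
            )
        else:
            b = SegmentAlignment(
                b.contig, b.ref_start, b.ref_end - 1, b.strand, j, b.read_end, b.mismatches
            )
    return SplitAlignment(split.read_id, a, b, j, split.score, split.unique)


def write_sam(
    results: Sequence[AlignmentResult],
    refset: ReferenceSet,
    path,
    reads: dict[str, str] | None = None,
) -> None:
    """Write alignments as SAM: full/seg_a as primary, seg_b supplementary (0x800).

    Segment coordinates are emitted 1-based per SAM convention; split mates
    cross-reference each other through SA tags.  If ``reads`` maps read ids
    to sequences, SEQ fields are filled (reverse-complemented on '-').
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.name, "LN": len(c)} for c in refset.contigs],
    }
    tid = {c.name: i for i, c in enumerate(refset.contigs)}

    def cigar(seg: SegmentAlignment, read_len: int) -> list[tuple[int, int]]:
        # soft clips flank the aligned block; on '-' the stored SEQ is the
        # reverse complement, so the clip sides swap
        left, right = seg.read_start, read_len - seg.read_end
        if seg.strand == "-":
            left, right = right, left
        ops = []
        if left:
            ops.append((4, left))
        ops.append((0, seg.read_end - seg.read_start))
        if right:
            ops.append((4, right))
        return ops

    def sa_tag(seg: SegmentAlignment, read_len: int) -> str:
        cig = "".join(f"{n}{'SM'[op == 0]}" for op, n in cigar(seg, read_len))
        return f"{seg.contig},{seg.ref_start + 1},{seg.strand},{cig},60,{seg.mismatches};"

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            if res.kind == "unmapped":
                continue
            read_seq = reads.get(res.read_id) if reads else None
            segs: list[tuple[SegmentAlignment, bool]]
            if res.kind == "full":
                segs = [(res.full, False)]
                read_len = res.full.read_end
            else:
                segs = [(res.split.seg_a, False), (res.split.seg_b, True)]
                read_len = res.split.seg_b.read_end
            if read_seq is not None:
                read_len = len(read_seq)
            for seg, supplementary in segs:
                rec = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
                rec.query_name = res.read_id
                flag = 0
                if seg.strand == "-":
                    flag |= 16
                if supplementary:
                    flag |= 2048
                rec.flag = flag
                rec.reference_id = tid[seg.contig]
                rec.reference_start = seg.ref_start
                rec.mapping_quality = 60 if res.unique else 0
                rec.cigartuples = cigar(seg, read_len)
                if read_seq is not None:
                    rec.query_sequence = (
                        read_seq if seg.strand == "+" else dna.revcomp(read_seq)
                    )
                rec.set_tag("NM", seg.mismatches)
                rec.set_tag("AS", res.score)
                if res.kind == "split":
                    other = res.split.seg_b if not supplementary else res.split.seg_a
                    rec.set_tag("SA", sa_tag(other, read_len))
                out.write(rec)
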