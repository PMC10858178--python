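"""Brute-force alignment oracle shared by the aligner and acceptance tests.

Scans every placement of a read on every contig and strand and recomputes
the best full score (under the mismatch-rate gate) and the best
prefix+suffix partition score under the same segment constraints as the
aligner -- independently of the seed-and-extend path it checks.
"""

import numpy as np

from provmap import dna


def oracle_profiles(refset, read):
    """Match/mismatch profiles (+1/-1, read orientation) of every placement."""
    L = len(read)
    enc_read = dna.encode(read)
    enc_rc = dna.revcomp_enc(dna.encode(read))
    profs = []
    for contig in refset.contigs:
        enc = dna.encode(contig.sequence)
        if len(enc) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        for m in (win == enc_read[None, :]) * 2 - 1:
            profs.append(m)
        for m in (win == enc_rc[None, :]) * 2 - 1:
            profs.append(m[::-1])  # back to read orientation
    return profs


def oracle_best(refset, read, params):
    """Best rate-gated full score and best split score over all placements."""
    L = len(read)
    profs = oracle_profiles(refset, read)
    best_full = None
    P, M = [], []
    for prof in profs:
        score = int(prof.sum())
        mism = int((prof == -1).sum())
        if mism / L <= params.max_mismatch_rate:
            best_full = score if best_full is None else max(best_full, score)
        P.append(np.concatenate(([0], np.cumsum(prof))))
        M.append(np.concatenate(([0], np.cumsum(prof == -1))))
    P = np.array(P)
    M = np.array(M)
    js = np.arange(params.min_seg, L - params.min_seg + 1)
    pref = np.where(M[:, js] <= params.max_mismatch_rate * js, P[:, js], -np.inf)
    suf_m = M[:, [L]] - M[:, js]
    suf = np.where(
        suf_m <= params.max_mismatch_rate * (L - js), P[:, [L]] - P[:, js], -np.inf
    )
    tot = pref.max(axis=0) + suf.max(axis=0) + params.split_penalty
    best_split = None if not np.isfinite(tot).any() else int(tot.max())
    return best_full, best_split
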