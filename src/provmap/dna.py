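"""Nucleotide encodings shared across modules.

Bases are encoded A=0, C=1, G=2, T=3; anything else (including N and the
padding used by the aligner) is 4.  Code 4 never compares equal to a real
base in scoring, so N and padding behave as guaranteed mismatches without
special-casing.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = "ACGT"

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 .. T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    """Decode uint8 codes back to an upper-case DNA string."""
    a = np.asarray(arr, dtype=np.uint8)
    return _DEC[np.minimum(a, N)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPL)[::-1]


def revcomp_enc(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded array; code 4 is self-complementary."""
    out = np.asarray(arr)[::-1].copy()
    real = out < N
    out[real] = 3 - out[real]
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def phred_to_ascii(quals) -> str:
    """Integer Phred scores -> Phred+33 quality string."""
    q = np.asarray(quals, dtype=np.int16)
    return (q + 33).astype(np.uint8).tobytes().decode("ascii")


def ascii_to_phred(qstr: str) -> np.ndarray:
    """Phred+33 quality string -> integer scores."""
    return np.frombuffer(qstr.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
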