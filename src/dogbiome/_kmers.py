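"""Vectorized 2-bit k-mer encoding shared by the host screen and the mapper.

Bases map to 2-bit codes (A=0, C=1, G=2, T=3); a k-mer is the base-4 integer
of its codes, which fits in uint64 for k <= 31. Windows containing any
non-ACGT base are reported as invalid rather than silently encoded.
"""

from __future__ import annotations

import numpy as np

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE_TABLE[base] = i
    _CODE_TABLE[ord(chr(base).lower())] = i

COMPLEMENT = 3  # complement code = 3 - code


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """2-bit codes of a sequence; non-ACGT bases become 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE_TABLE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (COMPLEMENT - codes[::-1].astype(np.int16)).astype(np.uint8)


def encode_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping k-mers of a code array as uint64, plus a validity mask.

    Returns (kmers, valid) of length len(codes) - k + 1; empty arrays when the
    sequence is shorter than k.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    clean = np.where(codes > 3, 0, codes).astype(np.uint64)
    kmers = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        kmers = (kmers << np.uint64(2)) | clean[i : i + n]
    bad = (codes > 3).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return kmers, valid


def canonical_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical k-mers: elementwise min of forward and reverse-complement."""
    fwd, valid_f = encode_kmers(codes, k)
    rc, valid_r = encode_kmers(revcomp_codes(codes), k)
    if len(fwd) == 0:
        return fwd, valid_f
    rc = rc[::-1]  # align rc k-mer i with forward k-mer i
    return np.minimum(fwd, rc), valid_f & valid_r[::-1]
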