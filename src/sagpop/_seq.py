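"""Low-level sequence helpers shared across stages.

Sequences travel as Python strings over {A,C,G,T,N} at module boundaries;
internally they are encoded to small integer arrays (A=0, C=1, G=2, T=3,
N=4) so that k-mer extraction, mismatch counting and consensus calls are
vectorized.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer k-mer at every position (length len-k+1); -1 where the
    window contains a non-ACGT code."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        col = codes[i : i + n].astype(np.int64)
        bad |= col >= 4
        vals = vals * 4 + np.where(col >= 4, 0, col)
    vals[bad] = -1
    return vals


def sliding_mismatches(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of `query` against every window of `target`.

    Non-ACGT codes never match. Returns array of length
    len(target) - len(query) + 1 (empty if query is longer).
    """
    m = query.size
    n = target.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(m):
        col = target[i : i + n]
        out += (col != query[i]) | (col >= 4) | (query[i] >= 4)
    return out
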