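"""Small DNA utilities shared across the package.

Bases are handled in two representations: Python strings over {A,C,G,T,N}
and numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4). Code arrays are the
working representation for pileups and the simulator; strings appear only at
file-format boundaries.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

# byte value -> code, everything unexpected maps to N
_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def phred_to_string(quals: np.ndarray) -> str:
    """Phred scores -> FASTQ quality string (offset 33, capped at 93)."""
    q = np.clip(np.asarray(quals, dtype=np.int64), 0, 93)
    return (q + 33).astype(np.uint8).tobytes().decode("ascii")


def string_to_phred(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def homopolymer_run_length(codes: np.ndarray, pos: int) -> int:
    """Length of the maximal single-base run containing position ``pos``."""
    b = codes[pos]
    i = pos
    while i > 0 and codes[i - 1] == b:
        i -= 1
    j = pos
    n = len(codes)
    while j + 1 < n and codes[j + 1] == b:
        j += 1
    return j - i + 1
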