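"""Nucleotide sequence helpers.

Sequences are held internally as ``numpy.uint8`` arrays with the coding
A=0, C=1, G=2, T=3; ambiguous bases (anything else, typically N) are
coded 4 and skipped by the PWM scanner.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
AMBIGUOUS_CODE = 4

_ENCODE = np.full(256, AMBIGUOUS_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string (4 -> N)."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def as_codes(seq) -> np.ndarray:
    """Coerce a str or code array to a uint8 code array."""
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array; ambiguous bases stay ambiguous."""
    codes = np.asarray(codes, dtype=np.uint8)
    comp = np.where(codes < 4, 3 - codes, codes)
    return comp[::-1]


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """I.i.d. random sequence with the given GC fraction (default uniform)."""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(4, size=length, p=p).astype(np.uint8)
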