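"""Nucleotide encoding helpers shared across modules.

Bases are stored as uint8 codes in alphabetical order (A=0, C=1, G=2, T=3),
so that ``argmax`` over per-base counts breaks ties toward the
lexicographically smallest base.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: code -> base letter, for building character matrices
BASE_CHARS = np.array(list("ACGT"), dtype="U1")
#: code -> complement code (A<->T, C<->G)
COMPLEMENT = np.array([T, G, C, A], dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string into uint8 codes; reject other characters."""
    raw = seq.encode() if isinstance(seq, str) else seq
    codes = _ENCODE[np.frombuffer(raw, dtype=np.uint8)]
    if (codes == 255).any():
        bad = raw[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {chr(bad)!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode uint8 base codes back into an ACGT string."""
    return BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded sequence."""
    return COMPLEMENT[codes[::-1]]
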