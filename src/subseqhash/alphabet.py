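"""DNA alphabet and 2-bit encoding helpers.

The whole package works over the four-letter DNA alphabet with the
lexicographic order A < C < G < T.  Sequences are internally encoded as
int8 arrays with codes A=0, C=1, G=2, T=3; any other character maps to -1
and invalidates every window that contains it.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
SIGMA = 4

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a string as int8 codes (A=0..T=3, -1 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes) -> str:
    """Inverse of :func:`encode` for valid codes."""
    return "".join(ALPHABET[c] for c in codes)


def check_dna(seq: str, what: str = "sequence") -> np.ndarray:
    """Encode and require every character to be in ACGT."""
    codes = encode(seq)
    if len(codes) and codes.min() < 0:
        bad = seq[int(np.argmin(codes >= 0))]
        raise ValueError(f"{what} contains non-ACGT character {bad!r}")
    return codes
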