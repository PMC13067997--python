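"""Nucleotide alphabet, encoding and sanitization helpers.

The index works over the ordered alphabet ``$ < A < C < G < T`` where ``$``
is a unique terminator that sorts before every nucleotide.  Internally
characters are stored as small integer codes (``$``=0 .. ``T``=4) so that
suffix sorting and rank computations can run on numpy arrays.
"""

from __future__ import annotations

import re

import numpy as np

TERMINATOR = "$"
ALPHABET = "$ACGT"
SIGMA = len(ALPHABET)

CHAR_TO_CODE = {c: i for i, c in enumerate(ALPHABET)}
CODE_TO_CHAR = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile(r"[^ACGT]+")

# 256-entry lookup: ASCII byte -> code, -1 for anything outside {$,A,C,G,T}
_BYTE_TO_CODE = np.full(256, -1, dtype=np.int8)
for _c, _i in CHAR_TO_CODE.items():
    _BYTE_TO_CODE[ord(_c)] = _i


def encode(text: str) -> np.ndarray:
    """Encode a ``$ACGT`` string into int8 codes."""
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    if (codes < 0).any():
        bad = text[int(np.argmax(codes < 0))]
        raise ValueError(f"character {bad!r} outside alphabet {ALPHABET!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return CODE_TO_CHAR[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str) -> list[str]:
    """Split a raw sequence at non-ACGT characters.

    Ambiguity codes (N, R, Y, ...) are never converted into concrete bases;
    the sequence is upper-cased and broken into clean ACGT fragments at every
    stretch of disallowed characters.  Empty fragments are dropped.
    """
    return [frag for frag in _NON_ACGT.split(seq.upper()) if frag]
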