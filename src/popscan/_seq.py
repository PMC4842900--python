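"""Low-level nucleotide sequence helpers shared across modules.

Sequences cross module boundaries as plain Python strings over {A,C,G,T};
internally the aligner works on uint8 code arrays (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII byte -> 2-bit code; anything outside ACGT maps to 255 (never matches).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of 2-bit codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """Draw an i.i.d. nucleotide string with the given expected GC content."""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return decode(codes)


def substitute(
    codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Return a copy with the given positions replaced by a *different* base.

    The replacement is drawn uniformly from the three non-original bases, so
    every flagged position is a true substitution.
    """
    out = codes.copy()
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
        out[positions] = (out[positions] + shift) % 4
    return out


def gc_content(seq: str) -> float:
    codes = encode(seq)
    return float(np.count_nonzero((codes == 1) | (codes == 2)) / codes.size)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All overlapping k-mers of a code array packed into uint64 integers.

    Windows containing a non-ACGT base are returned as the sentinel 2**63
    (which cannot collide with a packed k-mer for k <= 31).
    """
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    packed = windows.astype(np.uint64) @ powers
    bad = (windows == 255).any(axis=1)
    if bad.any():
        packed = packed.copy()
        packed[bad] = np.uint64(1) << np.uint64(63)
    return packed
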