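"""Shared nucleotide-sequence primitives.

Sequences are held in two interchangeable representations:

* *codes*: ``numpy.uint8`` arrays with A=0, C=1, G=2, T=3 (N=4 where an
  unknown state is allowed) — used for all numerical work;
* *bytes*: upper-case ASCII ``bytes`` — used for k-mer dictionary keys and
  on-disk formats.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"
N_CODE = np.uint8(4)
ALPHABET = b"ACGTN"

# ASCII byte -> code lookup (255 = invalid)
ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    ENCODE[_b] = _i
    ENCODE[_b + 32] = _i  # lower case

DECODE = np.frombuffer(ALPHABET, dtype=np.uint8)

# code -> complement code (N stays N)
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

RC_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT(N) string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode()
    codes = ENCODE[np.frombuffer(seq, dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid nucleotide {chr(seq[bad])!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an ACGTN string."""
    return DECODE[codes].tobytes().decode()


def to_bytes(codes: np.ndarray) -> bytes:
    return DECODE[codes].tobytes()


def revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP_CODE[codes][::-1]


def canonical(kmer: bytes) -> bytes:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = kmer.translate(RC_TABLE)[::-1]
    return kmer if kmer <= rc else rc


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform ACGT code array of the given length."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)
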