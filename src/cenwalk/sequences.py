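"""Core sequence records and nucleotide utilities.

All coordinates in this package are 1-based and inclusive, matching NCBI
interval notation (``chr11:27592872-28352430``).  Conversion to 0-based
half-open coordinates happens only at BED/bedGraph boundaries in
:mod:`cenwalk.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

ALPHABET = frozenset("ACGTN")

#: ASCII byte -> internal code (A=0, C=1, G=2, T=3, N=4; 255 = invalid)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8).copy()
#: complement in code space (A<->T, C<->G, N->N)
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_RC_TRANS = str.maketrans("ACGTN", "TGCAN")


class ReadPair(NamedTuple):
    """A paired-end read: mate 1 and mate 2 as sequenced (5'->3')."""

    id: str
    seq1: str
    seq2: str


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-ACGTN symbols: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Raises ``ValueError`` for any other symbol.
    """
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement symbols {sorted(bad)!r}")
    return seq.translate(_RC_TRANS)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array (A=0..N=4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max(initial=0) == 255:
        raise ValueError("sequence contains non-ACGTN symbols")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for codes in 0..4."""
    return _ASCII[codes].tobytes().decode("ascii")


def encode_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    joined = "".join(seqs).encode("ascii")
    arr = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    try:
        return arr.reshape(len(seqs), length)
    except ValueError as exc:  # ragged input
        raise ValueError("encode_matrix requires equal-length sequences") from exc


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode an (n, L) code matrix back to a list of strings."""
    if mat.size == 0:
        return []
    n, length = mat.shape
    raw = _ASCII[mat].tobytes().decode("ascii")
    return [raw[i * length : (i + 1) * length] for i in range(n)]


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of a code matrix."""
    return COMP_CODE[mat][:, ::-1]
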