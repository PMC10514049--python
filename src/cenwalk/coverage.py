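"""Normalized ChIP-minus-input signal tracks.

The profiling chain is: place each mate at its unique best position
(exact seed, bounded-mismatch verification, ties discarded), count mate
starts into fixed-size bins, normalize each library to RPKM (reads per
kilobase per million mapped reads), and subtract the input track from
the ChIP track, keeping negative values.

The aligner is deliberately minimal — ungapped, substitution-only,
deterministic — because the package's subject is what happens *after*
alignment; discarding multi-mapping ties (rather than placing them
randomly) is exactly what makes a falsely duplicated reference visible
as a coverage hole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequences import (
    ReadPair,
    SequenceRecord,
    encode,
    encode_matrix,
    revcomp_matrix,
)

__all__ = [
    "AlignmentRecord",
    "CoverageTrack",
    "GenomeIndex",
    "align_reads_minimal",
    "pair_fragments",
    "count_bins",
    "rpkm_normalize",
    "subtract_tracks",
    "mates_of",
]

_BASE5 = 5  # code alphabet size for seed hashing (A,C,G,T,N)


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped unique-best placement of one mate."""

    read_id: str
    contig: str
    start: int  # 1-based leftmost
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"
    n_mismatch: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("alignment start > end")
        if self.n_mismatch < 0:
            raise ValueError("negative mismatch count")


@dataclass
class CoverageTrack:
    """Dense binned signal over one contig, from position 1."""

    contig: str
    bin_size: int
    values: np.ndarray
    kind: str  # "raw" | "rpkm" | "difference"
    total_mapped: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = np.asarray(self.values)
        if self.kind == "raw":
            if np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def mates_of(reads: Sequence) -> list[tuple[str, str]]:
    """Flatten pairs into individually mappable mates.

    Accepts :class:`ReadPair` items (mates get ``/1``/``/2`` suffixes)
    or pre-flattened ``(id, sequence)`` tuples.
    """
    mates: list[tuple[str, str]] = []
    for r in reads:
        if isinstance(r, ReadPair):
            mates.append((f"{r.id}/1", r.seq1))
            mates.append((f"{r.id}/2", r.seq2))
        else:
            rid, seq = r
            mates.append((rid, seq))
    return mates


class GenomeIndex:
    """Exact seed index over every ``seed_len``-mer of the genome.

    Seeds are packed base-5 into int64 (exact, collision-free for
    ``seed_len`` <= 27); windows containing N are excluded.
    """

    def __init__(self, genome: Sequence[SequenceRecord], seed_len: int = 24):
        if not 8 <= seed_len <= 27:
            raise ValueError("seed_len must be in [8, 27]")
        self.seed_len = seed_len
        self.names = [r.id for r in genome]
        self.lengths = np.array([len(r) for r in genome], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.codes = np.concatenate(
            [encode(r.sequence) for r in genome]
            + [np.full(512, 255, dtype=np.uint8)]  # tail pad, never matches
        )
        w = _BASE5 ** np.arange(seed_len - 1, -1, -1, dtype=np.int64)
        self._weights = w
        hashes = []
        positions = []
        for i, rec in enumerate(genome):
            arr = self.codes[self.offsets[i] : self.offsets[i] + len(rec)]
            if len(arr) < seed_len:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, seed_len)
            valid = (win < 4).all(axis=1)
            h = win.astype(np.int64) @ w
            pos = np.nonzero(valid)[0] + self.offsets[i]
            hashes.append(h[valid])
            positions.append(pos)
        h_all = np.concatenate(hashes) if hashes else np.empty(0, np.int64)
        p_all = np.concatenate(positions) if positions else np.empty(0, np.int64)
        order = np.argsort(h_all, kind="stable")
        self._h = h_all[order]
        self._pos = p_all[order]

    def hash_seeds(self, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(hash, valid) for the first ``seed_len`` columns of each row."""
        k = self.seed_len
        sub = mat[:, :k].astype(np.int64)
        valid = (sub < 4).all(axis=1)
        return sub @ self._weights, valid

    def candidates(
        self, hashes: np.ndarray, valid: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(row_index, genome_position) of every seed match."""
        h = np.where(valid, hashes, -1)
        lo = np.searchsorted(self._h, h, side="left")
        hi = np.searchsorted(self._h, h, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        rows = np.repeat(np.arange(len(h)), counts)
        flat = np.repeat(lo, counts) + (
            np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        )
        return rows, self._pos[flat]

    def contig_of(self, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, pos, side="right") - 1


def align_reads_minimal(
    reads: Sequence,
    genome: Sequence[SequenceRecord],
    seed_len: int = 24,
    max_mismatch: int = 3,
    index: GenomeIndex | None = None,
) -> list[AlignmentRecord]:
    """Unique best ungapped placement of every mate.

    The first ``seed_len`` bases (in each orientation) must match the
    genome exactly; the full mate is then verified with at most
    ``max_mismatch`` substitutions.  A mate with no placement, or with
    two equally good best placements, is unmapped — a normal outcome,
    simply absent from the output.
    """
    if index is None:
        index = GenomeIndex(genome, seed_len)
    mates = mates_of(reads)
    if not mates:
        return []
    out: list[AlignmentRecord] = []
    by_len: dict[int, list[int]] = {}
    for i, (_, seq) in enumerate(mates):
        by_len.setdefault(len(seq), []).append(i)
    for length, idxs in by_len.items():
        if length < index.seed_len:
            continue
        sub = [mates[i] for i in idxs]
        out.extend(_align_group(sub, index, max_mismatch))
    out.sort(key=lambda a: (a.contig, a.start, a.read_id))
    return out


def _align_group(
    mates: list[tuple[str, str]], index: GenomeIndex, max_mismatch: int
) -> list[AlignmentRecord]:
    L = len(mates[0][1])
    fwd = encode_matrix([seq for _, seq in mates])
    rev = revcomp_matrix(fwd)
    # recode read N so it never matches anything (including genome N)
    fwd = np.where(fwd == 4, 250, fwd)
    rev = np.where(rev == 4, 250, rev)

    rows_all, pos_all, strand_all = [], [], []
    for strand_code, mat in ((0, fwd), (1, rev)):
        h, valid = index.hash_seeds(mat)
        rows, pos = index.candidates(h, valid)
        rows_all.append(rows)
        pos_all.append(pos)
        strand_all.append(np.full(len(rows), strand_code, dtype=np.int8))
    rows = np.concatenate(rows_all)
    pos = np.concatenate(pos_all)
    strand = np.concatenate(strand_all)
    if len(rows) == 0:
        return []

    ci = index.contig_of(pos)
    local0 = pos - index.offsets[ci]
    ok = local0 + L <= index.lengths[ci]
    rows, pos, strand, ci, local0 = (
        rows[ok],
        pos[ok],
        strand[ok],
        ci[ok],
        local0[ok],
    )
    if len(rows) == 0:
        return []
    win = index.codes[pos[:, None] + np.arange(L)]
    query = np.where(strand[:, None] == 0, fwd[rows], rev[rows])
    nm = (win != query).sum(axis=1)
    ok = nm <= max_mismatch
    rows, strand, ci, local0, nm = (
        rows[ok],
        strand[ok],
        ci[ok],
        local0[ok],
        nm[ok],
    )
    if len(rows) == 0:
        return []

    order = np.lexsort((local0, nm, rows))
    rows, strand, ci, local0, nm = (
        rows[order],
        strand[order],
        ci[order],
        local0[order],
        nm[order],
    )
    first = np.ones(len(rows), dtype=bool)
    first[1:] = rows[1:] != rows[:-1]
    # tie: the entry right after a 'first' belongs to the same row with
    # the same mismatch count
    tie = np.zeros(len(rows), dtype=bool)
    same_row = ~first
    same_nm = np.zeros(len(rows), dtype=bool)
    same_nm[1:] = nm[1:] == nm[:-1]
    tie[:-1] = first[:-1] & same_row[1:] & same_nm[1:] if len(rows) > 1 else False
    keep = first & ~tie

    out = []
    for j in np.nonzero(keep)[0]:
        i = int(rows[j])
        out.append(
            AlignmentRecord(
                read_id=mates[i][0],
                contig=index.names[int(ci[j])],
                start=int(local0[j]) + 1,
                end=int(local0[j]) + L,
                strand="-" if strand[j] else "+",
                n_mismatch=int(nm[j]),
            )
        )
    return out


def pair_fragments(
    alignments: Sequence[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Collapse mate alignments into one record per sequenced fragment.

    Mates sharing a read id (up to a ``/1``/``/2`` suffix) on the same
    contig merge into a fragment spanning both; a lone mapped mate
    stands for its fragment.  Mates of one pair on different contigs
    are discordant and dropped.  Fragment counting removes the
    within-pair correlation that mate-level counts carry into
    island statistics.
    """
    by_id: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        base = a.read_id[:-2] if a.read_id.endswith(("/1", "/2")) else a.read_id
        by_id.setdefault(base, []).append(a)
    frags: list[AlignmentRecord] = []
    for base, alns in sorted(by_id.items()):
        if len({a.contig for a in alns}) != 1:
            continue
        frags.append(
            AlignmentRecord(
                read_id=base,
                contig=alns[0].contig,
                start=min(a.start for a in alns),
                end=max(a.end for a in alns),
                strand=alns[0].strand,
                n_mismatch=sum(a.n_mismatch for a in alns),
            )
        )
    return frags


def count_bins(
    alignments: Sequence[AlignmentRecord],
    contig: str,
    contig_length: int,
    bin_size: int = 50,
    total_mapped: int | None = None,
    at: str = "start",
) -> CoverageTrack:
    """Raw counts: each record adds 1 to the bin containing its leftmost
    coordinate (``at="start"``, the default) or its midpoint
    (``at="midpoint"``, the natural choice for fragment records).
    ``total_mapped`` defaults to the full library (all contigs), which
    is what RPKM normalization wants.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if at not in ("start", "midpoint"):
        raise ValueError("at must be 'start' or 'midpoint'")
    n_bins = -(-contig_length // bin_size)
    if at == "start":
        starts = np.array(
            [a.start for a in alignments if a.contig == contig], dtype=np.int64
        )
    else:
        starts = np.array(
            [(a.start + a.end) // 2 for a in alignments if a.contig == contig],
            dtype=np.int64,
        )
    if len(starts):
        values = np.bincount((starts - 1) // bin_size, minlength=n_bins)
    else:
        values = np.zeros(n_bins, dtype=np.int64)
    return CoverageTrack(
        contig=contig,
        bin_size=bin_size,
        values=values.astype(np.int64),
        kind="raw",
        total_mapped=total_mapped if total_mapped is not None else len(alignments),
    )


def rpkm_normalize(
    track: CoverageTrack, total_mapped: int | None = None
) -> CoverageTrack:
    """RPKM: count / ((bin_size/1000) * (total_mapped/1e6))."""
    tm = total_mapped if total_mapped is not None else track.total_mapped
    if tm < 1:
        raise ValueError("total_mapped must be >= 1")
    values = track.values / ((track.bin_size / 1000) * (tm / 1e6))
    return CoverageTrack(
        contig=track.contig,
        bin_size=track.bin_size,
        values=values,
        kind="rpkm",
        total_mapped=tm,
    )


def subtract_tracks(chip: CoverageTrack, input_: CoverageTrack) -> CoverageTrack:
    """ChIP minus input, negatives preserved (subtractive normalization)."""
    if (
        chip.contig != input_.contig
        or chip.bin_size != input_.bin_size
        or len(chip) != len(input_)
    ):
        raise ValueError("tracks must share contig, bin size and length")
    return CoverageTrack(
        contig=chip.contig,
        bin_size=chip.bin_size,
        values=chip.values - input_.values,
        kind="difference",
        total_mapped=chip.total_mapped,
    )
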