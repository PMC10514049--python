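"""Reference patching: excise a locus, splice in a walked contig, and
keep the books straight.

Replacing an interval of a chromosome shifts every downstream
coordinate, so the patcher emits an ordered block liftover map that
translates positions between the original and patched assemblies.
Assembly quality is summarised as N nucleotides per 100 kb, and the
single-copy vs duplicated structure of the patched locus is adjudicated
by counting long reads that span the diagnostic junction of each
candidate structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .sequences import SequenceRecord, reverse_complement

__all__ = [
    "GenomicInterval",
    "AssemblyStats",
    "LiftoverMap",
    "StructureSupport",
    "interval_length",
    "assembly_stats",
    "replace_interval",
    "lift",
    "validate_structure",
]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Length of a 1-based inclusive interval: ``end - start + 1``."""
    return len(iv)


@dataclass(frozen=True)
class AssemblyStats:
    length: int
    n_count: int
    n_per_100kb: float


def assembly_stats(seq: str | SequenceRecord) -> AssemblyStats:
    """Length, N count, and N per 100 kb (rounded to 2 decimals)."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("cannot compute assembly stats of an empty sequence")
    n = s.count("N")
    return AssemblyStats(
        length=len(s),
        n_count=n,
        n_per_100kb=round(n * 100_000 / len(s), 2),
    )


class LiftoverMap:
    """Ordered old -> new coordinate blocks, one list per contig.

    Each block is ``(old_start, old_end, new_start)`` with
    ``new_start is None`` marking deletion.  Blocks are sorted and
    non-overlapping; within a block the shift is constant.
    """

    def __init__(
        self, blocks: dict[str, list[tuple[int, int, int | None]]]
    ):
        self.blocks: dict[str, list[tuple[int, int, int | None]]] = {}
        for contig, blist in blocks.items():
            blist = sorted(blist)
            for (s1, e1, _), (s2, _, _) in zip(blist, blist[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping liftover blocks on {contig}"
                    )
            self.blocks[contig] = blist

    def lift(self, contig: str, pos: int) -> int | None:
        """New coordinate of an old position, or None if deleted."""
        if contig not in self.blocks:
            raise KeyError(f"unknown contig {contig!r}")
        for old_start, old_end, new_start in self.blocks[contig]:
            if old_start <= pos <= old_end:
                if new_start is None:
                    return None
                return new_start + (pos - old_start)
        raise ValueError(
            f"position {contig}:{pos} outside the mapped old contig"
        )

    def to_rows(self) -> list[tuple[str, int, int, str]]:
        rows = []
        for contig, blist in self.blocks.items():
            for old_start, old_end, new_start in blist:
                rows.append(
                    (
                        contig,
                        old_start,
                        old_end,
                        "deleted" if new_start is None else str(new_start),
                    )
                )
        return rows


def lift(liftover: LiftoverMap, contig: str, pos: int) -> int | None:
    """Functional alias for :meth:`LiftoverMap.lift`."""
    return liftover.lift(contig, pos)


def replace_interval(
    genome: Sequence[SequenceRecord],
    iv: GenomicInterval,
    new_seq: str | SequenceRecord,
    drop_contigs: Iterable[str] = (),
) -> tuple[list[SequenceRecord], LiftoverMap]:
    """Excise ``iv`` from its contig, splice in ``new_seq``, and drop
    redundant contigs; returns the patched genome and its liftover map.

    Positions before the interval map identically, positions after it
    shift by ``len(new_seq) - len(iv)``, positions inside map to
    deleted.  Dropped contigs are wholly deleted.
    """
    new_s = new_seq.sequence if isinstance(new_seq, SequenceRecord) else new_seq
    if not new_s:
        raise ValueError("replacement sequence is empty")
    drop = set(drop_contigs)
    names = {r.id for r in genome}
    missing = drop - names
    if missing:
        raise ValueError(f"drop contigs not present: {sorted(missing)!r}")
    if iv.contig not in names:
        raise ValueError(f"target contig {iv.contig!r} not in genome")

    patched: list[SequenceRecord] = []
    blocks: dict[str, list[tuple[int, int, int | None]]] = {}
    for rec in genome:
        if rec.id in drop:
            blocks[rec.id] = [(1, len(rec), None)]
            continue
        if rec.id != iv.contig:
            patched.append(rec)
            blocks[rec.id] = [(1, len(rec), 1)]
            continue
        if iv.end > len(rec):
            raise ValueError(
                f"interval end {iv.end} beyond contig {rec.id!r} "
                f"({len(rec)} nt)"
            )
        seq = rec.sequence
        out = seq[: iv.start - 1] + new_s + seq[iv.end :]
        patched.append(SequenceRecord(rec.id, out, rec.description))
        shift = len(new_s) - len(iv)
        blist: list[tuple[int, int, int | None]] = []
        if iv.start > 1:
            blist.append((1, iv.start - 1, 1))
        blist.append((iv.start, iv.end, None))
        if iv.end < len(rec):
            blist.append((iv.end + 1, len(rec), iv.end + 1 + shift))
        blocks[rec.id] = blist
    return patched, LiftoverMap(blocks)


@dataclass(frozen=True)
class StructureSupport:
    support_single: int
    support_dup: int


def _diagnostic_window(
    seq: str, lcp: int, lcs: int, anchor_len: int
) -> tuple[int, int]:
    """1-based window around the differing region of one candidate."""
    lo = min(lcp + 1, len(seq) - lcs + 1)
    hi = max(lcp, len(seq) - lcs)
    start = max(1, lo - anchor_len)
    end = min(len(seq), hi + anchor_len)
    return start, end


def _count_once(hay: str, needle: str) -> int:
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i == -1:
            return count
        count += 1
        start = i + 1


def validate_structure(
    candidate_single: str | SequenceRecord,
    candidate_dup: str | SequenceRecord,
    long_reads: Sequence[SequenceRecord],
    anchor_len: int = 500,
    max_mismatch_frac: float = 0.0,
) -> StructureSupport:
    """Count long reads spanning the diagnostic junction of each
    candidate structure.

    The two candidates are assumed to share flanking anchors around the
    region in which they differ (a single-copy block vs a tandem
    duplication).  The diagnostic string of each candidate is the
    differing region extended by ``anchor_len`` on both sides; a long
    read supports a structure when it contains that string exactly
    (``max_mismatch_frac = 0``) or within the stated edit fraction.
    A read supports at most one structure; ambiguous reads support none.
    """
    s1 = (
        candidate_single.sequence
        if isinstance(candidate_single, SequenceRecord)
        else candidate_single
    )
    s2 = (
        candidate_dup.sequence
        if isinstance(candidate_dup, SequenceRecord)
        else candidate_dup
    )
    if s1 == s2:
        raise ValueError("candidate structures are identical")
    lcp = 0
    m = min(len(s1), len(s2))
    while lcp < m and s1[lcp] == s2[lcp]:
        lcp += 1
    lcs = 0
    while lcs < m - 1 and s1[len(s1) - 1 - lcs] == s2[len(s2) - 1 - lcs]:
        lcs += 1
    w1 = _diagnostic_window(s1, lcp, lcs, anchor_len)
    w2 = _diagnostic_window(s2, lcp, lcs, anchor_len)
    diag1 = s1[w1[0] - 1 : w1[1]]
    diag2 = s2[w2[0] - 1 : w2[1]]
    for diag, owner in ((diag1, s1), (diag2, s2)):
        if _count_once(owner, diag) != 1:
            raise ValueError(
                "diagnostic anchors are not unique within the candidate"
            )

    def distance(read: str, diag: str, k: int) -> int:
        best = -1
        for probe in (read, reverse_complement(read)):
            if k == 0:
                if diag in probe:
                    return 0
                continue
            res = edlib.align(diag, probe, mode="HW", task="distance", k=k)
            d = res["editDistance"]
            if d != -1 and (best == -1 or d < best):
                best = d
        return best

    n_single = n_dup = 0
    for rec in long_reads:
        read = rec.sequence if isinstance(rec, SequenceRecord) else str(rec)
        k1 = int(max_mismatch_frac * len(diag1))
        k2 = int(max_mismatch_frac * len(diag2))
        d1 = distance(read, diag1, k1)
        d2 = distance(read, diag2, k2)
        if d1 != -1 and (d2 == -1 or d1 < d2):
            n_single += 1
        elif d2 != -1 and (d1 == -1 or d2 < d1):
            n_dup += 1
        # d1 == d2 != -1: ambiguous, supports neither
    return StructureSupport(support_single=n_single, support_dup=n_dup)
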