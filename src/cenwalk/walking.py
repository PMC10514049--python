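"""Iterative chromosome walking from joined paired-end reads.

The walker closes gaps and re-derives misassembled regions by the
classic read-walking loop: design a query from the end of the known
sequence, retrieve every read containing the query verbatim (either
orientation, either mate), build a majority-vote consensus of the bases
those reads carry beyond the query, extend the known sequence, redesign
the query, and repeat.  Two walks converging from the flanks of a gap
are merged when they agree exactly over a minimum overlap.

Query matching is exact (no mismatches): error tolerance is delegated
entirely to the consensus vote, which requires a minimum read support
and a minimum agreement fraction per column.  Columns where two bases
are each well supported are reported as branch events and stop the walk
rather than silently choosing one branch — tandem duplications and
heterozygous sites surface to the caller this way.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequences import ReadPair, SequenceRecord, reverse_complement

__all__ = [
    "JoinedRead",
    "QueryHit",
    "WalkParams",
    "WalkResult",
    "BranchEvent",
    "GapClosure",
    "ResolveResult",
    "QueryIndex",
    "WalkError",
    "join_pairs",
    "find_reads_by_query",
    "extend_consensus",
    "walk",
    "close_gap",
    "resolve_region",
]

QUERY_RANGE = (60, 95)


class WalkError(RuntimeError):
    """A walk could not be started or continued."""


@dataclass(frozen=True)
class JoinedRead:
    """A searchable read pair; both mates are queried independently."""

    id: str
    mate1: str
    mate2: str

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise ValueError(f"joined read {self.id!r} has an empty mate")

    def mate(self, index: int) -> str:
        return self.mate1 if index == 1 else self.mate2


@dataclass(frozen=True, order=True)
class QueryHit:
    """One exact occurrence of a query (or its reverse complement)."""

    read_id: str
    mate: int  # 1 or 2
    offset: int  # 0-based position of the match within the mate
    orientation: str = "F"  # "F": query as-is; "RC": revcomp(query) in mate


@dataclass(frozen=True)
class WalkParams:
    query_len: int = 75
    min_support: int = 5
    min_agreement: float = 0.8
    branch_fraction: float = 0.3
    max_iterations: int = 500
    min_merge_overlap: int = 100

    def __post_init__(self) -> None:
        if not 0.5 < self.min_agreement <= 1.0:
            raise ValueError("min_agreement must be in (0.5, 1]")
        if self.branch_fraction >= self.min_agreement:
            raise ValueError("branch_fraction must be < min_agreement")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.query_len < 1:
            raise ValueError("query_len must be positive")


@dataclass(frozen=True)
class BranchEvent:
    """Conflicting, well-supported bases at one consensus column."""

    position: int  # 0-based column in the final walk sequence
    base_counts: dict[str, int] = field(hash=False, default_factory=dict)


@dataclass
class WalkResult:
    sequence: str
    status: str  # "open" | "branched" | "max_iter" | "closed"
    iterations: int
    support: list[int]  # per extended column, aligned with the extension
    branch_events: list[BranchEvent]


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2", "_1", "_2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def join_pairs(
    reads1: Iterable, reads2: Iterable | None = None
) -> list[JoinedRead]:
    """Pair up mates into searchable :class:`JoinedRead` units.

    Accepts either a single iterable of :class:`ReadPair` or two
    parallel iterables of ``(id, sequence)`` records (R1 and R2 files).
    Mates are matched by id after stripping ``/1``-style suffixes; any
    orphan mate is an error listing the offending ids.
    """
    if reads2 is None:
        return [JoinedRead(r.id, r.seq1, r.seq2) for r in reads1]
    m1 = {_strip_mate_suffix(rid): seq for rid, seq in reads1}
    m2 = {_strip_mate_suffix(rid): seq for rid, seq in reads2}
    orphans = sorted(set(m1) ^ set(m2))
    if orphans:
        raise ValueError(f"orphan mates without a partner: {orphans[:10]!r}")
    return [JoinedRead(rid, m1[rid], m2[rid]) for rid in m1]


class QueryIndex:
    """Exact-substring index over all fixed-length windows of the mates.

    Lookup of a query returns the same hits as a brute-force scan of
    every mate in both orientations, in deterministic order.
    """

    def __init__(self, reads: Sequence[JoinedRead], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.reads = list(reads)
        self.read_map: dict[str, JoinedRead] = {r.id: r for r in self.reads}
        table: dict[str, list[tuple[str, int, int]]] = {}
        for r in self.reads:
            for mate_idx, seq in ((1, r.mate1), (2, r.mate2)):
                for off in range(len(seq) - k + 1):
                    table.setdefault(seq[off : off + k], []).append(
                        (r.id, mate_idx, off)
                    )
        self._table = table

    def find(self, query: str) -> list[QueryHit]:
        if len(query) != self.k:
            raise ValueError(
                f"index built for queries of length {self.k}, got {len(query)}"
            )
        hits: dict[tuple[str, int, int], QueryHit] = {}
        for rid, mate, off in self._table.get(query, ()):
            hits[(rid, mate, off)] = QueryHit(rid, mate, off, "F")
        for rid, mate, off in self._table.get(reverse_complement(query), ()):
            hits.setdefault((rid, mate, off), QueryHit(rid, mate, off, "RC"))
        return sorted(hits.values())


def _validate_query(query: str) -> None:
    if "N" in query:
        raise WalkError("query contains N and cannot anchor a walk")
    lo, hi = QUERY_RANGE
    if not lo <= len(query) <= hi:
        warnings.warn(
            f"query length {len(query)} outside the usual {lo}-{hi} bp range",
            stacklevel=3,
        )


def find_reads_by_query(
    query: str,
    reads: Sequence[JoinedRead],
    index: QueryIndex | None = None,
) -> list[QueryHit]:
    """Every exact occurrence of ``query`` or its reverse complement.

    Both mates of every joined read are scanned; duplicate
    ``(read, mate, offset)`` hits are deduplicated (forward orientation
    wins) and the result is sorted by read id, mate and offset.
    """
    _validate_query(query)
    if index is not None:
        return index.find(query)
    rc = reverse_complement(query)
    hits: dict[tuple[str, int, int], QueryHit] = {}
    for r in reads:
        for mate_idx, seq in ((1, r.mate1), (2, r.mate2)):
            for probe, orient in ((query, "F"), (rc, "RC")):
                start = seq.find(probe)
                while start != -1:
                    key = (r.id, mate_idx, start)
                    if orient == "F":
                        hits[key] = QueryHit(r.id, mate_idx, start, "F")
                    else:
                        hits.setdefault(
                            key, QueryHit(r.id, mate_idx, start, "RC")
                        )
                    start = seq.find(probe, start + 1)
    return sorted(hits.values())


def _as_read_map(
    reads: Sequence[JoinedRead] | Mapping[str, JoinedRead] | QueryIndex,
) -> Mapping[str, JoinedRead]:
    if isinstance(reads, QueryIndex):
        return reads.read_map
    if isinstance(reads, Mapping):
        return reads
    return {r.id: r for r in reads}


def extend_consensus(
    anchor: str,
    hits: Sequence[QueryHit],
    reads: Sequence[JoinedRead] | Mapping[str, JoinedRead] | QueryIndex,
    params: WalkParams | None = None,
) -> tuple[str, list[int], BranchEvent | None]:
    """Majority-vote extension of the consensus beyond the anchor.

    Each hit's mate is oriented so the anchor matches forward; the bases
    beyond the anchor form the voting columns.  Columns are emitted
    while coverage >= ``min_support`` and the majority fraction >=
    ``min_agreement``.  If two bases each reach ``branch_fraction`` at a
    covered column, extension stops there and the conflict is returned
    as a :class:`BranchEvent`.
    """
    params = params or WalkParams()
    if not hits:
        raise WalkError("walk stalled: no hits for the anchor query")
    read_map = _as_read_map(reads)
    qlen = len(anchor)
    tails: list[str] = []
    for h in hits:
        mate = read_map[h.read_id].mate(h.mate)
        if h.orientation == "RC":
            mate = reverse_complement(mate)
            off = len(mate) - h.offset - qlen
        else:
            off = h.offset
        if mate[off : off + qlen] != anchor:
            continue  # defensive: stale hit
        tails.append(mate[off + qlen :])
    extension: list[str] = []
    support: list[int] = []
    col = 0
    while True:
        votes = Counter(t[col] for t in tails if len(t) > col)
        coverage = sum(votes.values())
        if coverage < params.min_support:
            break
        strong = [b for b, c in votes.items() if c / coverage >= params.branch_fraction]
        if len(strong) >= 2:
            return (
                "".join(extension),
                support,
                BranchEvent(position=col, base_counts=dict(votes)),
            )
        base, count = votes.most_common(1)[0]
        if count / coverage < params.min_agreement or base == "N":
            break
        extension.append(base)
        support.append(coverage)
        col += 1
    return "".join(extension), support, None


class _Walker:
    """Stateful rightward walker (leftward walks run in revcomp space)."""

    def __init__(
        self,
        index: QueryIndex,
        seed_query: str,
        params: WalkParams,
    ):
        _validate_query(seed_query)
        self.index = index
        self.params = params
        if not index.find(seed_query):
            raise WalkError("seed query not found in the reads")
        self.consensus = seed_query
        self.support: list[int] = []
        self.branch_events: list[BranchEvent] = []
        self.status = "active"
        self.iterations = 0

    def step(self) -> bool:
        """One find -> extend -> redesign cycle; True if the walk grew."""
        if self.status != "active":
            return False
        if self.iterations >= self.params.max_iterations:
            self.status = "max_iter"
            return False
        self.iterations += 1
        qlen = self.params.query_len
        anchor = self.consensus[-qlen:]
        hits = self.index.find(anchor)
        if not hits:
            self.status = "open"
            return False
        ext, sup, branch = extend_consensus(anchor, hits, self.index, self.params)
        if branch is not None:
            self.branch_events.append(
                BranchEvent(
                    position=len(self.consensus) + branch.position,
                    base_counts=branch.base_counts,
                )
            )
            self.status = "branched"
            return False
        if ext:
            self.consensus += ext
            self.support += sup
            return True
        self.status = "open"
        return False


def _finalize(walker: _Walker, leftward: bool) -> WalkResult:
    seq = walker.consensus
    support = walker.support
    events = walker.branch_events
    if leftward:
        seq = reverse_complement(seq)
        support = support[::-1]
        events = [
            BranchEvent(
                position=len(seq) - 1 - e.position, base_counts=e.base_counts
            )
            for e in events
        ]
    status = "open" if walker.status == "active" else walker.status
    return WalkResult(
        sequence=seq,
        status=status,
        iterations=walker.iterations,
        support=support,
        branch_events=events,
    )


def walk(
    reads: Sequence[JoinedRead],
    seed_query: str,
    direction: str = "rightward",
    params: WalkParams | None = None,
    index: QueryIndex | None = None,
) -> WalkResult:
    """Walk from a seed query until the consensus can no longer grow.

    ``direction="leftward"`` walks toward lower coordinates by running
    the same procedure on the reverse complement and flipping the result
    at the end.  The returned sequence always includes the seed.
    """
    params = params or WalkParams()
    if direction not in ("rightward", "leftward"):
        raise ValueError("direction must be 'rightward' or 'leftward'")
    if len(seed_query) != params.query_len:
        params = WalkParams(
            **{**params.__dict__, "query_len": len(seed_query)}
        )
    if index is None:
        index = QueryIndex(reads, params.query_len)
    leftward = direction == "leftward"
    seed = reverse_complement(seed_query) if leftward else seed_query
    walker = _Walker(index, seed, params)
    while walker.step():
        pass
    return _finalize(walker, leftward)


@dataclass
class GapClosure:
    status: str  # "closed" | "open" | "branched"
    sequence: str | None  # full merged sequence spanning flank to flank
    left: WalkResult
    right: WalkResult
    overlap: int = 0


def _merge_overlap(left_known: str, right_known: str, min_overlap: int) -> int:
    """Largest-first suffix/prefix exact overlap >= ``min_overlap`` (0 if none)."""
    if len(left_known) < min_overlap or len(right_known) < min_overlap:
        return 0
    probe = left_known[-min_overlap:]
    i = right_known.find(probe)
    while i != -1:
        k = i + min_overlap
        if k <= len(left_known) and left_known[-k:] == right_known[:k]:
            return k
        i = right_known.find(probe, i + 1)
    return 0


def close_gap(
    left_flank: str,
    right_flank: str,
    reads: Sequence[JoinedRead],
    params: WalkParams | None = None,
    index: QueryIndex | None = None,
    max_walk: int | None = None,
) -> GapClosure:
    """Walk rightward from the left flank and leftward from the right
    flank, merging when the completed walks agree exactly over at least
    ``min_merge_overlap`` bases.

    Both walks run to their natural termination (or to ``max_walk``
    extended bases per side) *before* any merge is attempted, and a
    merge is refused when either walk ended at a branch: inside a
    tandem repeat the two walks' sequences overlap perfectly long
    before the copy junctions are reached, so merging early (or merging
    through a branch) would silently collapse a genuine duplication.
    ``max_walk`` also keeps a walk from running deep into flank regions
    that may hold further, not-yet-repaired defects.

    No overlap is not an exception: the two open walks are returned so
    the caller can inspect how far each side reached.
    """
    params = params or WalkParams()
    qlen = params.query_len
    if len(left_flank) < qlen or len(right_flank) < qlen:
        raise WalkError("flanks must be at least query_len long")
    if index is None:
        index = QueryIndex(reads, qlen)
    limit = qlen + max_walk if max_walk is not None else None
    lw = _Walker(index, left_flank[-qlen:], params)
    rw = _Walker(index, reverse_complement(right_flank[:qlen]), params)
    for w in (lw, rw):
        while (limit is None or len(w.consensus) < limit) and w.step():
            pass
    lres = _finalize(lw, leftward=False)
    rres = _finalize(rw, leftward=True)
    if "branched" in (lres.status, rres.status):
        return GapClosure("branched", None, lres, rres)
    left_known = left_flank[:-qlen] + lw.consensus
    right_known = reverse_complement(rw.consensus) + right_flank[qlen:]
    k = _merge_overlap(left_known, right_known, params.min_merge_overlap)
    if k:
        lres.status = rres.status = "closed"
        return GapClosure("closed", left_known + right_known[k:], lres, rres, overlap=k)
    return GapClosure("open", None, lres, rres)


@dataclass
class ResolveResult:
    sequence: str | None  # corrected contig, or None when unresolved
    closure: GapClosure

    @property
    def status(self) -> str:
        return self.closure.status


def resolve_region(
    draft: SequenceRecord | str,
    interval: tuple[int, int],
    reads: Sequence[JoinedRead],
    params: WalkParams | None = None,
    index: QueryIndex | None = None,
) -> ResolveResult:
    """Replace ``draft[interval]`` with the sequence walked between the
    flanking anchors.

    The flanks outside the interval are trusted; a false tandem
    duplication inside the interval collapses to a single copy when the
    reads support only one junction, while reads that genuinely carry
    two copies stop the walk at a branch instead of silently collapsing.
    Each walk is capped a little beyond the interval length so it does
    not run into distant flank regions that may hold other defects.
    """
    params = params or WalkParams()
    seq = draft.sequence if hasattr(draft, "sequence") else str(draft)
    start, end = interval
    if not 1 <= start <= end <= len(seq):
        raise ValueError(f"interval {interval!r} outside the draft contig")
    left_flank = seq[: start - 1]
    right_flank = seq[end:]
    max_walk = (end - start + 1) + params.min_merge_overlap + 1000
    closure = close_gap(left_flank, right_flank, reads, params, index, max_walk)
    corrected = closure.sequence if closure.status == "closed" else None
    return ResolveResult(sequence=corrected, closure=closure)
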