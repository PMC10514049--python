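"""Walking assembler: query retrieval, consensus extension, gap closing."""

import numpy as np
import pytest

from cenwalk.sequences import reverse_complement
from cenwalk.synthetic import (
    CorruptionSpec,
    ReadSimParams,
    corrupt_reference,
    make_true_locus,
    simulate_wgs_pairs,
)
from cenwalk.walking import (
    JoinedRead,
    QueryIndex,
    WalkError,
    WalkParams,
    close_gap,
    extend_consensus,
    find_reads_by_query,
    join_pairs,
    resolve_region,
    walk,
)

WGS = ReadSimParams(read_len=150, depth=50, error_rate=0.0, seed=0)


def brute_force_hits(query, reads):
    """Independent oracle: scan every mate in both orientations."""
    rc = reverse_complement(query)
    found = set()
    for r in reads:
        for mate_idx, seq in ((1, r.mate1), (2, r.mate2)):
            for probe in (query, rc):
                start = seq.find(probe)
                while start != -1:
                    found.add((r.id, mate_idx, start))
                    start = seq.find(probe, start + 1)
    return found


class TestJoinPairs:
    def test_cardinality_and_mate_order(self, locus12k):
        pairs, _ = simulate_wgs_pairs([locus12k], ReadSimParams(depth=2, seed=1))
        joined = join_pairs(pairs)
        assert len(joined) == len(pairs)
        assert joined[0].mate1 == pairs[0].seq1
        assert joined[0].mate2 == pairs[0].seq2

    def test_two_file_form_matches_ids(self):
        r1 = [("p1/1", "ACGT" * 20), ("p2/1", "TTTT" * 20)]
        r2 = [("p1/2", "GGGG" * 20), ("p2/2", "CCCC" * 20)]
        joined = {j.id: j for j in join_pairs(r1, r2)}
        assert joined["p1"].mate1 == "ACGT" * 20
        assert joined["p1"].mate2 == "GGGG" * 20

    def test_orphan_mate_is_an_error(self):
        r1 = [("p1/1", "ACGT" * 20), ("p2/1", "TTTT" * 20)]
        r2 = [("p1/2", "GGGG" * 20)]
        with pytest.raises(ValueError, match="p2"):
            join_pairs(r1, r2)


class TestFindReadsByQuery:
    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for case in range(200):
            reads = [
                JoinedRead(
                    f"r{i}",
                    "".join(rng.choice(bases, size=80)),
                    "".join(rng.choice(bases, size=80)),
                )
                for i in range(8)
            ]
            # half the cases plant the query into random mates
            if case % 2:
                query = "".join(rng.choice(bases, size=60))
                for _ in range(rng.integers(1, 4)):
                    i = int(rng.integers(0, 8))
                    mate = int(rng.integers(1, 3))
                    off = int(rng.integers(0, 21))
                    planted = query if rng.random() < 0.5 else reverse_complement(query)
                    r = reads[i]
                    seq = (r.mate1 if mate == 1 else r.mate2)
                    seq = seq[:off] + planted + seq[off + 60 :]
                    reads[i] = JoinedRead(
                        r.id,
                        seq if mate == 1 else r.mate1,
                        seq if mate == 2 else r.mate2,
                    )
            else:
                i = int(rng.integers(0, 8))
                src = reads[i].mate1
                query = src[10:70]
            hits = find_reads_by_query(query, reads)
            assert {(h.read_id, h.mate, h.offset) for h in hits} == brute_force_hits(
                query, reads
            )
            # index-backed lookup agrees with the scan
            idx = QueryIndex(reads, 60)
            assert idx.find(query) == hits

    def test_absent_query_and_n_query(self):
        reads = [JoinedRead("r0", "A" * 80, "A" * 80)]
        assert find_reads_by_query("GT" * 30, reads) == []
        with pytest.raises(WalkError):
            find_reads_by_query("N" * 60, reads)

    def test_revcomp_hit_is_labelled(self):
        core = make_true_locus(1000, 0.5, 3).sequence
        query = core[100:160]
        reads = [JoinedRead("r0", reverse_complement(core[80:180]), "T" * 80)]
        hits = find_reads_by_query(query, reads)
        assert len(hits) == 1 and hits[0].orientation == "RC"

    def test_out_of_range_length_warns(self):
        reads = [JoinedRead("r0", "A" * 80, "C" * 80)]
        with pytest.warns(UserWarning):
            find_reads_by_query("A" * 40, reads)


def _reads_with_tails(anchor, tail, tail_lengths):
    return [
        JoinedRead(f"r{i}", anchor + tail[:n], "T" * 10)
        for i, n in enumerate(tail_lengths)
    ]


class TestExtendConsensus:
    def test_unanimous_extension(self):
        truth = make_true_locus(1000, 0.5, 1).sequence
        anchor, tail = truth[:60], truth[60:140]
        reads = _reads_with_tails(anchor, tail, [80] * 10)
        hits = find_reads_by_query(anchor, reads)
        ext, support, branch = extend_consensus(anchor, hits, reads)
        assert ext == tail and branch is None
        assert support == [10] * 80

    def test_extension_stops_at_support_floor(self):
        truth = make_true_locus(1000, 0.5, 2).sequence
        anchor, tail = truth[:60], truth[60:120]
        # columns 1..20 covered by 6 reads, column 21 by only 4 (< 5)
        reads = _reads_with_tails(anchor, tail, [30, 30, 30, 30, 20, 20])
        hits = find_reads_by_query(anchor, reads)
        ext, support, branch = extend_consensus(anchor, hits, reads)
        assert len(ext) == 20 and branch is None

    def test_planted_disagreement_is_a_branch(self):
        truth = make_true_locus(1000, 0.5, 3).sequence
        anchor, tail = truth[:60], truth[60:100]
        alt = ("A" if tail[5] != "A" else "C") + tail[6:]
        reads = _reads_with_tails(anchor, tail, [40] * 5)
        reads += [
            JoinedRead(f"alt{i}", anchor + tail[:5] + alt, "T" * 10)
            for i in range(5)
        ]
        hits = find_reads_by_query(anchor, reads)
        ext, support, branch = extend_consensus(anchor, hits, reads)
        assert branch is not None and branch.position == 5
        assert len(ext) == 5
        assert len(branch.base_counts) == 2

    def test_no_hits_is_an_error(self):
        with pytest.raises(WalkError):
            extend_consensus("A" * 60, [], [])

    def test_monotone_in_support_and_agreement(self):
        truth = make_true_locus(1000, 0.5, 4).sequence
        anchor, tail = truth[:60], truth[60:140]
        rng = np.random.default_rng(0)
        reads = _reads_with_tails(
            anchor, tail, list(rng.integers(10, 80, size=15))
        )
        hits = find_reads_by_query(anchor, reads)
        lengths = []
        for ms in (2, 5, 8, 12):
            ext, _, _ = extend_consensus(
                anchor, hits, reads, WalkParams(query_len=60, min_support=ms)
            )
            lengths.append(len(ext))
        assert lengths == sorted(lengths, reverse=True)


@pytest.fixture(scope="module")
def walk_fixture():
    locus = make_true_locus(8_000, 0.42, 21)
    pairs, _ = simulate_wgs_pairs([locus], WGS)
    joined = join_pairs(pairs)
    index = QueryIndex(joined, 60)
    return locus, joined, index


class TestWalk:
    def test_rightward_walk_reproduces_segment(self, walk_fixture):
        locus, joined, index = walk_fixture
        truth = locus.sequence
        seed = truth[1000:1060]
        res = walk(joined, seed, "rightward", WalkParams(query_len=60), index)
        assert res.status == "open"
        assert truth[1000 : 1000 + len(res.sequence)] == res.sequence
        assert len(res.sequence) > 5000  # reaches near the locus end

    def test_leftward_walk_is_reverse_symmetric(self, walk_fixture):
        locus, joined, index = walk_fixture
        truth = locus.sequence
        seed = truth[6940:7000]
        res = walk(joined, seed, "leftward", WalkParams(query_len=60), index)
        assert res.status == "open"
        assert truth[7000 - len(res.sequence) : 7000] == res.sequence

    def test_max_iterations_bounds_growth(self, walk_fixture):
        locus, joined, index = walk_fixture
        seed = locus.sequence[1000:1060]
        res = walk(
            joined,
            seed,
            "rightward",
            WalkParams(query_len=60, max_iterations=1),
            index,
        )
        assert res.iterations == 1
        assert len(res.sequence) <= 60 + 150  # one extension step at most

    def test_unknown_seed_is_an_error(self, walk_fixture):
        _, joined, index = walk_fixture
        with pytest.raises(WalkError):
            walk(joined, "A" * 60, "rightward", WalkParams(query_len=60), index)

    def test_determinism(self, walk_fixture):
        locus, joined, index = walk_fixture
        seed = locus.sequence[2000:2060]
        a = walk(joined, seed, "rightward", WalkParams(query_len=60), index)
        b = walk(joined, seed, "rightward", WalkParams(query_len=60), index)
        assert a.sequence == b.sequence and a.iterations == b.iterations


class TestCloseGap:
    @pytest.mark.parametrize("seed", range(20))
    def test_exact_recovery_across_seeds(self, seed):
        """Error-free reads at depth 50 close an N-gap byte-identically."""
        locus = make_true_locus(6_000, 0.42, 100 + seed)
        truth = locus.sequence
        pairs, _ = simulate_wgs_pairs(
            [locus], ReadSimParams(read_len=150, depth=50, seed=seed)
        )
        joined = join_pairs(pairs)
        left, right = truth[:2_000], truth[3_500:]
        closure = close_gap(left, right, joined, WalkParams(query_len=60))
        assert closure.status == "closed"
        assert closure.sequence == truth

    def test_central_read_dropout_leaves_both_sides_open(self):
        locus = make_true_locus(8_000, 0.42, 55)
        truth = locus.sequence
        pairs, origins = simulate_wgs_pairs(
            [locus], ReadSimParams(read_len=150, depth=50, seed=2)
        )
        # withhold every pair whose fragment could cover the central 2 kb
        kept = [
            r
            for r in pairs
            if not (2_200 < origins[r.id][1] < 5_000)
        ]
        joined = join_pairs(kept)
        closure = close_gap(
            truth[:2_000], truth[6_000:], joined, WalkParams(query_len=60)
        )
        assert closure.status == "open"
        assert closure.sequence is None

    def test_overlap_threshold_larger_than_walks(self):
        locus = make_true_locus(6_000, 0.42, 77)
        truth = locus.sequence
        pairs, _ = simulate_wgs_pairs(
            [locus], ReadSimParams(read_len=150, depth=50, seed=3)
        )
        joined = join_pairs(pairs)
        params = WalkParams(
            query_len=60, max_iterations=2, min_merge_overlap=5_000
        )
        closure = close_gap(truth[:2_000], truth[3_000:], joined, params)
        assert closure.status in ("open", "max_iter")
        assert closure.sequence is None


class TestResolveRegion:
    def test_false_duplication_collapses_to_truth(self):
        locus = make_true_locus(12_000, 0.42, 31)
        spec = CorruptionSpec(dup_block=(5_000, 6_999), gap_specs=((6_999, 800),))
        contigs, cmap = corrupt_reference(locus, spec)
        pairs, _ = simulate_wgs_pairs(
            [locus], ReadSimParams(read_len=150, depth=50, seed=4)
        )
        joined = join_pairs(pairs)
        res = resolve_region(
            contigs[0], cmap.misassembled_interval, joined, WalkParams(query_len=60)
        )
        assert res.status == "closed"
        assert res.sequence == locus.sequence

    def test_plain_gap_interval_reduces_to_close_gap(self):
        locus = make_true_locus(8_000, 0.42, 32)
        spec = CorruptionSpec(dup_block=None, gap_specs=((4_000, 600),))
        contigs, cmap = corrupt_reference(locus, spec)
        gap = cmap.gap_intervals[0]
        pairs, _ = simulate_wgs_pairs(
            [locus], ReadSimParams(read_len=150, depth=50, seed=5)
        )
        joined = join_pairs(pairs)
        res = resolve_region(contigs[0], gap, joined, WalkParams(query_len=60))
        assert res.status == "closed"
        assert res.sequence == locus.sequence

    def test_true_duplication_stops_at_branch_never_collapses(self):
        """Reads that genuinely carry two copies surface a branch event
        instead of a silently collapsed single copy."""
        locus = make_true_locus(12_000, 0.42, 33)
        spec = CorruptionSpec(dup_block=(5_000, 6_999), gap_specs=())
        contigs, _ = corrupt_reference(locus, spec)  # gapless two-copy truth
        dup_genome = contigs[0]
        pairs, _ = simulate_wgs_pairs(
            [dup_genome], ReadSimParams(read_len=150, depth=50, seed=6)
        )
        joined = join_pairs(pairs)
        # ask the walker to re-derive the duplicated region from its flanks
        res = resolve_region(
            dup_genome, (5_000, 8_999), joined, WalkParams(query_len=60)
        )
        assert res.sequence is None
        assert res.status == "branched"
        events = (
            res.closure.left.branch_events + res.closure.right.branch_events
        )
        assert events
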