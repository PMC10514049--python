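"""The synthetic study system: locus, corruption, and read simulators."""

import numpy as np
import pytest

from cenwalk.sequences import reverse_complement
from cenwalk.synthetic import (
    CorruptionSpec,
    DomainSpec,
    ReadSimParams,
    corrupt_reference,
    make_tissue_panel,
    make_true_locus,
    simulate_chip_pairs,
    simulate_long_reads,
    simulate_wgs_pairs,
)


class TestMakeTrueLocus:
    def test_length_alphabet_and_gc_extreme(self):
        rec = make_true_locus(10_000, 0.42, 7)
        assert len(rec) == 10_000
        assert set(rec.sequence) <= set("ACGT")
        gc_only = make_true_locus(10_000, 1.0, 7)
        assert set(gc_only.sequence) <= set("GC")

    def test_seeded_determinism(self):
        a = make_true_locus(5_000, 0.5, 3)
        b = make_true_locus(5_000, 0.5, 3)
        assert a.sequence == b.sequence

    def test_gc_fraction_converges(self):
        rec = make_true_locus(100_000, 0.42, 1)
        gc = (rec.sequence.count("G") + rec.sequence.count("C")) / len(rec)
        assert abs(gc - 0.42) < 3 * np.sqrt(0.42 * 0.58 / 100_000)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_true_locus(999, 0.5, 0)


class TestCorruptReference:
    def test_duplication_and_gap_lengths(self, locus12k):
        spec = CorruptionSpec(dup_block=(5000, 6999), gap_specs=((6999, 1000),))
        contigs, cmap = corrupt_reference(locus12k, spec)
        # 12000 + 2000 duplicated + 1000 N separator
        assert len(contigs[0]) == 15_000
        seq = contigs[0].sequence
        truth = locus12k.sequence
        assert seq[:6999] == truth[:6999]
        assert seq[6999:7999] == "N" * 1000
        assert seq[7999:9999] == truth[4999:6999]
        assert seq[9999:] == truth[6999:]
        assert cmap.misassembled_interval == (5000, 9999)

    def test_unplaced_contig_equals_block(self, corrupted12k, locus12k):
        contigs, cmap = corrupted12k
        assert cmap.unplaced_id == contigs[1].id
        assert contigs[1].sequence == locus12k.sequence[4999:6999]

    def test_empty_spec_is_identity(self, locus12k):
        contigs, cmap = corrupt_reference(locus12k, CorruptionSpec())
        assert contigs[0].sequence == locus12k.sequence
        assert cmap.misassembled_interval is None

    def test_extra_gap_inserted_at_position(self, locus12k):
        spec = CorruptionSpec(
            dup_block=(5000, 6999),
            gap_specs=((6999, 500), (10_000, 200)),
        )
        contigs, cmap = corrupt_reference(locus12k, spec)
        assert len(contigs[0]) == 12_000 + 2000 + 500 + 200
        # second gap: original position 10000 shifted by dup+separator (2500)
        seq = contigs[0].sequence
        assert seq[12_500:12_700] == "N" * 200
        assert (12_501, 12_700) in cmap.gap_intervals

    def test_gap_overlapping_dup_rejected(self, locus12k):
        spec = CorruptionSpec(
            dup_block=(5000, 6999), gap_specs=((6999, 500), (6000, 100))
        )
        with pytest.raises(ValueError):
            corrupt_reference(locus12k, spec)


class TestSimulateWgsPairs:
    def test_pair_count_formula(self, locus12k):
        p = ReadSimParams(depth=30, seed=1)
        pairs, origins = simulate_wgs_pairs([locus12k], p)
        assert len(pairs) == round(30 * 12_000 / (2 * 75))
        assert set(origins) == {r.id for r in pairs}

    def test_error_free_mates_are_substrings(self, locus12k):
        p = ReadSimParams(depth=2, seed=5, error_rate=0.0)
        pairs, _ = simulate_wgs_pairs([locus12k], p)
        genome = locus12k.sequence
        rc = reverse_complement(genome)
        for r in pairs[:100]:
            assert r.seq1 in genome or r.seq1 in rc
            assert r.seq2 in genome or r.seq2 in rc

    def test_origins_locate_fragments_exactly(self, locus12k):
        p = ReadSimParams(depth=2, seed=6, error_rate=0.0)
        pairs, origins = simulate_wgs_pairs([locus12k], p)
        genome = locus12k.sequence
        for r in pairs[:50]:
            contig, start, strand = origins[r.id]
            frag_window = genome[start - 1 : start - 1 + 800]
            mate = r.seq1 if strand == "+" else r.seq2
            assert frag_window.startswith(mate)

    def test_seeded_determinism(self, locus12k):
        p = ReadSimParams(depth=5, seed=11)
        a, _ = simulate_wgs_pairs([locus12k], p)
        b, _ = simulate_wgs_pairs([locus12k], p)
        assert a == b

    def test_short_contig_rejected(self):
        from cenwalk.sequences import SequenceRecord

        tiny = SequenceRecord("t", "ACGT" * 100)  # 400 < frag_max
        with pytest.raises(ValueError):
            simulate_wgs_pairs([tiny], ReadSimParams(depth=1, seed=0))


class TestSimulateChipPairs:
    def test_enrichment_ratio_converges_to_fold(self):
        # law-of-large-numbers check on the plateau model
        locus = make_true_locus(40_000, 0.42, 2)
        dom = DomainSpec(homolog1=(16_000, 23_999), enrichment_fold=8.0)
        # depth chosen to give ~50k fragments
        p = ReadSimParams(depth=187.5, seed=3)
        pairs, origins = simulate_chip_pairs(locus, dom, p)
        assert len(pairs) == 50_000
        # approximate midpoints from fragment starts; stay clear of the
        # domain edges where the +-300 bp fragment-length blur acts
        mids = np.array([origins[r.id][1] for r in pairs]) + 250
        in_zone = (17_000, 23_000)
        out_zone = (2_000, 14_000)
        inside = ((mids >= in_zone[0]) & (mids <= in_zone[1])).sum()
        outside = ((mids >= out_zone[0]) & (mids <= out_zone[1])).sum()
        in_len = in_zone[1] - in_zone[0] + 1
        out_len = out_zone[1] - out_zone[0] + 1
        ratio = (inside / in_len) / (outside / out_len)
        se = ratio * np.sqrt(1 / inside + 1 / outside)
        assert abs(ratio - 8.0) < 4 * se

    def test_fold_one_is_uniform(self):
        locus = make_true_locus(40_000, 0.42, 2)
        dom = DomainSpec(homolog1=(16_000, 23_999), enrichment_fold=1.0)
        pairs, origins = simulate_chip_pairs(
            locus, dom, ReadSimParams(depth=187.5, seed=4)
        )
        mids = np.array([origins[r.id][1] for r in pairs]) + 250
        inside = ((mids >= 16_000) & (mids <= 23_999)).sum()
        frac = inside / len(mids)
        expect = 8000 / 40_000
        assert abs(frac - expect) < 3 * np.sqrt(expect * (1 - expect) / len(mids))

    def test_homolog_mixture_zero_uses_second_homolog(self):
        locus = make_true_locus(20_000, 0.42, 2)
        dom = DomainSpec(
            homolog1=(2_000, 4_999),
            homolog2=(14_000, 16_999),
            enrichment_fold=10.0,
            homolog_mixture=0.0,
        )
        pairs, origins = simulate_chip_pairs(
            locus, dom, ReadSimParams(depth=40, seed=5)
        )
        mids = np.array([origins[r.id][1] for r in pairs]) + 250
        in1 = ((mids >= 2_000) & (mids <= 4_999)).mean()
        in2 = ((mids >= 14_000) & (mids <= 16_999)).mean()
        assert in2 > 3 * in1

    def test_domain_outside_locus_rejected(self, locus12k):
        dom = DomainSpec(homolog1=(11_000, 13_000))
        with pytest.raises(ValueError):
            simulate_chip_pairs(locus12k, dom, ReadSimParams(depth=1, seed=0))


class TestMakeTissuePanel:
    def test_cardinality_and_shared_truth(self, locus12k):
        base = DomainSpec(homolog1=(4_000, 6_999), enrichment_fold=6.0)
        slides = {t: 0 for t in ("a", "b", "c", "d", "e")}
        panel, domains = make_tissue_panel(
            locus12k, base, slides, ReadSimParams(depth=4, seed=1)
        )
        assert set(panel) == set(slides)
        assert all(tr.chip and tr.input for tr in panel.values())
        spans = {domains[t].span for t in slides}
        assert spans == {(4_000, 6_999)}

    def test_slide_produces_disjoint_truth(self, locus12k):
        base = DomainSpec(homolog1=(2_000, 4_999))
        panel, domains = make_tissue_panel(
            locus12k,
            base,
            {"brain": 0, "liver": 6_000},
            ReadSimParams(depth=2, seed=1),
        )
        b, l = domains["brain"].span, domains["liver"].span
        assert l[0] > b[1]  # disjoint: slide exceeds the domain span

    def test_out_of_bounds_slide_rejected(self, locus12k):
        base = DomainSpec(homolog1=(4_000, 6_999))
        with pytest.raises(ValueError):
            make_tissue_panel(
                locus12k, base, {"x": 6_000}, ReadSimParams(depth=1, seed=1)
            )


class TestTruthSet:
    def test_bundle_invariants(self, locus12k, corrupted12k):
        from cenwalk.synthetic import TruthSet

        contigs, cmap = corrupted12k
        dom = DomainSpec(homolog1=(4_000, 6_999))
        pairs, origins = simulate_wgs_pairs(
            [locus12k], ReadSimParams(depth=2, seed=1)
        )
        truth = TruthSet(
            true_locus=locus12k,
            corrupted_ref=list(contigs),
            corruption_map=cmap,
            tissue_domains={"fibroblast": dom},
            read_origins=origins,
        )
        assert all(r.id in truth.read_origins for r in pairs)
        with pytest.raises(ValueError):
            TruthSet(locus12k, list(contigs), cmap, {}, origins)


class TestSimulateLongReads:
    def test_error_free_reads_are_substrings(self, locus12k):
        reads, origins = simulate_long_reads(
            [locus12k], mean_len=2000, depth=5, error_rate=0.0, seed=8
        )
        genome = locus12k.sequence
        rc = reverse_complement(genome)
        for rec in reads:
            assert rec.sequence in genome or rec.sequence in rc

    def test_read_count_tracks_depth(self, locus12k):
        reads, _ = simulate_long_reads(
            [locus12k], mean_len=2000, depth=10, seed=8
        )
        assert len(reads) == round(10 * 12_000 / 2000)

    def test_determinism_and_min_length(self, locus12k):
        a, _ = simulate_long_reads([locus12k], mean_len=1500, depth=5, seed=9)
        b, _ = simulate_long_reads([locus12k], mean_len=1500, depth=5, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert min(len(r) for r in a) >= 1000
        with pytest.raises(ValueError):
            simulate_long_reads([locus12k], mean_len=500, depth=1, seed=0)
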