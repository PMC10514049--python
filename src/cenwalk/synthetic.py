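"""Synthetic study system: a satellite-free centromeric locus and its reads.

This module generates the ground truth against which the rest of the
package is exercised:

* a unique (non-satellite) centromeric locus,
* a deliberately corrupted draft reference that mimics a misassembly —
  a false tandem duplication of a block, N-run sequence gaps, and an
  optional redundant unplaced contig carrying the duplicated block,
* seeded read sets: paired-end whole-genome reads, paired-end CENP-A
  ChIP reads enriched over per-homolog binding domains, matched input
  reads, and long reads,
* a multi-"tissue" ChIP panel in which the binding domain is either held
  fixed across tissues or deliberately slid in one of them.

Fragments are drawn from the 200-800 bp sonication range typical of
CENP-A ChIP experiments.  Enrichment uses a plateau model: a fragment
whose midpoint lies inside the active homolog's binding domain is
sampled with weight ``enrichment_fold``, all other fragments with
weight 1.  Sequencing errors are substitutions only and never produce N.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .sequences import (
    ReadPair,
    SequenceRecord,
    decode,
    decode_rows,
    encode,
    revcomp_matrix,
)

__all__ = [
    "CorruptionSpec",
    "CorruptionMap",
    "DomainSpec",
    "ReadSimParams",
    "TissueReads",
    "TruthSet",
    "make_true_locus",
    "corrupt_reference",
    "simulate_wgs_pairs",
    "simulate_chip_pairs",
    "make_tissue_panel",
    "simulate_long_reads",
    "derive_seed",
]


def derive_seed(seed: int, label: str) -> int:
    """Mix a stage/sample label into a base seed, reproducibly (< 2**31)."""
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class CorruptionSpec:
    """How to corrupt the true locus into a misassembled draft.

    ``dup_block`` is a 1-based inclusive interval of the true locus that
    is falsely duplicated in tandem; the first entry of ``gap_specs``
    provides the N-run placed between the two copies.  Remaining gaps
    are ``(position, length)`` pairs: an N-run of ``length`` is inserted
    immediately after ``position`` of the true locus.  With
    ``emit_unplaced`` the duplicated block is additionally emitted as a
    redundant unplaced contig.
    """

    dup_block: tuple[int, int] | None = None
    gap_specs: tuple[tuple[int, int], ...] = ()
    emit_unplaced: bool = False

    def __post_init__(self) -> None:
        if self.dup_block is not None:
            s, e = self.dup_block
            if not 1 <= s <= e:
                raise ValueError(f"invalid dup_block {self.dup_block!r}")
        for pos, length in self.gap_specs:
            if length < 1:
                raise ValueError(f"gap length must be >= 1, got {length}")
            if pos < 0:
                raise ValueError(f"gap position must be >= 0, got {pos}")


@dataclass(frozen=True)
class CorruptionMap:
    """Exact bookkeeping of how the draft was produced from the truth.

    ``blocks`` maps true-locus segments to their start in the corrupted
    main contig as ``(old_start, old_end, corrupted_start)``.
    ``inserted`` lists foreign material in corrupted coordinates as
    ``(start, end, kind)`` with kind ``"gap"`` or ``"dup"``.
    ``misassembled_interval`` spans, in corrupted coordinates, the whole
    false structure (first copy, separator gap, second copy); it is the
    interval a caller would hand to the walking assembler.
    """

    blocks: tuple[tuple[int, int, int], ...]
    inserted: tuple[tuple[int, int, str], ...]
    misassembled_interval: tuple[int, int] | None
    gap_intervals: tuple[tuple[int, int], ...]
    unplaced_id: str | None


@dataclass(frozen=True)
class DomainSpec:
    """Per-homolog CENP-A binding domains on the true locus.

    Both intervals are 1-based inclusive.  ``homolog2`` defaults to the
    same interval as ``homolog1`` (coincident epialleles).  A fragment
    is attributed to homolog 1 with probability ``homolog_mixture``.
    """

    homolog1: tuple[int, int]
    homolog2: tuple[int, int] | None = None
    enrichment_fold: float = 8.0
    homolog_mixture: float = 0.5

    def __post_init__(self) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not 0.0 <= self.homolog_mixture <= 1.0:
            raise ValueError("homolog_mixture must be in [0, 1]")
        for iv in (self.homolog1, self.homolog2 or self.homolog1):
            if not 1 <= iv[0] <= iv[1]:
                raise ValueError(f"invalid domain interval {iv!r}")

    @property
    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.homolog1, self.homolog2 or self.homolog1

    @property
    def span(self) -> tuple[int, int]:
        """Union footprint of the two homolog domains."""
        (a1, b1), (a2, b2) = self.intervals
        return min(a1, a2), max(b1, b2)

    def shifted(self, offset: int) -> "DomainSpec":
        h2 = self.homolog2
        return replace(
            self,
            homolog1=(self.homolog1[0] + offset, self.homolog1[1] + offset),
            homolog2=None if h2 is None else (h2[0] + offset, h2[1] + offset),
        )


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end simulation parameters (fragment range 200-800 bp)."""

    read_len: int = 75
    frag_min: int = 200
    frag_max: int = 800
    depth: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frag_min < self.read_len:
            raise ValueError("frag_min must be >= read_len")
        if self.frag_max < self.frag_min:
            raise ValueError("frag_max must be >= frag_min")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class TissueReads:
    """ChIP and matched input read sets for one tissue."""

    chip: list[ReadPair]
    input: list[ReadPair]
    chip_origins: dict[str, tuple[str, int, str]]
    input_origins: dict[str, tuple[str, int, str]]


@dataclass
class TruthSet:
    """Ground truth bundle for a simulated study."""

    true_locus: SequenceRecord
    corrupted_ref: list[SequenceRecord]
    corruption_map: CorruptionMap
    tissue_domains: dict[str, DomainSpec]
    read_origins: dict[str, tuple[str, int, str]]

    def __post_init__(self) -> None:
        if not self.tissue_domains:
            raise ValueError("tissue_domains must be non-empty")


def make_true_locus(length: int, gc: float, seed: int) -> SequenceRecord:
    """Random i.i.d. locus with the requested GC fraction, no N."""
    if length < 1000:
        raise ValueError("locus length must be >= 1000 (too short for walking)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SequenceRecord(id="true_locus", sequence=decode(codes))


def corrupt_reference(
    locus: SequenceRecord, spec: CorruptionSpec
) -> tuple[list[SequenceRecord], CorruptionMap]:
    """Apply a false tandem duplication and N-run gaps to the true locus.

    The main corrupted contig is the locus with ``dup_block`` duplicated
    in tandem, the two copies separated by the first gap's N-run, and
    any remaining gaps inserted at their stated positions.  With
    ``emit_unplaced`` a second contig equal to the duplicated block is
    returned, mirroring a redundant unplaced contig.
    """
    seq = locus.sequence
    n = len(seq)
    gaps = list(spec.gap_specs)
    dup = spec.dup_block
    if dup is not None:
        if dup[1] > n:
            raise ValueError("dup_block extends past the locus")
        sep_len = gaps.pop(0)[1] if gaps else 0
    else:
        sep_len = 0

    # Insertions: (position after which to insert, payload, kind)
    insertions: list[tuple[int, str, str]] = []
    if dup is not None:
        ds, de = dup
        payload = "N" * sep_len + seq[ds - 1 : de]
        insertions.append((de, payload, "dup"))
    for pos, length in gaps:
        if pos > n:
            raise ValueError(f"gap position {pos} beyond locus length {n}")
        if dup is not None and dup[0] <= pos <= dup[1]:
            raise ValueError(
                f"gap at {pos} overlaps the duplicated block {dup!r}"
            )
        insertions.append((pos, "N" * length, "gap"))
    insertions.sort(key=lambda t: (t[0], t[2] != "dup"))
    for (p1, _, _), (p2, _, _) in zip(insertions, insertions[1:]):
        if p1 == p2:
            raise ValueError(f"overlapping insertions at position {p1}")

    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    inserted: list[tuple[int, int, str]] = []
    mis_interval: tuple[int, int] | None = None
    cursor = 1  # next true position to emit
    new_pos = 1  # next corrupted position
    for pos, payload, kind in insertions:
        if pos >= cursor:
            parts.append(seq[cursor - 1 : pos])
            blocks.append((cursor, pos, new_pos))
            new_pos += pos - cursor + 1
            cursor = pos + 1
        ins_start, ins_end = new_pos, new_pos + len(payload) - 1
        parts.append(payload)
        inserted.append((ins_start, ins_end, kind))
        if kind == "dup":
            # misassembled structure spans copy 1 + separator + copy 2
            ds, de = dup  # type: ignore[misc]
            copy1_new = blocks[-1][2] + (ds - blocks[-1][0])
            mis_interval = (copy1_new, ins_end)
        new_pos = ins_end + 1
    if cursor <= n:
        parts.append(seq[cursor - 1 :])
        blocks.append((cursor, n, new_pos))

    gap_intervals = tuple(
        (s, e)
        for s, e, kind in inserted
        if kind == "gap"
    )
    if dup is not None and sep_len:
        # the separator N-run sits right before the second copy
        for s, e, kind in inserted:
            if kind == "dup":
                gap_intervals = ((s, s + sep_len - 1),) + gap_intervals
    gap_intervals = tuple(sorted(gap_intervals))

    contigs = [SequenceRecord(id="draft_main", sequence="".join(parts))]
    unplaced_id = None
    if spec.emit_unplaced:
        if dup is None:
            raise ValueError("emit_unplaced requires a dup_block")
        unplaced_id = "unplaced_dup"
        contigs.append(
            SequenceRecord(id=unplaced_id, sequence=seq[dup[0] - 1 : dup[1]])
        )
    cmap = CorruptionMap(
        blocks=tuple(blocks),
        inserted=tuple(inserted),
        misassembled_interval=mis_interval,
        gap_intervals=gap_intervals,
        unplaced_id=unplaced_id,
    )
    return contigs, cmap


def _apply_errors(
    mat: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitution errors; N positions are left untouched."""
    if error_rate <= 0 or mat.size == 0:
        return mat
    mask = (rng.random(mat.shape) < error_rate) & (mat < 4)
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    out = mat.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _reads_from_fragments(
    codes: np.ndarray,
    starts0: np.ndarray,
    flens: np.ndarray,
    minus: np.ndarray,
    p: ReadSimParams,
    rng: np.random.Generator,
    prefix: str,
    contig_names: Sequence[str],
    contig_idx: np.ndarray,
    local_starts0: np.ndarray,
) -> tuple[list[ReadPair], dict[str, tuple[str, int, str]]]:
    L = p.read_len
    win = np.arange(L)
    first = codes[starts0[:, None] + win]
    last = codes[(starts0 + flens - L)[:, None] + win]
    rc_last = revcomp_matrix(last)
    m1 = np.where(minus[:, None], rc_last, first)
    m2 = np.where(minus[:, None], first, rc_last)
    m1 = _apply_errors(m1, p.error_rate, rng)
    m2 = _apply_errors(m2, p.error_rate, rng)
    s1 = decode_rows(m1)
    s2 = decode_rows(m2)
    pairs: list[ReadPair] = []
    origins: dict[str, tuple[str, int, str]] = {}
    for i in range(len(starts0)):
        rid = f"{prefix}_{i:07d}"
        pairs.append(ReadPair(rid, s1[i], s2[i]))
        origins[rid] = (
            contig_names[contig_idx[i]],
            int(local_starts0[i]) + 1,
            "-" if minus[i] else "+",
        )
    return pairs, origins


def simulate_wgs_pairs(
    genome: Sequence[SequenceRecord],
    p: ReadSimParams,
    prefix: str = "wgs",
) -> tuple[list[ReadPair], dict[str, tuple[str, int, str]]]:
    """Uniform paired-end whole-genome reads over one or more contigs.

    Fragment starts are uniform per contig; contigs are chosen in
    proportion to their length.  Pair count is
    ``round(depth * total_len / (2 * read_len))``.
    """
    if not genome:
        raise ValueError("genome is empty")
    lengths = np.array([len(r) for r in genome])
    for rec in genome:
        if len(rec) < p.frag_max:
            raise ValueError(
                f"contig {rec.id!r} shorter than frag_max ({p.frag_max})"
            )
    total = int(lengths.sum())
    n_pairs = int(round(p.depth * total / (2 * p.read_len)))
    rng = np.random.default_rng(p.seed)

    offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    codes = np.concatenate([encode(r.sequence) for r in genome])
    ci = rng.choice(len(genome), size=n_pairs, p=lengths / total)
    flens = rng.integers(p.frag_min, p.frag_max + 1, size=n_pairs)
    span = lengths[ci] - flens + 1
    local0 = np.floor(rng.random(n_pairs) * span).astype(np.int64)
    starts0 = offsets[ci] + local0
    minus = rng.random(n_pairs) < 0.5
    names = [r.id for r in genome]
    return _reads_from_fragments(
        codes, starts0, flens, minus, p, rng, prefix, names, ci, local0
    )


def simulate_chip_pairs(
    locus: SequenceRecord,
    d: DomainSpec,
    p: ReadSimParams,
    prefix: str = "chip",
) -> tuple[list[ReadPair], dict[str, tuple[str, int, str]]]:
    """ChIP fragments enriched over per-homolog binding domains.

    A homolog is chosen per fragment with probability
    ``homolog_mixture`` (homolog 1).  A candidate fragment is accepted
    with weight ``enrichment_fold`` when its midpoint falls inside the
    chosen homolog's domain and weight 1 otherwise (plateau model),
    implemented by rejection sampling.
    """
    n = len(locus)
    for iv in d.intervals:
        if iv[1] > n:
            raise ValueError(f"domain {iv!r} extends past the locus ({n} nt)")
    if n < p.frag_max:
        raise ValueError("locus shorter than frag_max")
    n_pairs = int(round(p.depth * n / (2 * p.read_len)))
    rng = np.random.default_rng(p.seed)
    codes = encode(locus.sequence)
    fold = d.enrichment_fold
    iv1, iv2 = d.intervals

    starts_acc: list[np.ndarray] = []
    flens_acc: list[np.ndarray] = []
    got = 0
    while got < n_pairs:
        batch = max(2048, int((n_pairs - got) * max(fold, 1.0) * 1.3))
        flens = rng.integers(p.frag_min, p.frag_max + 1, size=batch)
        local0 = np.floor(rng.random(batch) * (n - flens + 1)).astype(np.int64)
        mids = local0 + flens // 2 + 1  # 1-based fragment midpoint
        hom1 = rng.random(batch) < d.homolog_mixture
        lo = np.where(hom1, iv1[0], iv2[0])
        hi = np.where(hom1, iv1[1], iv2[1])
        inside = (mids >= lo) & (mids <= hi)
        weight = np.where(inside, fold, 1.0)
        keep = rng.random(batch) < weight / fold
        starts_acc.append(local0[keep])
        flens_acc.append(flens[keep])
        got += int(keep.sum())
    starts0 = np.concatenate(starts_acc)[:n_pairs]
    flens = np.concatenate(flens_acc)[:n_pairs]
    minus = rng.random(n_pairs) < 0.5
    ci = np.zeros(n_pairs, dtype=np.int64)
    return _reads_from_fragments(
        codes, starts0, flens, minus, p, rng, prefix, [locus.id], ci, starts0
    )


def make_tissue_panel(
    locus: SequenceRecord,
    base: DomainSpec,
    slides: Mapping[str, int],
    p: ReadSimParams,
) -> tuple[dict[str, TissueReads], dict[str, DomainSpec]]:
    """ChIP + matched input read sets for a panel of tissues.

    Tissue ``t`` uses the base domains translated by ``slides[t]``;
    input libraries are simulated with fold 1 over the same locus.
    """
    panel: dict[str, TissueReads] = {}
    domains: dict[str, DomainSpec] = {}
    n = len(locus)
    for tissue, offset in slides.items():
        spec = base.shifted(offset)
        for iv in spec.intervals:
            if iv[0] < 1 or iv[1] > n:
                raise ValueError(
                    f"slid domain {iv!r} for tissue {tissue!r} is out of bounds"
                )
        chip_p = replace(p, seed=derive_seed(p.seed, f"{tissue}:chip"))
        input_p = replace(p, seed=derive_seed(p.seed, f"{tissue}:input"))
        chip, chip_orig = simulate_chip_pairs(
            locus, spec, chip_p, prefix=f"{tissue}_chip"
        )
        null_spec = replace(spec, enrichment_fold=1.0)
        inp, inp_orig = simulate_chip_pairs(
            locus, null_spec, input_p, prefix=f"{tissue}_input"
        )
        panel[tissue] = TissueReads(chip, inp, chip_orig, inp_orig)
        domains[tissue] = spec
    return panel, domains


def simulate_long_reads(
    genome: Sequence[SequenceRecord],
    mean_len: int = 5000,
    depth: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
    prefix: str = "long",
) -> tuple[list[SequenceRecord], dict[str, tuple[str, int, str]]]:
    """Long reads with exponential lengths truncated to [1000, contig length]."""
    if mean_len < 1000:
        raise ValueError("mean_len must be >= 1000")
    lengths = np.array([len(r) for r in genome])
    total = int(lengths.sum())
    n_reads = int(round(depth * total / mean_len))
    rng = np.random.default_rng(seed)
    ci = rng.choice(len(genome), size=n_reads, p=lengths / total)
    raw = rng.exponential(mean_len, size=n_reads)
    reads: list[SequenceRecord] = []
    origins: dict[str, tuple[str, int, str]] = {}
    for i in range(n_reads):
        rec = genome[ci[i]]
        rl = int(min(max(1000, round(raw[i])), len(rec)))
        start0 = int(rng.integers(0, len(rec) - rl + 1))
        frag = encode(rec.sequence[start0 : start0 + rl])
        minus = bool(rng.random() < 0.5)
        if minus:
            frag = revcomp_matrix(frag[None, :])[0]
        frag = _apply_errors(frag[None, :], error_rate, rng)[0]
        rid = f"{prefix}_{i:06d}"
        reads.append(SequenceRecord(id=rid, sequence=decode(frag)))
        origins[rid] = (rec.id, start0 + 1, "-" if minus else "+")
    return reads, origins
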