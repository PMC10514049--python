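"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython; SAM through pysam.  Intervals are
1-based inclusive in memory and converted to 0-based half-open only
here, at the BED/bedGraph boundary.  The liftover map is a plain
3+1-column block table (contig, old_start, old_end, new_start|deleted)
rather than any chain dialect.
"""

from __future__ import annotations

import gzip
import hashlib
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .coverage import AlignmentRecord, CoverageTrack
from .patching import LiftoverMap
from .sequences import ReadPair, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_sam",
    "read_sam",
    "write_liftover",
    "read_liftover",
    "write_truth_table",
    "sha256_of",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode or "a" in mode:
            # mtime=0 and no embedded filename keep gzip output
            # byte-identical across reruns and paths
            raw = open(path, mode.replace("t", "") + "b")
            gz = gzip.GzipFile(
                filename="", mode=mode.replace("t", ""), fileobj=raw, mtime=0
            )
            gz.myfileobj = raw  # close the underlying handle with the member
            return io.TextIOWrapper(gz) if "t" in mode else gz
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path) as fh:
        return [
            SequenceRecord(
                id=rec.id, sequence=str(rec.seq).upper(), description=rec.description
            )
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> list[ReadPair]:
    reads1 = read_fastq(r1)
    reads2 = read_fastq(r2)
    if len(reads1) != len(reads2):
        raise ValueError("R1 and R2 files have different read counts")
    pairs = []
    for (id1, s1), (id2, s2) in zip(reads1, reads2):
        base1 = id1.rsplit("/", 1)[0]
        base2 = id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(base1, s1, s2))
    return pairs


def write_fastq_pairs(
    pairs: Sequence[ReadPair], r1: str | Path, r2: str | Path
) -> None:
    """Write pairs as _R1/_R2 FASTQ (gzipped if the path ends in .gz)."""
    with _open_text(r1, "wt") as f1, _open_text(r2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
) -> None:
    """Write (contig, start, end[, name[, score[, extra...]]]) rows,
    converting 1-based inclusive to 0-based half-open."""
    with _open_text(path, "wt") as fh:
        for row in intervals:
            contig, start, end, *rest = row
            cols = [contig, str(start - 1), str(end)] + [str(x) for x in rest]
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        w = track.bin_size
        for i, v in enumerate(track.values):
            val = f"{float(v):.6g}"
            fh.write(f"{track.contig}\t{i * w}\t{(i + 1) * w}\t{val}\n")


def read_bedgraph(path: str | Path, kind: str = "difference") -> CoverageTrack:
    """Read a uniform-bin bedGraph back into a track."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            contig, s, e, v = line.split()
            rows.append((contig, int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"empty bedGraph {path}")
    contig = rows[0][0]
    bin_size = rows[0][2] - rows[0][1]
    n_bins = max(e for _, _, e, _ in rows) // bin_size + (
        1 if max(e for _, _, e, _ in rows) % bin_size else 0
    )
    values = np.zeros(n_bins)
    for c, s, e, v in rows:
        if c != contig:
            raise ValueError("multi-contig bedGraph not supported")
        values[s // bin_size] = v
    return CoverageTrack(
        contig=contig, bin_size=bin_size, values=values, kind=kind, total_mapped=0
    )


def write_sam(
    alignments: Sequence[AlignmentRecord],
    ref_lengths: dict[str, int],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in ref_lengths.items()],
    }
    names = list(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = names.index(a.contig)
            seg.reference_start = a.start - 1
            seg.mapping_quality = 60
            length = a.end - a.start + 1
            seg.cigarstring = f"{length}M"
            seg.set_tag("NM", a.n_mismatch)
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start + 1,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    n_mismatch=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                )
            )
    return out


def write_liftover(liftover: LiftoverMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("contig\told_start\told_end\tnew_start\n")
        for row in liftover.to_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_liftover(path: str | Path) -> LiftoverMap:
    blocks: dict[str, list[tuple[int, int, int | None]]] = {}
    with _open_text(path) as fh:
        next(fh)  # header
        for line in fh:
            contig, s, e, ns = line.rstrip("\n").split("\t")
            blocks.setdefault(contig, []).append(
                (int(s), int(e), None if ns == "deleted" else int(ns))
            )
    return LiftoverMap(blocks)


def write_truth_table(
    origins: dict[str, tuple[str, int, str]], path: str | Path
) -> None:
    """Plain-text read origin table: read_id, contig, start, strand."""
    with _open_text(path, "wt") as fh:
        for rid in sorted(origins):
            contig, start, strand = origins[rid]
            fh.write(f"{rid}\t{contig}\t{start}\t{strand}\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
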