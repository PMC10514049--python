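"""End-to-end orchestration: simulate -> walk -> patch -> profile ->
callpeaks -> compare.

Each stage reads only the artifacts of earlier stages from the output
directory, so stages can be re-run individually from the CLI.  All
randomness is drawn from one seeded generator per stage with the stage
name mixed into the seed; re-running with the same config and seed
reproduces byte-identical text outputs (gzip members are written with a
zero mtime for this reason).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as cio
from .coverage import (
    GenomeIndex,
    align_reads_minimal,
    count_bins,
    rpkm_normalize,
    subtract_tracks,
)
from .domains import (
    classify_panel,
    domains_from_islands,
    signal_asymmetry,
)
from .islands import Island, IslandParams, call_islands
from .patching import (
    GenomicInterval,
    LiftoverMap,
    assembly_stats,
    replace_interval,
    validate_structure,
)
from .sequences import ReadPair, SequenceRecord
from .synthetic import (
    CorruptionSpec,
    DomainSpec,
    ReadSimParams,
    corrupt_reference,
    derive_seed,
    make_tissue_panel,
    make_true_locus,
    simulate_long_reads,
    simulate_wgs_pairs,
)
from .walking import QueryIndex, WalkParams, join_pairs, resolve_region

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunManifest",
    "run_pipeline",
    "profile_on_two_references",
    "TwoReferenceReport",
    "STAGES",
]

STAGES = ("simulate", "walk", "patch", "profile", "callpeaks", "compare")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending file."""


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline (INI-style on disk)."""

    seed: int = 1
    outdir: str = "cenwalk_run"
    stages: tuple[str, ...] = STAGES

    # --- simulate: locus, corruption, domains, read sets ---
    locus_len: int = 40_000
    gc: float = 0.42
    dup_start: int = 16_000
    dup_end: int = 17_999
    sep_gap_len: int = 1000
    extra_gap_pos: int = 30_000
    extra_gap_len: int = 500
    emit_unplaced: bool = True
    domain_start: int = 14_000
    domain_end: int = 22_000
    domain2_offset: int = 0
    enrichment_fold: float = 8.0
    homolog_mixture: float = 0.5
    chip_depth: float = 30.0
    wgs_depth: float = 50.0
    long_depth: float = 20.0
    long_mean_len: int = 5000
    read_len: int = 75
    wgs_read_len: int = 150
    frag_min: int = 200
    frag_max: int = 800
    error_rate: float = 0.0
    tissues: tuple[str, ...] = (
        "fibroblast",
        "brain",
        "lamina",
        "liver",
        "testis",
    )
    slides: dict[str, int] = field(default_factory=dict)

    # --- walk ---
    query_len: int = 60
    min_support: int = 5
    min_agreement: float = 0.8
    branch_fraction: float = 0.3
    max_iterations: int = 500
    min_merge_overlap: int = 100

    # --- profile ---
    bin_size: int = 50
    seed_len: int = 24
    max_mismatch: int = 3

    # --- callpeaks ---
    window_bp: int = 200
    gap_bp: int = 1000
    fdr: float = 0.01

    # --- compare ---
    reference_sample: str = "fibroblast"
    merge_gap: int = 10_000
    min_overlap: float = 0.5

    @property
    def read_params(self) -> ReadSimParams:
        return ReadSimParams(
            read_len=self.read_len,
            frag_min=self.frag_min,
            frag_max=self.frag_max,
            depth=self.chip_depth,
            error_rate=self.error_rate,
            seed=self.seed,
        )

    @property
    def walk_params(self) -> WalkParams:
        return WalkParams(
            query_len=self.query_len,
            min_support=self.min_support,
            min_agreement=self.min_agreement,
            branch_fraction=self.branch_fraction,
            max_iterations=self.max_iterations,
            min_merge_overlap=self.min_merge_overlap,
        )

    @property
    def island_params(self) -> IslandParams:
        return IslandParams(
            window_bp=self.window_bp,
            gap_bp=self.gap_bp,
            fdr_threshold=self.fdr,
        )

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        import configparser

        parser = configparser.ConfigParser()
        parser.read(str(path))
        kwargs: dict = {}
        defaults = cls()
        for section in parser.sections():
            for key, raw in parser.items(section):
                if not hasattr(defaults, key):
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if key == "slides":
                    kwargs[key] = {
                        t.split(":")[0].strip(): int(t.split(":")[1])
                        for t in raw.split(",")
                        if t.strip()
                    }
                elif key in ("stages", "tissues"):
                    kwargs[key] = tuple(
                        t.strip() for t in raw.split(",") if t.strip()
                    )
                elif isinstance(current, bool):
                    kwargs[key] = raw.strip().lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(raw)
                elif isinstance(current, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def to_ini(self, path: str | Path) -> None:
        lines = ["[pipeline]"]
        for key, value in asdict(self).items():
            if key == "slides":
                value = ",".join(f"{t}:{o}" for t, o in value.items())
            elif isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class StageRecord:
    stage: str
    runtime_s: float
    outputs: list[tuple[str, str]]  # (path, sha256)


@dataclass
class RunManifest:
    records: list[StageRecord] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\truntime_s\toutput\tsha256\n")
            for rec in self.records:
                for out, digest in rec.outputs:
                    fh.write(
                        f"{rec.stage}\t{rec.runtime_s:.2f}\t{out}\t{digest}\n"
                    )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing input file {path}")
    return path


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    seed = derive_seed(cfg.seed, "simulate")
    locus = make_true_locus(cfg.locus_len, cfg.gc, seed)
    spec = CorruptionSpec(
        dup_block=(cfg.dup_start, cfg.dup_end),
        gap_specs=(
            (cfg.dup_end, cfg.sep_gap_len),
            (cfg.extra_gap_pos, cfg.extra_gap_len),
        ),
        emit_unplaced=cfg.emit_unplaced,
    )
    corrupted, cmap = corrupt_reference(locus, spec)

    p = ReadSimParams(
        read_len=cfg.wgs_read_len,
        frag_min=cfg.frag_min,
        frag_max=cfg.frag_max,
        depth=cfg.wgs_depth,
        error_rate=cfg.error_rate,
        seed=derive_seed(cfg.seed, "simulate:wgs"),
    )
    wgs, wgs_origins = simulate_wgs_pairs([locus], p)
    long_reads, long_origins = simulate_long_reads(
        [locus],
        mean_len=cfg.long_mean_len,
        depth=cfg.long_depth,
        error_rate=cfg.error_rate,
        seed=derive_seed(cfg.seed, "simulate:long"),
    )

    base = DomainSpec(
        homolog1=(cfg.domain_start, cfg.domain_end),
        homolog2=(
            (cfg.domain_start + cfg.domain2_offset, cfg.domain_end + cfg.domain2_offset)
            if cfg.domain2_offset
            else None
        ),
        enrichment_fold=cfg.enrichment_fold,
        homolog_mixture=cfg.homolog_mixture,
    )
    slides = {t: cfg.slides.get(t, 0) for t in cfg.tissues}
    chip_p = ReadSimParams(
        read_len=cfg.read_len,
        frag_min=cfg.frag_min,
        frag_max=cfg.frag_max,
        depth=cfg.chip_depth,
        error_rate=cfg.error_rate,
        seed=derive_seed(cfg.seed, "simulate:chip"),
    )
    panel, tissue_domains = make_tissue_panel(locus, base, slides, chip_p)

    outputs = []

    def emit(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        outputs.append(path)

    emit("true_locus.fasta", lambda p_: cio.write_fasta([locus], p_))
    emit("corrupted_ref.fasta", lambda p_: cio.write_fasta(corrupted, p_))
    cio.write_fastq_pairs(wgs, outdir / "wgs_R1.fastq.gz", outdir / "wgs_R2.fastq.gz")
    outputs += [outdir / "wgs_R1.fastq.gz", outdir / "wgs_R2.fastq.gz"]
    emit("long_reads.fasta", lambda p_: cio.write_fasta(long_reads, p_))

    origins = dict(wgs_origins)
    origins.update(long_origins)
    for tissue, tr in panel.items():
        cio.write_fastq_pairs(
            tr.chip,
            outdir / f"{tissue}_chip_R1.fastq.gz",
            outdir / f"{tissue}_chip_R2.fastq.gz",
        )
        cio.write_fastq_pairs(
            tr.input,
            outdir / f"{tissue}_input_R1.fastq.gz",
            outdir / f"{tissue}_input_R2.fastq.gz",
        )
        outputs += [
            outdir / f"{tissue}_chip_R1.fastq.gz",
            outdir / f"{tissue}_chip_R2.fastq.gz",
            outdir / f"{tissue}_input_R1.fastq.gz",
            outdir / f"{tissue}_input_R2.fastq.gz",
        ]
        origins.update(tr.chip_origins)
        origins.update(tr.input_origins)
    emit("read_origins.tsv", lambda p_: cio.write_truth_table(origins, p_))
    emit(
        "truth_domains.bed",
        lambda p_: cio.write_bed(
            [
                (locus.id, d.span[0], d.span[1], tissue)
                for tissue, d in tissue_domains.items()
            ],
            p_,
        ),
    )

    truth = {
        "locus_id": locus.id,
        "locus_len": len(locus),
        "blocks": list(cmap.blocks),
        "inserted": list(cmap.inserted),
        "misassembled_interval": cmap.misassembled_interval,
        "gap_intervals": list(cmap.gap_intervals),
        "unplaced_id": cmap.unplaced_id,
        "tissue_domains": {
            t: {
                "homolog1": d.homolog1,
                "homolog2": d.homolog2 or d.homolog1,
                "span": d.span,
                "enrichment_fold": d.enrichment_fold,
            }
            for t, d in tissue_domains.items()
        },
    }
    emit("truth.json", lambda p_: Path(p_).write_text(json.dumps(truth, indent=1)))
    return outputs


def _defective_intervals(truth: dict) -> list[tuple[int, int]]:
    """Intervals of the corrupted main contig to re-walk, rightmost first."""
    mis = truth.get("misassembled_interval")
    intervals: list[tuple[int, int]] = []
    if mis:
        intervals.append(tuple(mis))
    for s, e in truth.get("gap_intervals", []):
        if mis and mis[0] <= s <= mis[1]:
            continue  # separator gap lives inside the misassembled interval
        intervals.append((s, e))
    return sorted(intervals, reverse=True)


def stage_walk(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    ref_path = _require(outdir / "corrupted_ref.fasta", "walk")
    truth = json.loads(_require(outdir / "truth.json", "walk").read_text())
    r1 = _require(outdir / "wgs_R1.fastq.gz", "walk")
    r2 = _require(outdir / "wgs_R2.fastq.gz", "walk")
    genome = cio.read_fasta(ref_path)
    main = genome[0]
    pairs = cio.read_fastq_pairs(r1, r2)
    joined = join_pairs(pairs)
    params = cfg.walk_params

    contig = main.sequence
    log_rows = []
    intervals = _defective_intervals(truth)
    if not intervals:
        raise PipelineError("stage 'walk': no defective intervals in truth.json")
    index = QueryIndex(joined, params.query_len)
    for start, end in intervals:
        res = resolve_region(contig, (start, end), joined, params, index)
        log_rows.append(
            (
                start,
                end,
                res.status,
                res.closure.left.iterations,
                res.closure.right.iterations,
                res.closure.overlap,
            )
        )
        if res.sequence is None:
            _write_walk_log(outdir, log_rows)
            raise PipelineError(
                f"stage 'walk': region {start}-{end} not closed "
                f"(status {res.status})"
            )
        contig = res.sequence

    o_start = min(s for s, _ in intervals)
    o_end = max(e for _, e in intervals)
    tail = len(main.sequence) - o_end
    new_seq = contig[o_start - 1 : len(contig) - tail]
    walked = SequenceRecord(
        id="walked_region",
        sequence=new_seq,
        description=f"replaces {main.id}:{o_start}-{o_end}",
    )
    cio.write_fasta([walked], outdir / "walked_region.fasta")
    _write_walk_log(outdir, log_rows)
    return [outdir / "walked_region.fasta", outdir / "walk_log.tsv"]


def _write_walk_log(outdir: Path, rows) -> None:
    with open(outdir / "walk_log.tsv", "w") as fh:
        fh.write("start\tend\tstatus\titer_left\titer_right\toverlap\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def stage_patch(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    genome = cio.read_fasta(_require(outdir / "corrupted_ref.fasta", "patch"))
    walked = cio.read_fasta(_require(outdir / "walked_region.fasta", "patch"))[0]
    truth = json.loads(_require(outdir / "truth.json", "patch").read_text())
    # the walked record's description carries its target interval
    target = walked.description.split()[-1]
    contig_name, span = target.rsplit(":", 1)
    start, end = (int(x) for x in span.split("-"))
    drop = [truth["unplaced_id"]] if truth.get("unplaced_id") else []
    patched, liftover = replace_interval(
        genome, GenomicInterval(contig_name, start, end), walked.sequence, drop
    )
    cio.write_fasta(patched, outdir / "patched_ref.fasta")
    cio.write_liftover(liftover, outdir / "liftover.tsv")
    with open(outdir / "assembly_stats.tsv", "w") as fh:
        fh.write("assembly\tcontig\tlength\tn_count\tn_per_100kb\n")
        for label, records in (("original", genome), ("patched", patched)):
            for rec in records:
                st = assembly_stats(rec)
                fh.write(
                    f"{label}\t{rec.id}\t{st.length}\t{st.n_count}\t"
                    f"{st.n_per_100kb:.2f}\n"
                )

    # long-read adjudication of the single-copy structure
    long_reads = cio.read_fasta(_require(outdir / "long_reads.fasta", "patch"))
    single = patched[0].sequence
    dup_candidate = genome[0].sequence.replace("N", "")
    support = validate_structure(single, dup_candidate, long_reads)
    with open(outdir / "structure_support.tsv", "w") as fh:
        fh.write("structure\tsupporting_long_reads\n")
        fh.write(f"single_copy\t{support.support_single}\n")
        fh.write(f"tandem_duplication\t{support.support_dup}\n")
    return [
        outdir / "patched_ref.fasta",
        outdir / "liftover.tsv",
        outdir / "assembly_stats.tsv",
        outdir / "structure_support.tsv",
    ]


def _effective_len(rec: SequenceRecord) -> int:
    return len(rec) - rec.sequence.count("N")


def stage_profile(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    patched = cio.read_fasta(_require(outdir / "patched_ref.fasta", "profile"))
    main = patched[0]
    index = GenomeIndex(patched, cfg.seed_len)
    outputs = []
    for tissue in cfg.tissues:
        tracks = {}
        for role in ("chip", "input"):
            r1 = _require(outdir / f"{tissue}_{role}_R1.fastq.gz", "profile")
            r2 = _require(outdir / f"{tissue}_{role}_R2.fastq.gz", "profile")
            pairs = cio.read_fastq_pairs(r1, r2)
            aln = align_reads_minimal(
                pairs, patched, cfg.seed_len, cfg.max_mismatch, index
            )
            cio.write_sam(
                aln,
                {r.id: len(r) for r in patched},
                outdir / f"{tissue}_{role}.sam",
            )
            outputs.append(outdir / f"{tissue}_{role}.sam")
            raw = count_bins(aln, main.id, len(main), cfg.bin_size)
            tracks[role] = rpkm_normalize(raw)
            cio.write_bedgraph(
                tracks[role], outdir / f"{tissue}_{role}_rpkm.bedgraph"
            )
            outputs.append(outdir / f"{tissue}_{role}_rpkm.bedgraph")
        diff = subtract_tracks(tracks["chip"], tracks["input"])
        cio.write_bedgraph(diff, outdir / f"{tissue}_diff.bedgraph")
        outputs.append(outdir / f"{tissue}_diff.bedgraph")

    # two-reference comparison for the reference sample
    corrupted = cio.read_fasta(_require(outdir / "corrupted_ref.fasta", "profile"))
    ref_t = cfg.reference_sample
    chip_pairs = cio.read_fastq_pairs(
        outdir / f"{ref_t}_chip_R1.fastq.gz", outdir / f"{ref_t}_chip_R2.fastq.gz"
    )
    input_pairs = cio.read_fastq_pairs(
        outdir / f"{ref_t}_input_R1.fastq.gz", outdir / f"{ref_t}_input_R2.fastq.gz"
    )
    reports = profile_on_two_references(
        chip_pairs,
        input_pairs,
        corrupted,
        patched,
        island_params=cfg.island_params,
        seed_len=cfg.seed_len,
        max_mismatch=cfg.max_mismatch,
    )
    with open(outdir / "two_reference_report.tsv", "w") as fh:
        fh.write(
            "reference\tuniquely_mapped_fraction\tin_domain_dip_bins\t"
            "domain_start\tdomain_end\n"
        )
        for rep in reports:
            fh.write(
                f"{rep.label}\t{rep.unique_fraction:.4f}\t{rep.dip_bins}\t"
                f"{rep.domain[0] if rep.domain else 'NA'}\t"
                f"{rep.domain[1] if rep.domain else 'NA'}\n"
            )
    outputs.append(outdir / "two_reference_report.tsv")
    return outputs


def stage_callpeaks(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    patched = cio.read_fasta(_require(outdir / "patched_ref.fasta", "callpeaks"))
    main = patched[0]
    eff = _effective_len(main)
    outputs = []
    for tissue in cfg.tissues:
        chip = cio.read_sam(_require(outdir / f"{tissue}_chip.sam", "callpeaks"))
        inp = cio.read_sam(_require(outdir / f"{tissue}_input.sam", "callpeaks"))
        islands = call_islands(
            chip, inp, main.id, len(main), cfg.island_params, effective_len=eff
        )
        rows = [
            (
                isl.contig,
                isl.start,
                isl.end,
                f"island_{i}",
                round(-math.log10(max(isl.q_value, 1e-300)), 3),
                ".",
                isl.chip_count,
                round(isl.expected, 3),
                f"{isl.q_value:.3e}",
            )
            for i, isl in enumerate(islands)
        ]
        cio.write_bed(rows, outdir / f"{tissue}_islands.bed")
        outputs.append(outdir / f"{tissue}_islands.bed")
    return outputs


def _read_islands_bed(path: Path) -> list[Island]:
    islands = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            islands.append(
                Island(
                    contig=cols[0],
                    start=int(cols[1]) + 1,
                    end=int(cols[2]),
                    chip_count=int(cols[6]),
                    expected=float(cols[7]),
                    p_value=float(cols[8]),
                    q_value=float(cols[8]),
                )
            )
    return islands


def stage_compare(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    domains_by_tissue = {}
    tracks = {}
    for tissue in cfg.tissues:
        islands = _read_islands_bed(
            _require(outdir / f"{tissue}_islands.bed", "compare")
        )
        diff = cio.read_bedgraph(
            _require(outdir / f"{tissue}_diff.bedgraph", "compare")
        )
        tracks[tissue] = diff
        domains_by_tissue[tissue] = domains_from_islands(
            islands, diff, cfg.merge_gap
        )
    outputs = []
    for tissue, doms in domains_by_tissue.items():
        rows = []
        for i, d in enumerate(doms):
            subs = ";".join(f"{s}-{e}" for s, e in d.subdomains)
            rows.append(
                (d.contig, d.start, d.end, f"domain_{i}", round(d.area, 2), ".",
                 d.apex, subs)
            )
        cio.write_bed(rows, outdir / f"{tissue}_domains.bed")
        outputs.append(outdir / f"{tissue}_domains.bed")

    ref_t = cfg.reference_sample
    if ref_t not in domains_by_tissue:
        raise PipelineError(
            f"stage 'compare': reference sample {ref_t!r} not in panel"
        )
    others = {
        t: doms for t, doms in domains_by_tissue.items() if t != ref_t
    }
    call = classify_panel(
        domains_by_tissue[ref_t], others, min_overlap=cfg.min_overlap
    )
    with open(outdir / "conservation.tsv", "w") as fh:
        fh.write("tissue\tlabel\toverlap\tshift_bp\tasymmetry\n")
        for tissue, tc in call.per_tissue.items():
            doms = domains_by_tissue[tissue]
            asym = (
                signal_asymmetry(max(doms, key=lambda d: d.area), tracks[tissue])
                if doms
                else float("nan")
            )
            fh.write(
                f"{tissue}\t{tc.label}\t{tc.overlap:.3f}\t{tc.shift_bp:.0f}\t"
                f"{asym:.3f}\n"
            )
        fh.write(f"# summary\t{call.summary}\n")
    outputs.append(outdir / "conservation.tsv")
    return outputs


_STAGE_FN = {
    "simulate": stage_simulate,
    "walk": stage_walk,
    "patch": stage_patch,
    "profile": stage_profile,
    "callpeaks": stage_callpeaks,
    "compare": stage_compare,
}


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and hash every output."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_ini(outdir / "effective_config.ini")
    manifest = RunManifest()
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FN[stage](cfg, outdir)
        manifest.records.append(
            StageRecord(
                stage=stage,
                runtime_s=time.perf_counter() - t0,
                outputs=[
                    (p.name, cio.sha256_of(p)) for p in outputs if p.exists()
                ],
            )
        )
    manifest.to_tsv(outdir / "manifest.tsv")
    return manifest


@dataclass
class TwoReferenceReport:
    label: str
    unique_fraction: float
    dip_bins: int
    domain: tuple[int, int] | None


def profile_on_two_references(
    chip_pairs: Sequence[ReadPair],
    input_pairs: Sequence[ReadPair],
    ref_old: Sequence[SequenceRecord],
    ref_new: Sequence[SequenceRecord],
    island_params: IslandParams | None = None,
    seed_len: int = 24,
    max_mismatch: int = 3,
    dip_fraction: float = 0.10,
) -> list[TwoReferenceReport]:
    """Profile the same reads on two references and report mapping and
    peak-shape quality.

    For each reference: the uniquely-mapped fraction of ChIP mates, and
    the number of in-domain bins whose difference signal falls below
    ``dip_fraction`` of the in-domain median (coverage dips).  A false
    duplication or residual gap inside the binding domain shows up as a
    lower unique fraction and more dips.
    """
    params = island_params or IslandParams()
    out = []
    for label, ref in (("old", ref_old), ("new", ref_new)):
        index = GenomeIndex(ref, seed_len)
        chip_aln = align_reads_minimal(chip_pairs, ref, seed_len, max_mismatch, index)
        input_aln = align_reads_minimal(
            input_pairs, ref, seed_len, max_mismatch, index
        )
        unique_fraction = len(chip_aln) / (2 * len(chip_pairs))
        main = max(ref, key=len)
        eff = _effective_len(main)
        chip_raw = count_bins(chip_aln, main.id, len(main), params.window_bp)
        input_raw = count_bins(input_aln, main.id, len(main), params.window_bp)
        diff = subtract_tracks(rpkm_normalize(chip_raw), rpkm_normalize(input_raw))
        islands = call_islands(
            chip_aln, input_aln, main.id, len(main), params, effective_len=eff
        )
        doms = domains_from_islands(islands, diff)
        if not doms:
            out.append(TwoReferenceReport(label, unique_fraction, 0, None))
            continue
        dom = max(doms, key=lambda d: d.area)
        b0 = (dom.start - 1) // params.window_bp
        b1 = (dom.end - 1) // params.window_bp
        vals = np.asarray(diff.values[b0 : b1 + 1], dtype=float)
        med = float(np.median(vals))
        dips = int(np.sum(vals < dip_fraction * med))
        out.append(
            TwoReferenceReport(label, unique_fraction, dips, dom.interval)
        )
    return out
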