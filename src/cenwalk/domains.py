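"""CENP-A binding domains and their conservation across samples.

Islands from a single sample are merged into domains (broad CENP-A
binding regions, order 100 kb at full scale).  Each domain carries its
signal area, apex and epiallele sub-peaks, computed from the
ChIP-minus-input difference track.  Panels of samples (tissues of one
individual, against a reference sample such as the fibroblast line)
are classified as *conserved* or *slid* per tissue by interval overlap
and center shift — an explicit operationalization of what is otherwise
a visual judgement of stacked profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import CoverageTrack
from .islands import Island

__all__ = [
    "Domain",
    "TissueCall",
    "ConservationCall",
    "domains_from_islands",
    "overlap_coefficient",
    "center_shift",
    "split_subdomains",
    "classify_panel",
    "signal_asymmetry",
]


@dataclass
class Domain:
    contig: str
    start: int  # 1-based inclusive
    end: int
    area: float  # sum of positive difference signal within
    apex: int  # position of maximum difference signal
    subdomains: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start <= self.apex <= self.end:
            raise ValueError("apex must lie within the domain")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


def _track_slice(track: CoverageTrack, start: int, end: int) -> tuple[np.ndarray, int]:
    """(values, first_bin_index) for bins overlapping [start, end]."""
    b0 = (start - 1) // track.bin_size
    b1 = (end - 1) // track.bin_size
    return np.asarray(track.values[b0 : b1 + 1], dtype=float), b0


def domains_from_islands(
    islands: Sequence[Island],
    difference_track: CoverageTrack,
    merge_gap: int = 10_000,
) -> list[Domain]:
    """Merge islands within ``merge_gap`` into domains and profile them.

    Area is the sum of positive difference signal over the domain, the
    apex is the center of the highest-signal bin, and sub-peaks are
    split out by :func:`split_subdomains`.
    """
    if not islands:
        return []
    ivs = sorted((i.start, i.end) for i in islands)
    merged: list[list[int]] = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out: list[Domain] = []
    w = difference_track.bin_size
    for s, e in merged:
        vals, b0 = _track_slice(difference_track, s, e)
        area = float(np.sum(vals[vals > 0]))
        apex_bin = int(np.argmax(vals)) + b0
        apex = min(max(apex_bin * w + w // 2 + 1, s), e)
        dom = Domain(
            contig=difference_track.contig,
            start=s,
            end=e,
            area=area,
            apex=apex,
        )
        if area > 0:
            dom.subdomains = split_subdomains(dom, difference_track)
        else:
            dom.subdomains = [(s, e)]
        out.append(dom)
    return out


def overlap_coefficient(a: tuple[int, int], b: tuple[int, int]) -> float:
    """|a ∩ b| / min(|a|, |b|); 0 when disjoint."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0] + 1, b[1] - b[0] + 1)


def center_shift(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Absolute distance between interval midpoints, in bp."""
    return abs((a[0] + a[1]) / 2 - (b[0] + b[1]) / 2)


def split_subdomains(
    domain: Domain,
    difference_track: CoverageTrack,
    valley_fraction: float = 0.25,
    min_valley_bp: int = 2000,
) -> list[tuple[int, int]]:
    """Split a domain at deep, wide valleys between sub-peaks.

    A maximal run of at least ``min_valley_bp`` where the signal stays
    below ``valley_fraction`` times the smaller of the two flanking
    sub-peak maxima separates two epiallele sub-peaks.  Always returns
    at least one subdomain.
    """
    vals, b0 = _track_slice(difference_track, domain.start, domain.end)
    if vals.size == 0 or np.sum(vals[vals > 0]) <= 0:
        raise ValueError("cannot split a zero-area domain")
    w = difference_track.bin_size
    min_bins = max(1, min_valley_bp // w)
    prefix_max = np.maximum.accumulate(vals)
    suffix_max = np.maximum.accumulate(vals[::-1])[::-1]
    # exclude the current bin from its own flanking maxima
    left = np.concatenate([[0.0], prefix_max[:-1]])
    right = np.concatenate([suffix_max[1:], [0.0]])
    low = vals < valley_fraction * np.minimum(left, right)

    cuts: list[tuple[int, int]] = []
    i = 0
    n = len(vals)
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_bins and i > 0 and j < n:
                cuts.append((i, j))
            i = j
        else:
            i += 1
    if not cuts:
        return [(domain.start, domain.end)]
    subs: list[tuple[int, int]] = []
    seg_start = 0
    for i, j in cuts:
        subs.append((seg_start, i))
        seg_start = j
    subs.append((seg_start, n))
    out = []
    for s_bin, e_bin in subs:
        if e_bin <= s_bin:
            continue
        s = max((b0 + s_bin) * w + 1, domain.start)
        e = min((b0 + e_bin) * w, domain.end)
        out.append((s, e))
    return out or [(domain.start, domain.end)]


def signal_asymmetry(domain: Domain, difference_track: CoverageTrack) -> float:
    """Signed fraction of positive signal right vs left of the apex.

    Positive values indicate a rightward tail.  Reported per sample as a
    tail statistic; never used in conservation labels.
    """
    vals, b0 = _track_slice(difference_track, domain.start, domain.end)
    pos = np.clip(vals, 0, None)
    total = pos.sum()
    if total == 0:
        return 0.0
    apex_bin = (domain.apex - 1) // difference_track.bin_size - b0
    right = pos[apex_bin + 1 :].sum()
    left = pos[:apex_bin].sum()
    return float((right - left) / total)


@dataclass
class TissueCall:
    label: str  # "conserved" | "slid" | "absent"
    overlap: float
    shift_bp: float


@dataclass
class ConservationCall:
    per_tissue: dict[str, TissueCall]
    summary: str  # "conserved" | "not_conserved"
    reference_domain: tuple[int, int]

    def __post_init__(self) -> None:
        expected = (
            "conserved"
            if all(t.label == "conserved" for t in self.per_tissue.values())
            else "not_conserved"
        )
        if self.summary != expected:
            raise ValueError("summary inconsistent with per-tissue labels")


def classify_panel(
    reference: Sequence[Domain],
    tissues: Mapping[str, Sequence[Domain]],
    min_overlap: float = 0.5,
    max_shift_bp: float | None = None,
) -> ConservationCall:
    """Compare each tissue's domains against the reference sample.

    The reference's largest-area domain anchors the comparison.  Per
    tissue, the best-matching domain (maximal overlap coefficient, ties
    broken by smaller center shift) is *conserved* when its overlap
    coefficient is at least ``min_overlap`` and its center shift at most
    ``max_shift_bp`` (default: half the reference span); *slid*
    otherwise; *absent* when the tissue called no domains.  The summary
    is conserved only when every tissue is conserved.
    """
    if not reference:
        raise ValueError("reference sample has no domains")
    ref = max(reference, key=lambda d: d.area)
    if max_shift_bp is None:
        max_shift_bp = len(ref) / 2
    per_tissue: dict[str, TissueCall] = {}
    for name, doms in tissues.items():
        if not doms:
            per_tissue[name] = TissueCall("absent", 0.0, float("inf"))
            continue
        best = max(
            doms,
            key=lambda d: (
                overlap_coefficient(d.interval, ref.interval),
                -center_shift(d.interval, ref.interval),
            ),
        )
        ov = overlap_coefficient(best.interval, ref.interval)
        shift = center_shift(best.interval, ref.interval)
        label = (
            "conserved" if ov >= min_overlap and shift <= max_shift_bp else "slid"
        )
        per_tissue[name] = TissueCall(label, ov, shift)
    summary = (
        "conserved"
        if all(t.label == "conserved" for t in per_tissue.values())
        else "not_conserved"
    )
    return ConservationCall(
        per_tissue=per_tissue, summary=summary, reference_domain=ref.interval
    )
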