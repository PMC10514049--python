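# Methods

`cenwalk` re-implements, at desk scale, the computational workflow used
to resolve a misassembled satellite-free centromeric locus and to map
CENP-A binding domains from ChIP-seq across tissues: iterative
chromosome walking from paired-end reads, reference patching with a
coordinate liftover, RPKM-subtractive enrichment profiling, window/gap
island calling with FDR filtering, and cross-sample domain comparison.
This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## The synthetic study system

Real centromeric ChIP-seq experiments are hundreds of gigabases; the
package ships a generator that reproduces the *structure* of the
problem at a scale where every property can be tested exactly.

**True locus.** `make_true_locus` draws an i.i.d. base sequence with a
chosen GC fraction (default 0.42, a typical mammalian value). This
stands in for a unique, satellite-free locus: the essential property is
that k-mers of query length are unique, which holds overwhelmingly for
random sequence at the sizes used (10–40 kb).

**Corrupted draft.** `corrupt_reference` inverts the curation the real
study performed: it takes the truth and *inserts* the defects — a block
duplicated in tandem with an N-run separating the copies, further
N-run gaps, and optionally a redundant unplaced contig carrying the
duplicated block. The corruption map records exact old→new offsets and
the interval a caller would hand to the assembler.

**Reads.** Fragments are uniform over positions, 200–800 bp (the
sonication range of CENP-A ChIP protocols), sequenced as mate pairs
from both strands. ChIP fragments use a plateau model: a fragment whose
midpoint lies in the active homolog's binding domain is sampled with
weight `enrichment_fold`, others with weight 1. A homolog is chosen per
fragment (`homolog_mixture`, default 0.5), so two offset per-homolog
domains produce the partially-overlapping epiallele profiles seen in
real individuals. Errors are substitutions only and never produce N;
indels, quality scores, GC bias and satellite arrays are deliberately
out of scope, so passing tests demonstrate correctness of the
*algorithms*, not robustness to every artifact of real libraries.
Long reads have exponential lengths truncated to [1 kb, contig length].

Defaults that the underlying study does not state and that were fixed
once here: ChIP enrichment fold 8, sequencing depth 30× per library,
short-read length 75 bp for ChIP libraries and 150 bp for WGS
libraries (current Illumina practice; the WGS reads drive the walker,
where longer mates matter — see below), long-read depth 20× with mean
5 kb.

## Chromosome walking

`walking` implements the classic iterative loop: take the terminal
`query_len` bases of the known sequence as the query, retrieve every
joined read containing the query verbatim in either orientation
(`find_reads_by_query`, backed by an exact substring index that is
property-tested against a brute-force scan), orient the hits, and vote
column-by-column on the bases beyond the anchor (`extend_consensus`).
A column is accepted while coverage ≥ `min_support` (default 5) and the
majority fraction ≥ `min_agreement` (default 0.8). If two bases each
reach `branch_fraction` (default 0.3) at a covered column, the walk
stops and reports a branch event: heterozygous sites and repeat
junctions are surfaced, never resolved silently. Manual curation of
ambiguous consensus characters in the original protocol is automated
the same way — a column that fails agreement stops extension rather
than emitting an ambiguity code.

Queries default to 75 bp (midpoint of the 60–95 bp range used in
practice; lengths outside that range warn but are accepted). Mate-pair
distance information is deliberately not used — each mate is an
independent searchable unit — which keeps the consensus logic exact.

A quantitative constraint worth recording: a mate can only extend the
consensus by `read_len − query_len` bases past the anchor, and an
extension column is covered only by mates that contain the whole
anchor. With 75 bp mates and 60 bp queries the walk needs
≥ `min_support` mates spanning a 61 bp window, which fails somewhere in
any multi-kb walk even at 50×. With 150 bp WGS mates the per-column
failure probability drops below 10⁻⁷ and walks of tens of kb are
reliable. This is why the generator's WGS default is 150 bp.

**Gap closing.** `close_gap` walks rightward from the left flank and
leftward from the right flank (leftward walks run in reverse-complement
space), lets *both* walks run to natural termination (or to a caller
cap), and then merges if a suffix of the left-side known sequence
equals a prefix of the right-side known sequence over
≥ `min_merge_overlap` bases (default 100, exact match). Two rules
protect against repeat collapse, the classic failure of overlap
merging:

* a merge is refused outright when either walk ended at a branch —
  inside a tandem repeat the two walks overlap perfectly long before
  the copy junctions are reached, so an early or branch-crossing merge
  would silently collapse a genuine duplication;
* `resolve_region` caps each walk at the interval length plus a margin,
  so a walk never runs deep into flank territory that may contain
  other, not-yet-repaired defects whose draft sequence would poison the
  overlap verification.

Consequently, when reads genuinely carry two copies the resolver
returns `branched` and no sequence; adjudication between one and two
copies is delegated to long reads (below), exactly as in the original
study. When the reads come from a single-copy truth, the false tandem
duplication collapses to one copy and the output is byte-identical to
the truth (property-tested across seeds).

## Reference patching and liftover

`replace_interval` excises a 1-based inclusive interval, splices in the
walked contig, and drops redundant unplaced contigs. The liftover map
is an ordered block table (contig, old_start, old_end,
new_start-or-deleted): positions before the interval map identically,
positions after shift by the length difference, positions inside map to
deleted. No chain dialect is emitted — the block table is bit-exact and
trivially parseable. Assembly QC is the N count per 100 kb,
`n_count × 100000 / length`, rounded to two decimals to match the
precision such statistics are reported at.

**Long-read adjudication.** `validate_structure` compares a single-copy
and a duplicated candidate sequence. The differing region is located by
longest common prefix/suffix, extended by `anchor_len` (default 500 bp)
on both sides, and required to occur exactly once in its candidate.
For the single-copy candidate this diagnostic spans the entire
once-present block plus anchors; for the duplicated candidate it is the
copy1→copy2 junction. A long read supports a structure when it contains
that diagnostic exactly (error-free mode) or within a stated edit
fraction (edlib infix alignment); a read never supports both. At 20×
long-read depth with 5 kb mean length, several reads span the
single-copy diagnostic of a 2 kb block, while none contain the
duplication junction unless the duplication is real.

## Enrichment profiling

The aligner is intentionally minimal: exact seed (first `seed_len`
bases, default 24, both orientations), full-length ungapped
verification with ≤ `max_mismatch` substitutions (default 3), unique
best placement only. Ties are *discarded*, not placed randomly — this
keeps every downstream number deterministic and makes a falsely
duplicated reference visible as a coverage hole, which is the
phenomenon the reference-improvement check measures. Gapped alignment,
quality awareness and duplicate marking are non-goals; the subject of
the package is what happens after alignment.

Signal tracks are binned mate-start counts (default 50 bp bins),
RPKM-normalized (`count / ((bin/1000) × (total/10⁶))`), and compared
subtractively (ChIP − input, negatives preserved), mirroring
bamCompare-style subtractive RPKM normalization.

## Island calling

The caller keeps the published framework's shape — windows of
`window_bp` = 200, gaps up to `gap_bp` = 1000, FDR ≤ 0.01 — as a fully
specified, deterministic variant (byte-identical reproduction of any
external tool is a non-goal). A window is eligible when its coverage
beats a genome-wide Poisson background at upper-tail probability
< `window_p` = 0.2; eligible windows merge across ≤ `gap_bp` of
ineligible sequence; candidate islands are scored against the input
library and filtered by Benjamini–Hochberg q ≤ 0.01.

Desk-scale data put this procedure in a regime the genome-scale
original never sees: with all reads on a 40 kb locus, the background is
~80 fragments per 200 bp window, and a naive chain — eligibility on
ChIP counts plus a Poisson test of the island's ChIP count against the
scaled input count — produced a false island in ~90% of null
simulations. Three classical corrections restore calibration, and all
three are defensible on their own terms rather than desk-scale hacks:

1. **Fragment counting.** Mate pairs are collapsed to one count per
   fragment (midpoint placement) inside the caller; the two mates of
   one fragment are not independent observations, and counting them
   separately doubles the variance relative to any count model.
2. **Selection on totals.** With an input library, window eligibility
   is computed on the combined ChIP + input coverage. Under the null
   the combined total of a region is independent of how reads split
   between the libraries, so selecting candidate islands on totals
   does not bias the enrichment score (conditional inference).
3. **Exact conditional binomial score.** The island p-value is the
   binomial upper tail of the ChIP/input split given the island total,
   with success probability set by the library-size ratio. Unlike a
   Poisson test against the scaled input, this accounts for input
   sampling variance.

With these choices, 2 of 200 null simulations produce any island at
q ≤ 0.01 (the BH family-wise rate under a global null is ≤ the
threshold), while an 8-fold 8 kb domain is recovered with overlap
coefficient ~1.0 and center shift ~1 bin. The reported `expected`
count of an island remains the input count scaled by the library
ratio (floored at `input_pseudocount`), which is the scale-free
quantity: doubling both libraries doubles counts and expected alike.
ChIP-only mode scores islands against the genome-wide Poisson
background; in that mode selection and score share the same counts and
q-values are approximate — it exists for completeness, not inference.

## Domains and conservation

Significant islands within `merge_gap` = 10 kb merge into domains; each
domain carries its positive-signal area, its apex (center of the
highest difference bin), and epiallele sub-peaks: `split_subdomains`
cuts at maximal runs ≥ `min_valley_bp` = 2 kb where the signal stays
below `valley_fraction` = 0.25 of the smaller flanking sub-peak
maximum. A two-epiallele simulation (offset per-homolog domains)
yields two subdomains; coincident homolog domains yield one.

Conservation across a panel is an explicit operationalization of what
is otherwise a visual judgement of stacked profiles: per tissue, the
best-matching domain against the reference sample's largest domain
(maximal overlap coefficient |a∩b|/min(|a|,|b|), ties broken by smaller
center shift) is *conserved* iff overlap ≥ `min_overlap` = 0.5 and
center shift ≤ half the reference span; *slid* otherwise; *absent* when
no domain was called. The panel summary is conserved only if every
tissue is. A per-sample signed asymmetry statistic (signal mass right
minus left of the apex, over total) reports tail-shaped profiles but
never changes a label. The 0.5/half-span thresholds are reported in
every output so downstream users can judge them; they recover a
no-slide truth and flag a 1.5×-span slide in ≥ 95% of seeded runs.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → walk → patch → profile → callpeaks →
compare; every stage reads only prior-stage artifacts from the output
directory, so stages rerun individually from the CLI. All randomness
derives from one global seed with the stage or sample name mixed in via
CRC32; gzip members are written with zero mtime and no embedded
filename, so a rerun with the same config is byte-identical (the run
manifest records SHA-256 of every output).

The shipped defaults simulate a 40 kb locus with a 2 kb false tandem
duplication, a 1 kb separator gap, a 500 bp distal gap, an unplaced
duplicate contig, an 8 kb binding domain at fold 8, five samples
(fibroblast reference plus four tissues), 30× ChIP/input libraries,
50× WGS at 150 bp, and 20× long reads — sizes chosen so a full run
takes seconds and the statistical checks (200-replicate null, 50-seed
panels) run in minutes while keeping every rate parameter at its
study-condition value.

## Known limitations

* Substitution-only error model; the walker's consensus is not
  indel-aware.
* The aligner is ungapped with exact seeds; reads with errors in the
  seed are unmapped (symmetrically for ChIP and input, so subtractive
  profiles are unbiased).
* Exact-match walking cannot traverse repeats longer than the read
  span; such regions end as branch events by design.
* ChIP-only island mode is approximate (see above).
* Conservation thresholds are reasonable defaults, not fitted
  quantities; real cross-tissue data additionally vary in library
  quality and chromatin background in ways the generator does not
  model.
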