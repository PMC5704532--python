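# Methods

## Model and assumptions

`fmoe` corrects per-base errors in short reads under the standard Illumina
regime: substitution-dominated errors at roughly 1% per base, rare indels,
error rates that climb toward the 3' end and in high-GC regions, and
coverage deep enough (tens of fold) that the true allele at any position is
carried by many overlapping reads.  The central assumption of overlap-based
correction is that a k-mer's frequency *among the reads that overlap the
query* separates signal from noise even where a global k-mer table would
not — in particular near repeats, where globally frequent k-mers from a
diverged repeat copy must not outvote the locally correct ones.

## Index

Both strands of every read are indexed: the forward FM-index holds each
read and its reverse complement, the reversed FM-index holds the same
strings character-reversed.  A substring count in the forward index is
therefore already a both-strands frequency, and the pair supports
bidirectional single-base extension of a matched substring: extending left
is a backward-search step in the forward index; extending right is the
mirror step in the reversed index.  In either case the companion interval
is updated by symbol-count bookkeeping — the four single-base extensions
(plus read-end terminations) partition the parent interval, and they are
laid out contiguously in the companion index in symbol order, so both
intervals always have identical size.

The BWT is a plain suffix-array construction over the concatenation of all
indexed strings, each terminated by a shared sentinel; sentinel ties
resolve by suffix order of the concatenation, which is a valid total order
for counting because search patterns never contain the sentinel.  The
suffix array is built by numpy prefix doubling (O(n log² n), a few seconds
for the multi-megabase texts this package targets).  Occurrence counts are
stored as a full per-symbol cumulative int32 matrix rather than a sampled
checkpoint structure: rank becomes a single (vectorizable) array lookup,
which is what makes whole-read k-mer profiling a batched numpy operation;
the price, ~20 bytes per indexed base across both indices, is comfortable
at desk scale.  Indices can be saved to and reloaded from a single
versioned `.npz` file.

Reads containing N are excluded from indexing and passed through to the
output unchanged; correction semantics for N are undefined and dropping is
the conservative choice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| seed k | 31 bases | window length for error detection and seeding |
| spectrum sample | 10,000 k-mers | positions sampled uniformly to estimate the frequency median |
| threshold t | median × 0.5 | a window below t on either strand is low-quality |
| min path frequency | 3 reads | extension branches below this are pruned |
| max live paths w | 64 | exceeding it aborts the read (too repetitive) |
| indel tolerance d | 2 bases | half-width of the A[i−d..i+d] matching window |
| min similarity | 0.95 | paths estimated above 5% error versus the query die |
| align/vote k | 5 bases | k-mer length for interval matching and voting |
| max rounds | 2 | re-profiling passes per read |

The spectrum median uses the lower middle element for even-sized samples so
the threshold stays anchored to an observed integer frequency; t keeps its
fractional value (no flooring).  The strand test is min(freq, freq_rc) ≥ t,
which on both-strand indices reduces to the combined count — the
conservative reading of requiring both strand tracks to clear the
threshold.  d defaults to 2 because Illumina indels are rare and short; the
flag is exposed.  The align k equals the vote k: a small k lets matching
recover immediately after a mismatch and lets voting reuse the same
machinery.

## Heuristic alignment and the kill rule

Matching is done on complete k-mer intervals: the interval of the path's
newest 5-mer (recomputed by backward search on its last five bases) is
compared for equality-or-containment against the stored query intervals in
the ±d window, nearest offset first, ties toward the smaller offset.  Two
complete k-mer intervals nest only when the k-mers are identical, so a hit
pins the path k-mer to a query locus; after a hit the expected offset
re-anchors to it, keeping the window centered across indels.

A path's raw similarity is matched/attempted k-mer comparisons, and that is
the quantity tested against brute-force windowed k-mer identity.  The
*kill* decision, however, cannot use the raw ratio directly: one
substitution suppresses k consecutive matches, and since the seed is by
construction adjacent to a suspected error, every correct path opens with
such a burst and a raw 0.95 cutoff would kill it.  The rule therefore
estimates error events — each maximal unmatched run counts ceil(run/k)
events — and kills a path when events exceed
(1 − min_similarity) · (matches + events) + 2, or immediately when a single
unmatched run exceeds 3k steps (persistent divergence rather than a
burst).  Isolated bursts survive; flanks that drift from the query at a
few percent divergence — repeat copies — die within roughly ten steps.
Setting min_similarity to 0 disables both tests.  Similarity is evaluated
per step (after a k-step warm-up) so dissimilar paths are discarded without
further extension.

## Voting

Each extension step records a tree node holding the added base and the
path's SA-interval size at that depth.  Nodes at equal depth of different
branches represent disjoint read sets, so candidate frequencies add across
branches; paths that share the node covering a locus (they diverge only
later) are deduplicated by node identity and counted once.  The candidate
a path presents at a locus is read off its sequence through the
query-to-path coordinate map interpolated from its matched anchors — each
window endpoint maps through its *nearest* anchor, so an indel between the
window and a farther anchor cannot leak its shift into the mapping.  When
the flanking anchors disagree about the window's width the candidate
changes length, which is how a one-base insertion or deletion in the query
is repaired.  Ties keep the query as written, then fall back to the
lexicographically smallest candidate, so output is deterministic.

Error loci are tiled with non-overlapping vote-k-wide windows across both
low-quality runs flanking the seed's region (backward-direction paths
serve the 5' run, forward-direction paths the 3' run), the nearest error
base centered in the first window.  All edits of a pass are spliced
against the original coordinates, then the read is re-profiled; a second
pass picks up reads split into several high-quality regions.  Within a
pass, if the largest region's runs produce no edit, up to three further
regions are tried in size order.  Corrections always run against the
immutable original index — no read-after-write coupling, so read order
cannot influence results.

## Synthetic data

The generator emulates what the corrector assumes: a uniform-random
genome, uniform read starts on both strands at configurable fold coverage,
and independent per-base substitution/insertion/deletion errors, optionally
multiplied inside designated windows to mimic high-GC error elevation.  A
planted tandem-repeat block (copy count, length, per-base divergence) makes
repeat-robustness testable.  Every injected error is recorded in observed
read coordinates, and reversing the truth table reproduces the error-free
read exactly, so correction is scored positionally without an aligner
(reads carrying indels are scored by edlib edit distance instead).

What the generator does *not* model: position-dependent quality profiles,
motif-driven error hotspots, PCR duplicates, adapter contamination, paired
ends, or realistic quality strings (all bases get one placeholder score).
Passing tests therefore demonstrate the algorithm's behavior under its own
stated assumptions, not performance on any particular instrument's data.

The reference evaluation condition used by `scripts/acceptance.py` and the
end-to-end tests is a 50 kb genome, 100 bp reads, 50× coverage and 1%
substitutions — deep-coverage bacterial-like sequencing scaled to a size
that runs in about a minute — with scoring restricted to reads whose every
overlapping genome 31-mer is unique (on a random 50 kb genome that is
essentially all of them).  Smaller fixtures are used where a property does
not depend on problem size (e.g. byte-level determinism).

## Numerical and degenerate-input choices

- SA intervals are half-open `[lower, upper)`; emptiness is `lower == upper`
  and empty intervals are not positionally canonical.
- Children are expanded in fixed A,C,G,T order; all tie-breaks are
  deterministic, so identical inputs and flags give byte-identical output.
- Reads shorter than the seed k, or containing N, are passed through with a
  PASSTHROUGH status; reads whose every window is low-quality are passed
  through as UNCORRECTED_NO_SEED (no trimming or discarding).
- A read is abandoned (TOO_REPETITIVE) only when extension exceeds the
  live-path cap in some direction and no other region produced an edit.
- Qualities pass through unchanged; after a length-changing repair the
  quality string is truncated or padded with a placeholder score, so
  per-base quality provenance across an indel edit is approximate.

## Known limitations

- Errors within k−1 bases of the middle of a read shorter than ~2k leave no
  high-quality window at all; such reads are passed through.
- Reads with three or more well-separated errors may need more than the
  default two rounds; recall on them is reduced.
- Indel repair relies on anchors on both sides of the error, so indels in
  the last few bases of a read are generally not length-corrected.
- Homopolymer indels can be alignment-ambiguous; the corrector may place
  the repaired base at an equivalent but different offset, or leave the
  locus unedited when candidates tie.
- The in-memory occurrence matrix targets desk-scale data (tens of
  megabases of reads); indexing a full human-scale run is out of scope.
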