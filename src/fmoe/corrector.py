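"""Error correction by k-mer voting over overlapping reads.

Each surviving extension path presents, at every error locus, the k-mer it
carries there; the path's SA-interval size at the node completing that k-mer
is the number of reads voting for it.  Sibling paths diverging before the
locus represent disjoint read sets, so their votes add; paths sharing the
covering node are deduplicated by node identity.  The most frequent k-mer
replaces the query's k-mer at the locus — votes therefore come from
overlapping reads only, never from a global k-mer table, which is what makes
the approach robust to repeats elsewhere in the genome.
"""

from __future__ import annotations

import bisect
import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .extension import (
    BACKWARD,
    FORWARD,
    ExtensionConfig,
    ExtStatus,
    OverlapSet,
    PathState,
    build_query_intervals,
    extend_overlaps,
)
from .fmindex import IndexPair, ReadSet, build_indices
from .seeds import Region, Seed, SeedStatus, profile_read, select_seed
from .spectrum import SpectrumStats, sample_spectrum

logger = logging.getLogger(__name__)

DEFAULT_VOTE_K = 5


class CorrectionStatus(enum.Enum):
    NO_ERROR = "NO_ERROR"
    CORRECTED = "CORRECTED"
    UNCORRECTED = "UNCORRECTED"              # errors seen, no edit won a vote
    UNCORRECTED_NO_SEED = "UNCORRECTED_NO_SEED"
    TOO_REPETITIVE = "TOO_REPETITIVE"
    PASSTHROUGH = "PASSTHROUGH"              # too short / contains N


@dataclass
class CorrectionConfig:
    """End-to-end correction parameters."""

    extension: ExtensionConfig = field(default_factory=ExtensionConfig)
    vote_k: int = DEFAULT_VOTE_K
    max_rounds: int = 2


@dataclass
class Edit:
    query_offset: int
    old_kmer: str
    new_kmer: str
    winning_freq: int
    runner_up_freq: int

    @property
    def bases_changed(self) -> int:
        same = sum(a == b for a, b in zip(self.old_kmer, self.new_kmer))
        return max(len(self.old_kmer), len(self.new_kmer)) - same


@dataclass
class CorrectionRecord:
    read_id: Optional[str]
    status: CorrectionStatus
    edits: list[Edit] = field(default_factory=list)
    seed_offsets: list[int] = field(default_factory=list)
    rounds: int = 0

    @property
    def bases_changed(self) -> int:
        return sum(e.bases_changed for e in self.edits)


@dataclass
class VoteTable:
    """Candidate k-mers at one error locus with their summed frequencies."""

    locus: int
    candidates: dict[str, int]

    @property
    def empty(self) -> bool:
        return not self.candidates


def _path_candidate(
    path: PathState, seed: Seed, locus: int, vote_k: int
) -> Optional[tuple[str, int, int]]:
    """The path's k-mer over ``[locus, locus + vote_k)`` of the query.

    The query-to-path coordinate map is interpolated from the matched
    anchors bracketing the window; the seed itself contributes two identity
    anchors, so the seed-side mapping is exact and the far-side anchor
    carries any indel shift, which resizes the extracted segment (indel
    repair).  Returns (kmer, dedupe_node_id, frequency) or None when the
    path does not fully cover the window.
    """
    ks = len(seed.sequence)
    anchors = [(seed.query_offset, 0), (seed.query_offset + ks - 1, ks - 1)]
    anchors.extend(path.anchor_map)
    anchors.sort()
    q_end = locus + vote_k
    qs = [a[0] for a in anchors]

    def _nearest(q: int, prefer_left: bool) -> tuple[int, int]:
        # anchor minimizing |anchor_q - q|; an indel between the window and
        # a farther anchor must not leak its shift into the mapping
        i = bisect.bisect_left(qs, q)
        left = anchors[i - 1] if i > 0 else None
        right = anchors[i] if i < len(anchors) else None
        if left is None:
            return right
        if right is None:
            return left
        dl, dr = q - left[0], right[0] - q
        if dl == dr:
            return left if prefer_left else right
        return left if dl < dr else right

    a = _nearest(locus, prefer_left=True)
    c_start = a[1] + (locus - a[0])
    b = _nearest(q_end, prefer_left=False)
    c_end = b[1] + (q_end - b[0])
    if c_end <= c_start:
        return None
    lo, hi = path.coord_span
    if c_start < lo or c_end > hi:
        return None
    kmer = path.seq[c_start - lo : c_end - lo]
    far = c_end - 1 if path.direction == FORWARD else c_start
    node = path.node_at(far)
    return kmer, id(node), node.size


def tally_votes(
    overlaps: OverlapSet, error_locus: int, vote_k: int = DEFAULT_VOTE_K
) -> VoteTable:
    """Sum per-path k-mer frequencies over one error locus.

    Only paths of the direction that covers the locus (forward right of the
    seed, backward left of it) can contribute; paths sharing the covering
    tree node are counted once.
    """
    side = FORWARD if error_locus > overlaps.seed.query_offset else BACKWARD
    by_kmer: dict[str, dict[int, int]] = {}
    for path in overlaps.by_direction(side):
        got = _path_candidate(path, overlaps.seed, error_locus, vote_k)
        if got is None:
            continue
        kmer, node_id, freq = got
        by_kmer.setdefault(kmer, {})[node_id] = freq
    return VoteTable(
        error_locus,
        {km: sum(v.values()) for km, v in by_kmer.items()},
    )


def apply_vote(
    query: str, table: VoteTable, locus: int, vote_k: int = DEFAULT_VOTE_K
) -> tuple[str, Optional[Edit]]:
    """Replace the query's k-mer at ``locus`` with the winning candidate.

    Frequency ties keep the candidate equal to the original query k-mer when
    present (conservative no-edit), else the lexicographically smallest.
    Returns the edited query and the edit record (None when the winner
    equals the original).
    """
    if table.empty:
        return query, None
    original = query[locus : locus + vote_k]
    winner, freq = None, -1
    for km in sorted(table.candidates):  # lexicographic; first max wins ties
        v = table.candidates[km]
        if v > freq:
            winner, freq = km, v
    if table.candidates.get(original, -1) == freq:
        winner = original  # conservative tie: keep the query as written
    runner_up = max(
        (v for k, v in table.candidates.items() if k != winner), default=0
    )
    if winner == original:
        return query, None
    edited = query[:locus] + winner + query[locus + vote_k :]
    return edited, Edit(locus, original, winner, freq, runner_up)


def _error_windows(
    flags, region: Region, k_seed: int, vote_k: int, read_len: int, side: str
) -> list[int]:
    """Vote-window start offsets tiling the low-quality run on one side.

    For a run of low k-mer offsets [f0, f1) right of the region the error
    bases lie in [f0 + k_seed - 1, f1 + k_seed - 1); left of the region they
    lie in [f0, f1).  Windows of width vote_k tile the span, padded so the
    error base nearest the region sits mid-window.
    """
    pad = (vote_k - 1) // 2
    n_flags = len(flags)
    out: list[int] = []
    if side == "right":
        f0 = region.end
        if f0 >= n_flags:
            return []
        f1 = f0
        while f1 < n_flags and not flags[f1]:
            f1 += 1
        span_lo = f0 + k_seed - 1
        span_hi = read_len if f1 >= n_flags else f1 + k_seed - 1
        pos = span_lo - pad
        while pos < span_hi:
            out.append(max(0, min(pos, read_len - vote_k)))
            pos += vote_k
    else:
        f1 = region.start
        if f1 <= 0:
            return []
        f0 = f1
        while f0 > 0 and not flags[f0 - 1]:
            f0 -= 1
        pos = (f1 - 1) - pad
        while pos + vote_k > f0:
            out.append(max(0, min(pos, read_len - vote_k)))
            pos -= vote_k
    return sorted(set(out))


def _splice(query: str, edits: list[Edit], vote_k: int) -> str:
    """Apply non-overlapping edits (original coordinates) left to right."""
    parts = []
    cursor = 0
    for e in sorted(edits, key=lambda e: e.query_offset):
        parts.append(query[cursor : e.query_offset])
        parts.append(e.new_kmer)
        cursor = e.query_offset + len(e.old_kmer)
    parts.append(query[cursor:])
    return "".join(parts)


def correct_read(
    query: str,
    indices: IndexPair,
    stats: SpectrumStats,
    config: Optional[CorrectionConfig] = None,
    read_id: Optional[str] = None,
) -> tuple[str, CorrectionRecord]:
    """Correct one read against the (immutable) indices.

    Orchestrates profile -> seed -> query-interval array -> bidirectional
    extension -> per-locus voting over both low-quality runs flanking the
    seed's region, then re-profiles the edited read for up to ``max_rounds``
    passes (reads split into several high-quality regions need a second
    seed).  Never raises on well-formed input: every failure mode is a
    status on the returned record.
    """
    cfg = config or CorrectionConfig()
    record = CorrectionRecord(read_id, CorrectionStatus.NO_ERROR)
    current = query
    if len(query) < stats.k_seed or "N" in query:
        record.status = CorrectionStatus.PASSTHROUGH
        return current, record

    saw_error = False
    saw_abort = False
    max_regions_per_round = 4
    for _ in range(cfg.max_rounds):
        record.rounds += 1
        profile = profile_read(current, indices, stats, read_id)
        _, sstatus = select_seed(profile, current, indices)
        if sstatus is SeedStatus.NO_ERROR:
            break
        saw_error = True
        if sstatus is not SeedStatus.OK:
            if not record.edits:
                record.status = CorrectionStatus.UNCORRECTED_NO_SEED
                return current, record
            break
        if len(current) < cfg.extension.align_k:
            break
        A = build_query_intervals(current, indices, cfg.extension.align_k)
        regions = sorted(profile.regions, key=lambda r: (-r.size, r.start))
        edits: list[Edit] = []
        for region in regions[:max_regions_per_round]:
            seed, sstatus = select_seed(profile, current, indices, region)
            if sstatus is not SeedStatus.OK:
                continue
            record.seed_offsets.append(seed.query_offset)
            overlaps = extend_overlaps(seed, current, indices, A,
                                       cfg.extension)
            if overlaps.status is ExtStatus.TOO_REPETITIVE:
                saw_abort = True
                continue
            occupied: list[tuple[int, int]] = []
            for side in ("left", "right"):
                for locus in _error_windows(
                    profile.kmer_flags, seed.region, stats.k_seed,
                    cfg.vote_k, len(current), side,
                ):
                    if any(locus < b and locus + cfg.vote_k > a
                           for a, b in occupied):
                        continue
                    table = tally_votes(overlaps, locus, cfg.vote_k)
                    _, edit = apply_vote(current, table, locus, cfg.vote_k)
                    if edit is not None:
                        edits.append(edit)
                        occupied.append((locus, locus + cfg.vote_k))
            if edits:
                break  # re-profile before touching further regions
        if not edits:
            break
        current = _splice(current, edits, cfg.vote_k)
        record.edits.extend(edits)

    if not record.edits and saw_abort:
        record.status = CorrectionStatus.TOO_REPETITIVE
        return current, record
    if record.edits:
        record.status = CorrectionStatus.CORRECTED
    elif saw_error:
        record.status = CorrectionStatus.UNCORRECTED
    else:
        record.status = CorrectionStatus.NO_ERROR
    return current, record


@dataclass
class CorrectionSummary:
    status_counts: dict[str, int]
    corrected_bases: int
    reads: int

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [(s.value, self.status_counts.get(s.value, 0))
                for s in CorrectionStatus]
        rows.append(("corrected_bases", self.corrected_bases))
        rows.append(("reads", self.reads))
        return rows


def correct_all(
    sequences: Sequence[str],
    config: Optional[CorrectionConfig] = None,
    ids: Optional[Sequence[str]] = None,
    k_seed: int = 31,
    sample_size: int = 10_000,
    threshold_factor: float = 0.5,
    rng_seed: int = 0,
    include_reverse_complement: bool = True,
    progress_every: int = 1000,
) -> tuple[list[str], list[CorrectionRecord], CorrectionSummary]:
    """Correct every read independently against indices built once.

    Reads containing N (or shorter than the seed length) are excluded from
    indexing and passed through unchanged; input order is preserved.  The
    output is deterministic for fixed inputs and parameters.
    """
    cfg = config or CorrectionConfig()
    if ids is None:
        ids = [str(i) for i in range(len(sequences))]
    clean = [s.upper() for s in sequences]
    indexable = [s for s in clean if "N" not in s]
    if not indexable:
        raise ValueError("no reads")
    readset = ReadSet.from_sequences(clean)
    indices = build_indices(readset, include_reverse_complement)
    k_eff = min(k_seed, max(len(r) for r in indexable))
    long_enough = [r for r in indexable if len(r) >= k_eff]
    stats = sample_spectrum(
        ReadSet(long_enough),
        indices,
        k_seed=k_eff,
        sample_size=sample_size,
        rng_seed=rng_seed,
        threshold_factor=threshold_factor,
    )
    out: list[str] = []
    records: list[CorrectionRecord] = []
    counts: dict[str, int] = {}
    for i, (rid, seq) in enumerate(zip(ids, clean)):
        corrected, rec = correct_read(seq, indices, stats, cfg, rid)
        out.append(corrected)
        records.append(rec)
        counts[rec.status.value] = counts.get(rec.status.value, 0) + 1
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("corrected %d/%d reads", i + 1, len(clean))
    summary = CorrectionSummary(
        counts, sum(r.bases_changed for r in records), len(clean)
    )
    return out, records, summary
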