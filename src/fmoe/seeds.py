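"""Seed identification: classify query k-mers by frequency and pick a seed.

A seed-length window slides across the query; offsets whose both-strand
frequency drops below the spectrum threshold t mark potential error bases.
Maximal runs of high-quality offsets form high-quality regions; the seed is
the k-mer of the largest region closest to an adjacent error run, so that
extension starts right next to the error it must repair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fmindex import BiInterval, IndexPair, bi_interval_of
from .spectrum import SpectrumStats, kmer_flags


class SeedStatus(enum.Enum):
    OK = "OK"
    NO_ERROR = "NO_ERROR"          # every k-mer is high quality
    NO_SEED = "NO_SEED"            # no high-quality k-mer exists
    TOO_SHORT = "TOO_SHORT"        # query shorter than the seed length


@dataclass(frozen=True)
class Region:
    """Maximal run of high-quality k-mer offsets, half-open [start, end)."""

    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class QualityProfile:
    """Per-offset high-quality flags and their maximal-run decomposition."""

    kmer_flags: np.ndarray
    regions: list[Region]
    k_seed: int
    read_id: Optional[str] = None

    @property
    def all_high(self) -> bool:
        return self.kmer_flags.size > 0 and bool(self.kmer_flags.all())

    @property
    def none_high(self) -> bool:
        return self.kmer_flags.size == 0 or not bool(self.kmer_flags.any())


@dataclass
class Seed:
    """The anchor k-mer: sequence, query offset, owning region, BiInterval."""

    sequence: str
    query_offset: int
    region: Region
    bi: BiInterval
    error_side: str  # "left" or "right": which flank is corrected first


def _runs(flags: np.ndarray) -> list[Region]:
    regions: list[Region] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            regions.append(Region(start, i))
            start = None
    if start is not None:
        regions.append(Region(start, flags.size))
    return regions


def profile_read(
    query: str,
    indices: IndexPair,
    stats: SpectrumStats,
    read_id: Optional[str] = None,
) -> QualityProfile:
    """Flag every seed-length k-mer offset of the query as high/low quality.

    A query shorter than the seed length yields an empty profile (the read is
    passed through uncorrected by the caller).
    """
    flags = kmer_flags(query, indices, stats)
    return QualityProfile(flags, _runs(flags), stats.k_seed, read_id)


def select_seed(
    profile: QualityProfile,
    query: str,
    indices: IndexPair,
    region: Optional[Region] = None,
) -> tuple[Optional[Seed], SeedStatus]:
    """Pick the seed from the largest high-quality region.

    Returns (None, status) when the read needs no correction (all offsets
    high-quality), cannot be corrected (none high-quality), or is too short.
    Region-size ties break leftmost.  When error runs flank the region on
    both sides, the side with the longer run is taken first (ties toward the
    5' end); the seed is the region-edge k-mer abutting that side.  An
    explicit ``region`` overrides the largest-region choice (used to retry
    other regions when the first seed yields no correction).
    """
    if profile.kmer_flags.size == 0:
        return None, SeedStatus.TOO_SHORT
    if profile.all_high:
        return None, SeedStatus.NO_ERROR
    if profile.none_high:
        return None, SeedStatus.NO_SEED

    if region is None:
        region = max(profile.regions, key=lambda r: (r.size, -r.start))
    n_flags = profile.kmer_flags.size
    left_run = region.start  # false run length immediately to the left
    prev_end = 0
    next_start = n_flags
    for r in profile.regions:
        if r.end <= region.start:
            prev_end = max(prev_end, r.end)
        if r.start >= region.end and r.start < next_start:
            next_start = r.start
    left_run = region.start - prev_end
    right_run = next_start - region.end

    if left_run >= right_run and left_run > 0:
        side = "left"
        offset = region.start
    else:
        side = "right"
        offset = region.end - 1
    k = profile.k_seed
    seq = query[offset : offset + k]
    return Seed(seq, offset, region, bi_interval_of(indices, seq), side), (
        SeedStatus.OK
    )
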