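"""k-mer frequency spectrum estimation by random sampling from the index.

Rather than counting every k-mer, a fixed number of seed-length k-mers
(default 10,000) is sampled uniformly over all (read, offset) positions and
their frequencies are looked up in the FM-index; the sampled median then
yields the high-quality threshold t = median * threshold_factor (0.5 by
default).  Sampling over positions rather than distinct k-mers weights the
spectrum by abundance, which is what the threshold needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fmindex import IndexPair, ReadSet, encode, revcomp

DEFAULT_K_SEED = 31
DEFAULT_SAMPLE_SIZE = 10_000
DEFAULT_THRESHOLD_FACTOR = 0.5


@dataclass(frozen=True)
class SpectrumStats:
    """Sampled k-mer frequency statistics and the derived threshold.

    ``threshold_t`` is the floor-free product median_freq * threshold_factor;
    a k-mer offset on a query is high-quality iff its both-strand frequency
    clears this threshold.
    """

    k_seed: int
    sample_size: int
    median_freq: int
    threshold_t: float
    rng_seed: int
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR


def sample_spectrum(
    readset: ReadSet,
    indices: IndexPair,
    k_seed: int = DEFAULT_K_SEED,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    rng_seed: int = 0,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> SpectrumStats:
    """Sample k-mer frequencies and derive the high-quality threshold.

    Positions are drawn uniformly without replacement over all (read, offset)
    pairs; if fewer positions exist than ``sample_size``, every position is
    used exactly once.  Deterministic for a given ``rng_seed``.

    The median of an even-sized sample is the lower middle element, so the
    threshold stays anchored to an observed integer frequency before the
    factor is applied.
    """
    if k_seed > readset.min_length():
        raise ValueError(
            f"k_seed={k_seed} exceeds the minimum read length "
            f"{readset.min_length()}"
        )
    per_read = np.array([len(r) - k_seed + 1 for r in readset.reads])
    total = int(per_read.sum())
    if total <= 0:
        raise ValueError("no valid sample positions")
    rng = np.random.default_rng(rng_seed)
    if sample_size >= total:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=sample_size, replace=False)
        flat.sort()
    bounds = np.cumsum(per_read)
    read_idx = np.searchsorted(bounds, flat, side="right")
    offsets = flat - (bounds[read_idx] - per_read[read_idx])

    km = np.empty((flat.size, k_seed), dtype=np.uint8)
    for row, (ri, off) in enumerate(zip(read_idx, offsets)):
        km[row] = encode(readset.reads[ri][off : off + k_seed])
    lo, hi = indices.fwd.batch_kmer_intervals(km)
    freqs = np.sort(hi - lo)
    median = int(freqs[(freqs.size - 1) // 2])
    return SpectrumStats(
        k_seed=k_seed,
        sample_size=int(flat.size),
        median_freq=median,
        threshold_t=median * threshold_factor,
        rng_seed=rng_seed,
        threshold_factor=threshold_factor,
    )


def kmer_strand_freqs(indices: IndexPair, kmer: str) -> tuple[int, int]:
    """Occurrence counts of a k-mer and of its reverse complement.

    Both counts are taken from the forward index.  On indices built without
    reverse-complement doubling these are the per-strand counts among reads
    as sequenced; on RC-doubled indices the two are identical by strand
    symmetry and each already totals both strands.
    """
    f = indices.fwd.count(kmer)
    r = indices.fwd.count(revcomp(kmer))
    return f, r


def kmer_flags(query: str, indices: IndexPair, stats: SpectrumStats) -> np.ndarray:
    """Boolean high-quality flag per k-mer offset of ``query``.

    Offset i covers ``query[i : i + k_seed)``; the flag is true iff the
    frequency on both strands clears ``threshold_t`` (min of the two strand
    counts; a single combined count suffices on RC-doubled indices).
    """
    k = stats.k_seed
    n = len(query) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    codes = encode(query)
    km = np.lib.stride_tricks.sliding_window_view(codes, k)
    lo, hi = indices.fwd.batch_kmer_intervals(km)
    freq = hi - lo
    if not indices.rc_indexed:
        rc_codes = encode(revcomp(query))
        rc_km = np.lib.stride_tricks.sliding_window_view(rc_codes, k)[::-1]
        rlo, rhi = indices.fwd.batch_kmer_intervals(rc_km)
        freq = np.minimum(freq, rhi - rlo)
    return freq >= stats.threshold_t
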