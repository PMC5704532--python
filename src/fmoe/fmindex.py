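"""Multi-string FM-index over a sequencing read set.

The index is a plain Burrows-Wheeler transform of the concatenation of all
indexed strings, each terminated by a shared sentinel ``$`` (sentinel ties are
broken by the text that follows, i.e. by suffix order of the concatenation,
which is a valid total order for counting purposes because search patterns
never contain the sentinel).  Two indices are kept: one over the strings as
given ("forward") and one over each string character-reversed ("reversed"),
which together support bidirectional single-base extension of a matched
substring while maintaining one suffix-array (SA) interval per index.

Occurrence counts are stored as a full per-symbol cumulative matrix so that a
rank query is a single array lookup; this trades O(sigma * n) int32 memory for
O(1) vectorizable rank, which is the right trade at the read-set scales this
package targets (tens of megabases of indexed text).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

SENTINEL = "$"
ALPHABET = "$ACGT"
ALPHABET_SIZE = 5
_BASES = "ACGT"
_BASE_CODES = (1, 2, 3, 4)

_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _CODE_OF[ord(_ch)] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a string over ``$ACGT`` to its numeric codes (uint8)."""
    codes = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return codes


class SAInterval(NamedTuple):
    """Half-open range ``[lower, upper)`` of suffix-array ranks.

    All suffixes in the range share the matched prefix; the interval size is
    the number of occurrences of that prefix in the indexed text.
    """

    lower: int
    upper: int

    @property
    def size(self) -> int:
        return self.upper - self.lower

    @property
    def empty(self) -> bool:
        return self.upper <= self.lower

    def contains(self, other: "SAInterval") -> bool:
        """True iff ``other`` is equal to or nested inside this interval."""
        return self.lower <= other.lower and other.upper <= self.upper


class BiInterval(NamedTuple):
    """Paired SA intervals of one substring in the forward and reversed index.

    Both components always have the same size (they count the same substring
    multiset); ``size`` is that shared occurrence count.
    """

    fwd: SAInterval
    rev: SAInterval

    @property
    def size(self) -> int:
        return self.fwd.upper - self.fwd.lower

    @property
    def empty(self) -> bool:
        return self.fwd.upper <= self.fwd.lower


EMPTY_BI = BiInterval(SAInterval(0, 0), SAInterval(0, 0))


@dataclass
class ReadSet:
    """An ordered collection of DNA reads over {A,C,G,T}.

    ``dropped`` records how many input reads were removed by the N policy
    (reads containing any N are excluded from indexing; callers are expected
    to pass such reads through to the output unchanged).
    """

    reads: list[str]
    dropped: int = 0

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("no reads")
        for i, r in enumerate(self.reads):
            if not r:
                raise ValueError(f"read {i} is empty")

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReadSet":
        """Build a read set, dropping reads that contain N.

        Raises on characters outside {A,C,G,T,N}, naming read and position.
        """
        kept: list[str] = []
        dropped = 0
        for i, raw in enumerate(seqs):
            s = raw.upper()
            stripped = s.replace("A", "").replace("C", "").replace("G", "")
            stripped = stripped.replace("T", "").replace("N", "")
            if stripped:
                pos = min(s.index(ch) for ch in set(stripped))
                raise ValueError(
                    f"read {i}: invalid base {s[pos]!r} at position {pos}"
                )
            if "N" in s:
                dropped += 1
                continue
            kept.append(s)
        if not kept:
            raise ValueError("no reads")
        return cls(kept, dropped=dropped)

    @property
    def n(self) -> int:
        return len(self.reads)

    def min_length(self) -> int:
        return min(len(r) for r in self.reads)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (Manber-Myers) with numpy lexsort."""
    n = codes.size
    rank = codes.astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r1 = second[order]
        r0 = rank[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r0[1:] != r0[:-1]) | (r1[1:] != r1[:-1])
        rank[order] = np.cumsum(bump)
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


class FMIndex:
    """FM-index over a multi-string text (see module docstring).

    Attributes
    ----------
    codes : uint8 array, the BWT as symbol codes over ``$ACGT``
    C : int64 array of length 6, ``C[s]`` = count of symbols with code < s
        (so ``C[5] == text_size``)
    occ : int32 matrix (5, text_size + 1); ``occ[s, i]`` = occurrences of
        symbol ``s`` in ``bwt[0:i)``
    """

    __slots__ = ("codes", "C", "occ", "text_size", "n_strings")

    def __init__(self, bwt_codes: np.ndarray, n_strings: int):
        self.codes = bwt_codes
        self.text_size = int(bwt_codes.size)
        self.n_strings = n_strings
        counts = np.bincount(bwt_codes, minlength=ALPHABET_SIZE)
        self.C = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        occ = np.zeros((ALPHABET_SIZE, self.text_size + 1), dtype=np.int32)
        for s in range(ALPHABET_SIZE):
            np.cumsum(bwt_codes == s, out=occ[s, 1:], dtype=np.int32)
        self.occ = occ

    @classmethod
    def from_strings(cls, strings: Sequence[str]) -> "FMIndex":
        parts = []
        for s in strings:
            parts.append(encode(s))
            parts.append(np.zeros(1, dtype=np.uint8))
        text = np.concatenate(parts)
        sa = _suffix_array(text)
        bwt = text[(sa - 1) % text.size]
        return cls(bwt, len(strings))

    @property
    def bwt(self) -> str:
        return "".join(ALPHABET[c] for c in self.codes)

    def rank(self, code: int, i: int) -> int:
        """Occurrences of symbol ``code`` in ``bwt[0:i)``."""
        return int(self.occ[code, i])

    def full_interval(self) -> SAInterval:
        return SAInterval(0, self.text_size)

    def extend_backward(self, iv: SAInterval, base: str) -> SAInterval:
        """Interval of ``base + s`` where ``s`` is the string ``iv`` matches."""
        c = int(_CODE_OF[ord(base)])
        if c >= ALPHABET_SIZE:
            return SAInterval(0, 0)
        occ_c = self.occ[c]
        base_c = int(self.C[c])
        lo = base_c + int(occ_c[iv.lower])
        hi = base_c + int(occ_c[iv.upper])
        return SAInterval(lo, hi)

    def backward_search(self, pattern: str) -> SAInterval:
        """SA interval of all occurrences of ``pattern`` (empty matches all)."""
        lo, hi = 0, self.text_size
        occ = self.occ
        C = self.C
        for ch in reversed(pattern):
            c = int(_CODE_OF[ord(ch)])
            if c >= ALPHABET_SIZE:
                return SAInterval(0, 0)
            occ_c = occ[c]
            base_c = int(C[c])
            lo = base_c + int(occ_c[lo])
            hi = base_c + int(occ_c[hi])
            if lo >= hi:
                return SAInterval(lo, lo)
        return SAInterval(lo, hi)

    def count(self, pattern: str) -> int:
        return self.backward_search(pattern).size

    def batch_kmer_intervals(
        self, km_codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Backward-search many equal-length patterns in lockstep.

        ``km_codes``: (m, k) uint8 matrix of symbol codes.  Returns ``(L, U)``
        int64 arrays; rows containing a non-ACGT code come back empty.
        """
        m, k = km_codes.shape
        lo = np.zeros(m, dtype=np.int64)
        hi = np.full(m, self.text_size, dtype=np.int64)
        valid = (km_codes >= 1).all(axis=1) & (km_codes <= 4).all(axis=1)
        occ = self.occ
        C = self.C
        safe = np.where(valid, km_codes.T, 1)  # dead rows zeroed at the end
        for j in range(k - 1, -1, -1):
            c = safe[j]
            lo = C[c] + occ[c, lo]
            hi = C[c] + occ[c, hi]
        dead = ~valid | (hi < lo)
        lo[dead] = 0
        hi[dead] = 0
        return lo, hi

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` file (versioned)."""
        np.savez_compressed(
            path, version=np.int64(1), codes=self.codes,
            n_strings=np.int64(self.n_strings),
        )

    @classmethod
    def load(cls, path) -> "FMIndex":
        with np.load(path) as z:
            if int(z["version"]) != 1:
                raise ValueError(f"unsupported index version {int(z['version'])}")
            return cls(z["codes"], int(z["n_strings"]))


class IndexPair(NamedTuple):
    """Forward and reversed FM-indices over one read set."""

    fwd: FMIndex
    rev: FMIndex
    rc_indexed: bool

    def save(self, path) -> None:
        np.savez_compressed(
            path, version=np.int64(1),
            fwd_codes=self.fwd.codes, rev_codes=self.rev.codes,
            n_strings=np.int64(self.fwd.n_strings),
            rc_indexed=np.bool_(self.rc_indexed),
        )

    @classmethod
    def load(cls, path) -> "IndexPair":
        with np.load(path) as z:
            if int(z["version"]) != 1:
                raise ValueError("unsupported index version")
            n = int(z["n_strings"])
            return cls(
                FMIndex(z["fwd_codes"], n), FMIndex(z["rev_codes"], n),
                bool(z["rc_indexed"]),
            )


def build_indices(
    readset: ReadSet, include_reverse_complement: bool = True
) -> IndexPair:
    """Build the forward and reversed FM-indices for a read set.

    With ``include_reverse_complement`` (the default) each read's reverse
    complement is indexed alongside the read, so substring counts are
    strand-symmetric: reads sequenced from either genome strand contribute to
    the frequency of a k-mer written on either strand.
    """
    strings = list(readset.reads)
    if include_reverse_complement:
        strings += [revcomp(r) for r in readset.reads]
    fwd = FMIndex.from_strings(strings)
    rev = FMIndex.from_strings([s[::-1] for s in strings])
    return IndexPair(fwd, rev, include_reverse_complement)


# --- module-level operation wrappers -------------------------------------

def backward_search(index: FMIndex, pattern: str) -> SAInterval:
    return index.backward_search(pattern)


def extend_backward(index: FMIndex, iv: SAInterval, base: str) -> SAInterval:
    return index.extend_backward(iv, base)


def bi_interval_of(indices: IndexPair, s: str) -> BiInterval:
    """BiInterval of an explicit substring, via two backward searches."""
    return BiInterval(
        indices.fwd.backward_search(s), indices.rev.backward_search(s[::-1])
    )


def _extend_all(primary: FMIndex, main_iv: SAInterval, companion: SAInterval):
    """One LF partition step shared by both extension directions.

    Partitions ``main_iv`` by preceding symbol in ``primary`` and lays the
    companion interval out contiguously in symbol order ($, A, C, G, T),
    which is the suffix order of the companion index within its interval.
    Yields ``(base_code, main_sub, companion_sub)`` for codes 1..4.
    """
    occ = primary.occ
    C = primary.C
    lo, hi = main_iv.lower, main_iv.upper
    # sentinel-preceded occurrences come first in the companion interval
    start = companion.lower + (int(occ[0, hi]) - int(occ[0, lo]))
    out = []
    for c in _BASE_CODES:
        occ_c = occ[c]
        nl = int(C[c]) + int(occ_c[lo])
        nu = int(C[c]) + int(occ_c[hi])
        size = nu - nl
        out.append((c, SAInterval(nl, nu), SAInterval(start, start + size)))
        start += size
    return out


def bi_extend_all(
    indices: IndexPair, bi: BiInterval, direction: str
) -> list[tuple[str, BiInterval]]:
    """All four single-base extensions of a BiInterval in one direction.

    ``direction`` is ``"backward"`` (prepend the base) or ``"forward"``
    (append it).  Empty children are included with size 0.
    """
    if direction == "backward":
        parts = _extend_all(indices.fwd, bi.fwd, bi.rev)
        return [(_BASES[c - 1], BiInterval(m, comp)) for c, m, comp in parts]
    elif direction == "forward":
        parts = _extend_all(indices.rev, bi.rev, bi.fwd)
        return [(_BASES[c - 1], BiInterval(comp, m)) for c, m, comp in parts]
    raise ValueError(f"unknown direction {direction!r}")


def bi_extend(
    indices: IndexPair, bi: BiInterval, base: str, direction: str
) -> BiInterval:
    """Extend a BiInterval by one base on the stated side."""
    for b, child in bi_extend_all(indices, bi, direction):
        if b == base:
            return child
    raise ValueError(f"base must be one of ACGT, got {base!r}")
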