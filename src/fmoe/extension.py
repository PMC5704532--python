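"""Compressed overlap extraction: grow an extension tree from the seed.

Starting from the seed's BiInterval, the flanking sequences of all reads
containing the seed are extracted base by base in both directions.  Reads
sharing an identical flank stay compressed in a single tree path whose
frequency is the size of its SA interval.  While growing, each path is
heuristically aligned against the query by comparing the SA interval of its
newest align_k-mer with the precomputed intervals of the query's k-mers
(array A): because two complete k-mer intervals are nested only when the
k-mers are identical, a containment hit at offset j means the path and the
query share that k-mer at (or, with indels, within +-d of) the expected
locus.  Paths are pruned by frequency, by dissimilarity, and the whole
extraction aborts when the number of live paths exceeds the cap, which is
the repeat guard: flanks that diverge from the query (e.g. other copies of
a repeat) die instead of contributing votes.

Work per read is O(r * w * d) interval comparisons: each of at most w live
paths takes at most r extension steps, each step scanning a 2d+1 window.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .fmindex import (
    BiInterval,
    IndexPair,
    SAInterval,
    bi_extend_all,
    encode,
)
from .seeds import Seed

FORWARD = "forward"
BACKWARD = "backward"


class ExtStatus(enum.Enum):
    OK = "OK"
    TOO_REPETITIVE = "TOO_REPETITIVE"


@dataclass
class ExtensionConfig:
    """Tuning knobs of the extension stage.

    min_path_freq : paths whose interval drops below this are pruned (3).
    max_paths     : live-path cap w; exceeding it aborts the read (64).
    max_indel     : +-d window when matching path k-mers to query k-mers (2).
    min_similarity: paths whose estimated error rate exceeds
                    1 - min_similarity are killed (0.95, i.e. 5% errors).
    align_k       : k-mer length for interval matching and voting (5).
    max_extension : cap on total path length; None means the query length.
    error_grace   : extra error events tolerated by the kill rule, so a path
                    is not killed for isolated error bursts on the query
                    itself (the seed sits right next to a suspected error,
                    so correct paths routinely open with one burst) (2).
    """

    min_path_freq: int = 3
    max_paths: int = 64
    max_indel: int = 2
    min_similarity: float = 0.95
    align_k: int = 5
    max_extension: Optional[int] = None
    error_grace: int = 2

    def __post_init__(self) -> None:
        if self.min_path_freq < 1 or self.max_paths < 1 or self.max_indel < 0:
            raise ValueError("invalid extension config")
        if not (0.0 <= self.min_similarity <= 1.0):
            raise ValueError("min_similarity must be in [0, 1]")


class Node:
    """One extension-tree node: a single added base and its path frequency.

    ``coord`` is in seed-anchored coordinates (seed base 0 at coord 0,
    forward extension at coords >= len(seed), backward at negative coords).
    ``size`` is the SA-interval size of the whole path prefix through this
    node, i.e. how many indexed occurrences carry this exact flank.
    """

    __slots__ = ("parent", "coord", "size")

    def __init__(self, parent: Optional["Node"], coord: int, size: int):
        self.parent = parent
        self.coord = coord
        self.size = size


class PathState:
    """One live or emitted branch of the extension tree."""

    __slots__ = (
        "direction", "seq", "left_coord", "bi", "node", "match_count",
        "step_count", "closed_errors", "cur_run", "next_expected",
        "anchor_map", "alive", "frequency", "terminal", "_coord_cache",
    )

    def __init__(self, direction: str, seq: str, bi: BiInterval, node: Node,
                 left_coord: int, next_expected: int):
        self.direction = direction
        self.seq = seq
        self.left_coord = left_coord
        self.bi = bi
        self.node = node
        self.match_count = 0
        self.step_count = 0
        self.closed_errors = 0      # error events from completed unmatched runs
        self.cur_run = 0            # length of the current unmatched run
        self.next_expected = next_expected
        self.anchor_map: list[tuple[int, int]] = []  # (query_offset, coord)
        self.alive = True
        self.frequency = bi.size    # finalized at emission
        self.terminal = False
        self._coord_cache = None

    # -- derived quantities -------------------------------------------------

    @property
    def sequence(self) -> str:
        return self.seq

    @property
    def similarity(self) -> float:
        """Raw windowed k-mer identity: matched / attempted comparisons."""
        if self.step_count == 0:
            return 1.0
        return self.match_count / self.step_count

    def error_events(self, align_k: int) -> int:
        """Estimated error count: each maximal unmatched run of length L
        counts as ceil(L / align_k) events (one substitution suppresses
        align_k consecutive k-mer matches)."""
        cur = -(-self.cur_run // align_k)
        return self.closed_errors + cur

    @property
    def coord_span(self) -> tuple[int, int]:
        return self.left_coord, self.left_coord + len(self.seq)

    def base_at(self, coord: int) -> str:
        return self.seq[coord - self.left_coord]

    def _coord_nodes(self) -> dict[int, Node]:
        if self._coord_cache is None:
            by_coord: dict[int, Node] = {}
            node = self.node
            root = node
            while node is not None:
                by_coord.setdefault(node.coord, node)
                root = node
                node = node.parent
            lo, hi = self.coord_span
            for c in range(lo, hi):
                by_coord.setdefault(c, root)
            self._coord_cache = by_coord
        return self._coord_cache

    def node_at(self, coord: int) -> Node:
        """Deepest node covering a coordinate (seed coords map to the root)."""
        return self._coord_nodes()[coord]

    # -- growth helpers -----------------------------------------------------

    def branch_copy(self) -> "PathState":
        c = PathState(self.direction, self.seq, self.bi, self.node,
                      self.left_coord, self.next_expected)
        c.match_count = self.match_count
        c.step_count = self.step_count
        c.closed_errors = self.closed_errors
        c.cur_run = self.cur_run
        c.anchor_map = list(self.anchor_map)
        return c

    def snapshot(self, frequency: int) -> "PathState":
        """Emitted copy for occurrences that terminate at a read end here."""
        c = self.branch_copy()
        c.frequency = frequency
        c.terminal = True
        c.alive = False
        return c


@dataclass
class OverlapSet:
    """Surviving extension paths of one query, plus bookkeeping counters."""

    seed: Seed
    paths: list[PathState]
    status: ExtStatus
    comparisons: int = 0
    total_steps: int = 0

    def by_direction(self, direction: str) -> list[PathState]:
        return [p for p in self.paths if p.direction == direction]


def build_query_intervals(
    query: str, indices: IndexPair, align_k: int
) -> list[SAInterval]:
    """Array A: A[i] is the SA interval of ``query[i : i + align_k)``."""
    if len(query) < align_k:
        raise ValueError(
            f"query length {len(query)} is below align_k={align_k}"
        )
    import numpy as np

    codes = encode(query)
    km = np.lib.stride_tricks.sliding_window_view(codes, align_k)
    lo, hi = indices.fwd.batch_kmer_intervals(km)
    return [SAInterval(int(a), int(b)) for a, b in zip(lo, hi)]


def match_step(
    new_iv: SAInterval,
    A: list[SAInterval],
    expected_offset: int,
    d: int,
    counter: Optional[list] = None,
) -> Optional[int]:
    """Locate the query offset whose stored interval contains ``new_iv``.

    Scans ``expected_offset - d .. expected_offset + d`` nearest-first (ties
    toward the smaller offset, i.e. 0, -1, +1, -2, +2, ...), clipped to the
    array; returns the first offset whose interval equals or encloses
    ``new_iv``, or None on a mismatch/indel at this step.
    """
    if new_iv.upper <= new_iv.lower:
        return None
    n = len(A)
    for step in range(0, d + 1):
        for delta in ((-step, step) if step else (0,)):
            j = expected_offset + delta
            if 0 <= j < n:
                if counter is not None:
                    counter[0] += 1
                a = A[j]
                if (a.upper > a.lower and a.lower <= new_iv.lower
                        and new_iv.upper <= a.upper):
                    return j
    return None


def _grow_direction(
    direction: str,
    seed: Seed,
    query: str,
    indices: IndexPair,
    A: list[SAInterval],
    cfg: ExtensionConfig,
    counter: list,
) -> Optional[list[PathState]]:
    """Breadth-first growth of one direction's tree; None signals abort."""
    k = cfg.align_k
    ks = len(seed.sequence)
    q0 = seed.query_offset
    max_ext = cfg.max_extension if cfg.max_extension is not None else len(query)
    n_A = len(A)
    fwd_dir = direction == FORWARD

    root = Node(None, ks - 1 if fwd_dir else 0, seed.bi.size)
    first_expected = (q0 + ks - k + 1) if fwd_dir else (q0 - 1)
    path0 = PathState(direction, seed.sequence, seed.bi, root, 0, first_expected)

    frontier = [path0]
    finished: list[PathState] = []
    bs = indices.fwd.backward_search
    tol = 1.0 - cfg.min_similarity

    while frontier:
        new_frontier: list[PathState] = []
        for p in frontier:
            exp = p.next_expected
            out_of_query = (exp > n_A - 1) if fwd_dir else (exp < 0)
            if out_of_query or len(p.seq) >= max_ext:
                p.frequency = p.bi.size
                finished.append(p)
                continue
            children = bi_extend_all(indices, p.bi, direction)
            term = p.bi.size - sum(c.size for _, c in children)
            kids = [(b, c) for b, c in children if c.size >= cfg.min_path_freq]
            if term >= cfg.min_path_freq and kids:
                finished.append(p.snapshot(term))
            if not kids:
                p.frequency = p.bi.size
                finished.append(p)
                continue
            targets = [p] + [p.branch_copy() for _ in kids[1:]]
            for (base, cbi), t in zip(kids, targets):
                t.bi = cbi
                if fwd_dir:
                    t.seq = t.seq + base
                    new_coord = t.left_coord + len(t.seq) - 1
                    kseq = t.seq[-k:]
                else:
                    t.seq = base + t.seq
                    t.left_coord -= 1
                    new_coord = t.left_coord
                    kseq = t.seq[:k]
                t.node = Node(t.node, new_coord, cbi.size)
                counter[1] += 1
                j = match_step(bs(kseq), A, t.next_expected, cfg.max_indel,
                               counter)
                t.step_count += 1
                if j is not None:
                    t.match_count += 1
                    if t.cur_run:
                        t.closed_errors += -(-t.cur_run // k)
                        t.cur_run = 0
                    kcoord = new_coord - k + 1 if fwd_dir else new_coord
                    t.anchor_map.append((j, kcoord))
                    t.next_expected = j + 1 if fwd_dir else j - 1
                else:
                    t.cur_run += 1
                    t.next_expected += 1 if fwd_dir else -1
                if cfg.min_similarity > 0 and t.step_count >= k:
                    ev = t.error_events(k)
                    # a run beyond 3k unmatched steps means persistent
                    # divergence, not an isolated error burst
                    if t.cur_run > 3 * k or (
                        ev > tol * (t.match_count + ev) + cfg.error_grace
                    ):
                        t.alive = False
                        continue
                new_frontier.append(t)
        if len(new_frontier) > cfg.max_paths:
            return None
        frontier = new_frontier
    return finished


def extend_overlaps(
    seed: Seed,
    query: str,
    indices: IndexPair,
    A: list[SAInterval],
    config: Optional[ExtensionConfig] = None,
) -> OverlapSet:
    """Grow the extension tree in both directions from the seed.

    Returns the surviving paths per direction; an abort (live-path count
    above ``max_paths`` in either direction) yields an empty OverlapSet with
    status TOO_REPETITIVE, and the read is passed through uncorrected.
    """
    cfg = config or ExtensionConfig()
    counter = [0, 0]  # [interval comparisons, extension steps]
    paths: list[PathState] = []
    for direction in (BACKWARD, FORWARD):
        grown = _grow_direction(direction, seed, query, indices, A, cfg,
                                counter)
        if grown is None:
            return OverlapSet(seed, [], ExtStatus.TOO_REPETITIVE,
                              counter[0], counter[1])
        paths.extend(grown)
    return OverlapSet(seed, paths, ExtStatus.OK, counter[0], counter[1])
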