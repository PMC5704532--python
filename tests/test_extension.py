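"""Extension-tree growth, heuristic interval alignment, and pruning."""

import random

import pytest

from fmoe.extension import (
    BACKWARD,
    FORWARD,
    ExtStatus,
    ExtensionConfig,
    build_query_intervals,
    extend_overlaps,
    match_step,
)
from fmoe.fmindex import ReadSet, SAInterval, bi_interval_of, build_indices
from fmoe.seeds import Region, Seed

from conftest import BASES, mutate, naive_count

NO_PRUNE = ExtensionConfig(min_path_freq=1, max_paths=10**9,
                           min_similarity=0.0, max_extension=10**9)


def make_seed(ix, sequence, query_offset, side="right"):
    return Seed(sequence, query_offset, Region(0, 1),
                bi_interval_of(ix, sequence), side)


def padded_query(seed_seq, pad=40):
    """Query hosting the seed with inert padding so growth is unconstrained."""
    return "A" * pad + seed_seq + "A" * pad


def brute_force_extensions(strings, seed_seq, direction):
    """Multiset of read substrings through the seed, to each read end."""
    from collections import Counter

    out = Counter()
    for s in strings:
        for i in range(len(s) - len(seed_seq) + 1):
            if s[i : i + len(seed_seq)] == seed_seq:
                if direction == FORWARD:
                    out[s[i:]] += 1
                else:
                    out[s[: i + len(seed_seq)]] += 1
    return dict(out)


class TestQueryIntervals:
    def test_array_length_is_query_minus_k_plus_one(self, deep_fixture):
        _, _, _, ix = deep_fixture
        A = build_query_intervals("ACGTACG", ix, 3)
        assert len(A) == 5

    def test_absent_kmer_stores_empty_interval(self):
        ix = build_indices(ReadSet(["ACGTACGT"]),
                           include_reverse_complement=False)
        A = build_query_intervals("TTTTT", ix, 5)
        assert A[0].empty

    def test_intervals_match_brute_force_counts(self, rng):
        reads = ["".join(rng.choice(BASES) for _ in range(30))
                 for _ in range(8)]
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        query = reads[0]
        A = build_query_intervals(query, ix, 5)
        for i, iv in enumerate(A):
            assert iv.size == naive_count(reads, query[i : i + 5])

    def test_too_short_query_errors(self, deep_fixture):
        _, _, _, ix = deep_fixture
        with pytest.raises(ValueError):
            build_query_intervals("ACG", ix, 5)


class TestMatchStep:
    """Mismatch/indel fixtures: recovery offsets reproduce the
    preceding/succeeding-locus behavior of common-interval alignment."""

    def _setup(self, path_seq, query):
        ix = build_indices(ReadSet([path_seq]),
                           include_reverse_complement=False)
        A = build_query_intervals(query, ix, 5)
        return ix, A

    def test_identical_kmer_matches_at_expected_offset(self, rng):
        q = "".join(rng.choice(BASES) for _ in range(30))
        ix, A = self._setup(q, q)
        for i in range(len(q) - 4):
            iv = ix.fwd.backward_search(q[i : i + 5])
            assert match_step(iv, A, i, d=1) == i

    def test_mismatch_gives_none_then_recovers_at_same_locus(self, rng):
        q = "".join(rng.choice(BASES) for _ in range(30))
        p = q[:15] + mutate(q[15]) + q[16:]
        ix, A = self._setup(p, q)
        # k-mers overlapping the mismatch match nothing nearby
        for i in range(11, 16):
            iv = ix.fwd.backward_search(p[i : i + 5])
            assert match_step(iv, A, i, d=1) is None
        # the first clean k-mer after the mismatch matches at its own locus
        iv = ix.fwd.backward_search(p[16 : 21])
        assert match_step(iv, A, 16, d=1) == 16

    def test_deletion_in_path_matches_at_succeeding_locus(self, rng):
        q = "".join(rng.choice(BASES) for _ in range(30))
        p = q[:15] + q[16:]  # path lost base 15: path[i] == q[i+1] after
        ix, A = self._setup(p, q)
        iv = ix.fwd.backward_search(p[15 : 20])  # == q[16:21]
        assert match_step(iv, A, 15, d=1) == 16

    def test_insertion_in_path_matches_at_preceding_locus(self, rng):
        q = "".join(rng.choice(BASES) for _ in range(30))
        p = q[:15] + mutate(q[15]) + q[15:]  # one extra base
        ix, A = self._setup(p, q)
        iv = ix.fwd.backward_search(p[16 : 21])  # == q[15:20]
        assert match_step(iv, A, 16, d=1) == 15

    def test_empty_interval_never_matches(self, deep_fixture):
        _, _, _, ix = deep_fixture
        A = build_query_intervals("ACGTACGTAC", ix, 5)
        assert match_step(SAInterval(3, 3), A, 2, d=2) is None

    def test_window_scan_order_prefers_nearest_then_smaller(self):
        big = SAInterval(0, 100)
        A = [big, big, big, big, big]
        inner = SAInterval(10, 20)
        # all contain: nearest (the expected offset itself) wins
        assert match_step(inner, A, 2, d=2) == 2
        # expected offset excluded: smaller neighbor wins the tie
        A2 = [big, big, SAInterval(50, 60), big, big]
        assert match_step(inner, A2, 2, d=2) == 1


class TestTreeGrowth:
    def test_identical_reads_single_path_full_similarity(self, deep_fixture):
        genome, reads, rs, ix = deep_fixture
        seed_seq = genome[30:61]
        seed = make_seed(ix, seed_seq, 30)
        A = build_query_intervals(genome, ix, 5)
        ov = extend_overlaps(seed, genome, ix, A, ExtensionConfig())
        for d in (FORWARD, BACKWARD):
            paths = ov.by_direction(d)
            assert len(paths) == 1
            assert paths[0].similarity == 1.0

    def test_branching_and_frequency_pruning(self):
        reads = ["GATAC"] * 3 + ["GATAG"]
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        seed = make_seed(ix, "GAT", 40)
        query = padded_query("GAT")
        A = build_query_intervals(query, ix, 3)
        loose = ExtensionConfig(min_path_freq=1, max_paths=10**9,
                                min_similarity=0.0, align_k=3,
                                max_extension=10**9)
        ov = extend_overlaps(seed, query, ix, A, loose)
        fwd = {p.seq: p.frequency for p in ov.by_direction(FORWARD)}
        assert fwd == {"GATAC": 3, "GATAG": 1}
        strict = ExtensionConfig(min_path_freq=3, max_paths=10**9,
                                 min_similarity=0.0, align_k=3,
                                 max_extension=10**9)
        ov2 = extend_overlaps(seed, query, ix, A, strict)
        fwd2 = {p.seq: p.frequency for p in ov2.by_direction(FORWARD)}
        assert fwd2 == {"GATAC": 3}

    def test_completeness_oracle_with_pruning_disabled(self, rng):
        """Tree paths with all pruning off enumerate exactly the distinct
        read substrings through the seed, with their occurrence counts."""
        for trial in range(25):
            r = random.Random(1000 + trial)
            reads = ["".join(r.choice(BASES) for _ in range(r.randint(8, 20)))
                     for _ in range(r.randint(2, 10))]
            ix = build_indices(ReadSet(reads),
                               include_reverse_complement=False)
            donor = r.choice([s for s in reads if len(s) >= 6])
            i = r.randint(0, len(donor) - 4)
            seed_seq = donor[i : i + 4]
            seed = make_seed(ix, seed_seq, 40)
            query = padded_query(seed_seq)
            A = build_query_intervals(query, ix, 4)
            cfg = ExtensionConfig(min_path_freq=1, max_paths=10**9,
                                  min_similarity=0.0, align_k=4,
                                  max_extension=10**9)
            ov = extend_overlaps(seed, query, ix, A, cfg)
            for direction in (FORWARD, BACKWARD):
                got = {p.seq: p.frequency for p in ov.by_direction(direction)}
                assert got == brute_force_extensions(reads, seed_seq,
                                                     direction)

    def test_path_cap_aborts_on_explosive_branching(self, rng):
        seed_seq = "".join(rng.choice(BASES) for _ in range(31))
        flanks = ["".join(f) for f in __import__("itertools").product(
            BASES, repeat=4)]
        reads = [seed_seq + f for f in flanks for _ in range(3)]
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        seed = make_seed(ix, seed_seq, 40)
        query = padded_query(seed_seq)
        A = build_query_intervals(query, ix, 5)
        ov = extend_overlaps(seed, query, ix, A, ExtensionConfig())
        assert ov.status is ExtStatus.TOO_REPETITIVE
        assert ov.paths == []

    def test_dissimilar_flank_dies_similar_survives(self, rng):
        seed_seq = "".join(rng.choice(BASES) for _ in range(31))
        good = "".join(rng.choice(BASES) for _ in range(30))
        bad = "".join(mutate(b) for b in good)
        reads = [seed_seq + good] * 10 + [seed_seq + bad] * 10
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        query = seed_seq + good
        seed = make_seed(ix, seed_seq, 0)
        A = build_query_intervals(query, ix, 5)
        ov = extend_overlaps(seed, query, ix, A, ExtensionConfig())
        fwd = ov.by_direction(FORWARD)
        assert len(fwd) == 1
        assert fwd[0].seq == seed_seq + good
        assert fwd[0].similarity >= 0.95

    def test_raising_min_freq_never_adds_paths(self, rng):
        reads = ["".join(rng.choice(BASES) for _ in range(20))
                 for _ in range(10)]
        reads = reads * 3
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        seed_seq = reads[0][5:10]
        seed = make_seed(ix, seed_seq, 40)
        query = padded_query(seed_seq)
        A = build_query_intervals(query, ix, 5)
        last = None
        for f in (1, 2, 3, 5):
            cfg = ExtensionConfig(min_path_freq=f, max_paths=10**9,
                                  min_similarity=0.0, max_extension=10**9)
            n = len(extend_overlaps(seed, query, ix, A, cfg).paths)
            if last is not None:
                assert n <= last
            last = n

    def test_work_bound_is_linear_in_steps_and_window(self, deep_fixture):
        genome, reads, rs, ix = deep_fixture
        seed = make_seed(ix, genome[30:61], 30)
        A = build_query_intervals(genome, ix, 5)
        cfg = ExtensionConfig()
        ov = extend_overlaps(seed, genome, ix, A, cfg)
        assert ov.comparisons <= ov.total_steps * (2 * cfg.max_indel + 1)
        assert ov.total_steps <= 2 * len(genome) * cfg.max_paths


class TestSimilarityBruteForce:
    def test_similarity_equals_windowed_kmer_identity(self, rng):
        """Raw path similarity equals the brute-force fraction of path
        k-mers with an identical query k-mer inside the +-d window."""
        genome = "".join(rng.choice(BASES) for _ in range(100))
        query = genome[:50] + mutate(genome[50]) + genome[51:]
        reads = [genome] * 10
        ix = build_indices(ReadSet(reads), include_reverse_complement=False)
        seed_seq = query[0:31]
        seed = make_seed(ix, seed_seq, 0)
        A = build_query_intervals(query, ix, 5)
        cfg = ExtensionConfig(min_similarity=0.0, min_path_freq=1)
        ov = extend_overlaps(seed, query, ix, A, cfg)
        path = max(ov.by_direction(FORWARD), key=lambda p: len(p.seq))
        d, k = cfg.max_indel, cfg.align_k
        matched = attempted = 0
        # replay: the path's newest k-mer at step s starts at path pos 27+s
        for s in range(1, len(path.seq) - 30):
            start = 31 + s - 1 - (k - 1)
            kmer = path.seq[start : start + k]
            attempted += 1
            window = range(max(0, start - d),
                           min(len(query) - k, start + d) + 1)
            if any(query[j : j + k] == kmer for j in window):
                matched += 1
        assert path.step_count == attempted
        assert path.similarity == pytest.approx(matched / attempted)
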