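"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import random
from collections import Counter

import pytest

from fmoe.fmindex import ReadSet, build_indices

BASES = "ACGT"


def random_reads(rng: random.Random, n_reads=None, min_len=5, max_len=30):
    n = n_reads or rng.randint(1, 15)
    return [
        "".join(rng.choice(BASES) for _ in range(rng.randint(min_len, max_len)))
        for _ in range(n)
    ]


def naive_count(strings, pattern: str) -> int:
    """Occurrences of pattern across strings, overlaps included."""
    if not pattern:
        return sum(len(s) + 1 for s in strings)  # one per suffix
    total = 0
    for s in strings:
        for i in range(len(s) - len(pattern) + 1):
            if s[i : i + len(pattern)] == pattern:
                total += 1
    return total


def substring_counter(strings, max_len: int) -> Counter:
    """Counter of every substring up to max_len across strings."""
    c: Counter = Counter()
    for s in strings:
        for i in range(len(s)):
            for l in range(1, min(max_len, len(s) - i) + 1):
                c[s[i : i + l]] += 1
    return c


def mutate(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


@pytest.fixture
def rng():
    return random.Random(20260922)


@pytest.fixture
def deep_fixture(rng):
    """20 identical 100 bp reads plus their index: deep unique coverage."""
    genome = "".join(rng.choice(BASES) for _ in range(100))
    reads = [genome] * 20
    readset = ReadSet.from_sequences(reads)
    indices = build_indices(readset)
    return genome, reads, readset, indices
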