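"""Synthetic genomes and Illumina-like read sets with known injected errors.

The generator emulates the regime the corrector is designed for: a random
reference, uniform read sampling from both strands at a configurable fold
coverage, and per-base substitution/insertion/deletion errors around the
platform-typical 1% rate, optionally elevated inside designated GC-rich
windows (where real Illumina error rates climb).  Every injected error is
recorded with its position in the observed read, so correction can be scored
exactly against ground truth without any aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class RepeatSpec:
    """Plant ``copies`` diverged duplicates of one ``length``-bp segment."""

    copies: int
    length: int
    divergence: float  # per-base substitution rate between copies


@dataclass
class SimConfig:
    genome_length: int = 50_000
    coverage: float = 50.0
    read_length: int = 100
    sub_rate: float = 0.01
    ins_rate: float = 0.0
    del_rate: float = 0.0
    gc_bias: Optional[float] = None     # error-rate multiplier in GC windows
    gc_windows: tuple[tuple[int, int], ...] = ()
    repeat_spec: Optional[RepeatSpec] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")


@dataclass(frozen=True)
class TruthEntry:
    """One injected error, positioned in the observed (errored) read.

    type 'sub': observed[offset] replaced ``original``.
    type 'ins': observed[offset] is a spurious base (original is '-').
    type 'del': ``original`` was deleted before observed[offset].
    """

    read_id: str
    read_offset: int
    type: str
    original: str
    observed: str


@dataclass
class SimRead:
    read_id: str
    sequence: str       # observed (with errors)
    clean: str          # error-free sequence as sampled (strand applied)
    genome_start: int
    strand: str         # '+' or '-'


@dataclass
class SimResult:
    genome: str
    reads: list[SimRead]
    truth: list[TruthEntry]
    config: SimConfig

    def truth_by_read(self) -> dict[str, list[TruthEntry]]:
        by: dict[str, list[TruthEntry]] = {r.read_id: [] for r in self.reads}
        for t in self.truth:
            by[t.read_id].append(t)
        return by

    # -- plain-text serialization ------------------------------------------

    def write_genome_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(">genome\n")
            for i in range(0, len(self.genome), 80):
                fh.write(self.genome[i : i + 80] + "\n")

    def write_reads_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n"
                         + "I" * len(r.sequence) + "\n")

    def write_truth_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [(t.read_id, t.read_offset, t.type, t.original, t.observed)
             for t in self.truth],
            columns=["read_id", "read_offset", "type", "original", "observed"],
        ).to_csv(path, sep="\t", index=False)


def _random_genome(rng: np.random.Generator, cfg: SimConfig) -> str:
    g = rng.integers(0, 4, size=cfg.genome_length)
    genome = _BASES[g].tobytes().decode("ascii")
    if cfg.repeat_spec is not None:
        rs = cfg.repeat_spec
        if rs.copies * rs.length > cfg.genome_length:
            raise ValueError("repeat_spec does not fit in the genome")
        unit = list(genome[: rs.length])
        chunks = []
        for _ in range(rs.copies):
            copy = list(unit)
            muts = rng.random(rs.length) < rs.divergence
            for i in np.flatnonzero(muts):
                copy[i] = _BASE_STR[
                    (_BASE_STR.index(copy[i]) + rng.integers(1, 4)) % 4
                ]
            chunks.append("".join(copy))
        planted = "".join(chunks)
        genome = planted + genome[len(planted):]
    return genome


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def apply_truth(observed: str, entries: Sequence[TruthEntry]) -> str:
    """Invert a read's injected errors; the result is the clean sequence.

    This is the round-trip guarantee the truth table carries: reversing
    every recorded error reproduces the error-free read exactly.
    """
    chars = list(observed)
    # substitutions in place, then structural edits right-to-left; adjacent
    # deletions share one observed offset and must be re-inserted in
    # reverse generation order to come out in genome order
    for t in entries:
        if t.type == "sub":
            chars[t.read_offset] = t.original
    structural = [t for t in entries if t.type != "sub"]
    for t in sorted(
        enumerate(structural), key=lambda it: (-it[1].read_offset, -it[0])
    ):
        t = t[1]
        if t.type == "ins":
            del chars[t.read_offset]
        else:
            chars.insert(t.read_offset, t.original)
    return "".join(chars)


def _error_rate_at(cfg: SimConfig, genome_pos: int, base_rate: float) -> float:
    if cfg.gc_bias is not None:
        for a, b in cfg.gc_windows:
            if a <= genome_pos < b:
                return min(base_rate * cfg.gc_bias, 0.9)
    return base_rate


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a genome, an errored read set, and its truth table.

    Read start positions and strands are uniform; deterministic for a given
    ``rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genome = _random_genome(rng, cfg)
    n_reads = int(np.ceil(cfg.genome_length * cfg.coverage / cfg.read_length))
    starts = rng.integers(0, cfg.genome_length - cfg.read_length + 1,
                          size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)

    indels = cfg.ins_rate > 0 or cfg.del_rate > 0
    biased = cfg.gc_bias is not None and cfg.gc_windows
    reads: list[SimRead] = []
    truth: list[TruthEntry] = []
    for i in range(n_reads):
        start = int(starts[i])
        strand = "-" if strands[i] else "+"
        clean = genome[start : start + cfg.read_length]
        if strand == "-":
            clean = _revcomp(clean)
        rid = f"read{i}"
        entries: list[TruthEntry] = []
        if not indels and not biased:
            # vectorized substitution-only fast path
            hits = np.flatnonzero(rng.random(len(clean)) < cfg.sub_rate)
            if hits.size:
                chars = list(clean)
                for p in hits:
                    p = int(p)
                    old = chars[p]
                    new = _BASE_STR[
                        (_BASE_STR.index(old) + int(rng.integers(1, 4))) % 4
                    ]
                    chars[p] = new
                    entries.append(TruthEntry(rid, p, "sub", old, new))
                observed = "".join(chars)
            else:
                observed = clean
        else:
            out: list[str] = []
            for j, base in enumerate(clean):
                gpos = start + j
                if rng.random() < _error_rate_at(cfg, gpos, cfg.ins_rate):
                    ins = _BASE_STR[int(rng.integers(0, 4))]
                    entries.append(TruthEntry(rid, len(out), "ins", "-", ins))
                    out.append(ins)
                if rng.random() < _error_rate_at(cfg, gpos, cfg.del_rate):
                    entries.append(TruthEntry(rid, len(out), "del", base, "-"))
                    continue
                if rng.random() < _error_rate_at(cfg, gpos, cfg.sub_rate):
                    new = _BASE_STR[
                        (_BASE_STR.index(base) + int(rng.integers(1, 4))) % 4
                    ]
                    entries.append(TruthEntry(rid, len(out), "sub", base, new))
                    out.append(new)
                else:
                    out.append(base)
            observed = "".join(out)
        reads.append(SimRead(rid, observed, clean, start, strand))
        truth.extend(entries)
    return SimResult(genome, reads, truth, cfg)


@dataclass
class CorrectionMetrics:
    """Truth-based scoring of a corrected read set.

    For substitution-only simulations the counts are exact and positional;
    with indels present, per-read Levenshtein distances to the clean read
    (via edlib) quantify residual errors instead.
    """

    injected: int
    true_corrections: int
    false_edits: int
    residual_errors: int
    corrected_bases: int
    recall: float
    reads_scored: int
    per_read_corrected_length: float

    @property
    def false_edit_fraction(self) -> float:
        if self.true_corrections == 0:
            return float("inf") if self.false_edits else 0.0
        return self.false_edits / self.true_corrections


def score_correction(
    sim: SimResult,
    corrected: Sequence[str],
    restrict_read_ids: Optional[set] = None,
) -> CorrectionMetrics:
    """Score corrected reads against simulation ground truth.

    ``corrected`` must parallel ``sim.reads`` in order.  When
    ``restrict_read_ids`` is given, only those reads enter the counts (used
    to confine scoring to reads from uniquely-mappable sequence).
    """
    if len(corrected) != len(sim.reads):
        raise ValueError("corrected read list does not match the read set")
    by_read = sim.truth_by_read()
    indels = any(t.type != "sub" for t in sim.truth)
    injected = tp = fp = residual = corrected_bases = 0
    scored = 0
    total_len = 0
    for read, fixed in zip(sim.reads, corrected):
        if restrict_read_ids is not None and read.read_id not in restrict_read_ids:
            continue
        scored += 1
        entries = by_read[read.read_id]
        if not indels and len(fixed) == len(read.clean):
            err_pos = {t.read_offset for t in entries}
            injected += len(err_pos)
            for p in range(len(fixed)):
                was_err = p in err_pos
                now_ok = fixed[p] == read.clean[p]
                if was_err and now_ok:
                    tp += 1
                elif not was_err and not now_ok:
                    fp += 1
                if not now_ok:
                    residual += 1
                if fixed[p] != read.sequence[p]:
                    corrected_bases += 1
            if len(fixed) != len(read.sequence):
                corrected_bases += abs(len(fixed) - len(read.sequence))
            total_len += len(fixed)
        else:
            import edlib

            injected += len(entries)
            d_raw = edlib.align(read.sequence, read.clean)["editDistance"]
            d_fix = edlib.align(fixed, read.clean)["editDistance"]
            gain = d_raw - d_fix
            tp += max(gain, 0)
            fp += max(-gain, 0)
            residual += d_fix
            corrected_bases += edlib.align(fixed, read.sequence)["editDistance"]
            total_len += len(fixed)
    recall = tp / injected if injected else 1.0
    return CorrectionMetrics(
        injected=injected,
        true_corrections=tp,
        false_edits=fp,
        residual_errors=residual,
        corrected_bases=corrected_bases,
        recall=recall,
        reads_scored=scored,
        per_read_corrected_length=(total_len / scored if scored else 0.0),
    )


def unique_context_read_ids(sim: SimResult, k: int = 31) -> set:
    """Read ids whose genomic footprint lies in uniquely-mappable sequence.

    A position is unique when every genome k-mer overlapping the read's
    source interval occurs exactly once in the genome (both strands).
    """
    from collections import Counter

    g = sim.genome
    counts: Counter = Counter()
    for i in range(len(g) - k + 1):
        km = g[i : i + k]
        counts[min(km, _revcomp(km))] += 1
    ok = np.ones(len(g) - k + 1, dtype=bool)
    for i in range(len(g) - k + 1):
        km = g[i : i + k]
        if counts[min(km, _revcomp(km))] > 1:
            ok[i] = False
    out = set()
    for r in sim.reads:
        a = max(0, r.genome_start - 0)
        b = min(len(g) - k + 1, r.genome_start + sim.config.read_length - k + 1)
        if a < b and ok[a:b].all():
            out.add(r.read_id)
    return out
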