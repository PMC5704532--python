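"""FASTA/FASTQ reading and writing for the correction pipeline.

Thin wrappers over Biopython's SeqIO.  Qualities are passed through
unchanged for length-preserving corrections; when an indel repair changes
the read length the quality string is spliced to the new length with a
placeholder score for gained bases.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}


def sniff_format(path) -> str:
    ext = Path(path).suffix.lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def read_records(path, fmt: Optional[str] = None) -> list[SeqRecord]:
    fmt = fmt or sniff_format(path)
    return list(SeqIO.parse(str(path), fmt))


def _adjust_quals(quals: list[int], old_len: int, new_len: int,
                  placeholder: int) -> list[int]:
    if new_len == old_len:
        return quals
    if new_len < old_len:
        return quals[:new_len]
    return quals + [placeholder] * (new_len - len(quals))


def write_corrected(
    records: list[SeqRecord],
    corrected: list[str],
    path,
    fmt: Optional[str] = None,
    placeholder_quality: int = 40,
) -> None:
    """Write corrected sequences, preserving ids, order and qualities."""
    fmt = fmt or sniff_format(path)
    out = []
    for rec, seq in zip(records, corrected):
        new = SeqRecord(Seq(seq), id=rec.id, name=rec.name,
                        description=rec.description)
        if fmt == "fastq":
            quals = rec.letter_annotations.get(
                "phred_quality", [placeholder_quality] * len(rec.seq)
            )
            new.letter_annotations["phred_quality"] = _adjust_quals(
                list(quals), len(rec.seq), len(seq), placeholder_quality
            )
        out.append(new)
    SeqIO.write(out, str(path), fmt)


def write_summary_tsv(summary, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for name, value in summary.as_rows():
            fh.write(f"{name}\t{value}\n")
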