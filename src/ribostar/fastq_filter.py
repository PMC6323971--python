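"""CLIP read preprocessing: quality filter, length filter, duplicate collapse.

The three rules applied to adaptor-trimmed reads before alignment:

* keep reads with quality strictly above Q20 in at least 80% of bases,
* discard reads shorter than 13 nt,
* collapse identical sequences to one representative (first occurrence),
  recording the multiplicity, to minimize PCR duplicates.

Inequality senses (strict "above 20", non-strict "80% of their
nucleotides") are configurable since either reading is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_QUALITY = 20
DEFAULT_QUALITY_FRACTION = 0.80
DEFAULT_MIN_LENGTH = 13


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def quality_filter(
    reads: Iterable[ReadRecord],
    q: int = DEFAULT_MIN_QUALITY,
    fraction: float = DEFAULT_QUALITY_FRACTION,
) -> list[ReadRecord]:
    """Retain reads with quality > q in at least ``fraction`` of bases."""
    out = []
    for read in reads:
        n = len(read)
        if n and sum(1 for s in read.qualities if s > q) / n >= fraction:
            out.append(read)
    return out


def length_filter(
    reads: Iterable[ReadRecord], min_len: int = DEFAULT_MIN_LENGTH
) -> list[ReadRecord]:
    """Discard reads shorter than ``min_len`` nt."""
    return [read for read in reads if len(read) >= min_len]


def collapse_duplicates(
    reads: Iterable[ReadRecord],
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """One representative per distinct sequence plus a multiplicity table.

    The representative keeps the first occurrence's id and qualities;
    first-occurrence order is preserved. The sum of multiplicities equals
    the input read count.
    """
    order: dict[str, ReadRecord] = {}
    counts: dict[str, int] = {}
    for read in reads:
        if read.sequence not in order:
            order[read.sequence] = read
        counts[read.sequence] = counts.get(read.sequence, 0) + 1
    unique = list(order.values())
    table = pd.DataFrame(
        {
            "read_id": [r.read_id for r in unique],
            "sequence": [r.sequence for r in unique],
            "count": [counts[r.sequence] for r in unique],
        }
    )
    return unique, table


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (Phred+33 by default, +64 via ``phred_offset``)."""
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    for rec in SeqIO.parse(str(path), fmt):
        yield ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(
    reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33
) -> int:
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    return SeqIO.write(records, str(path), fmt)
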