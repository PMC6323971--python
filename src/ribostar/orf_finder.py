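"""ORF enumeration and seven-way categorization on transcript models.

An ORF is any AUG paired with its *nearest* downstream in-frame stop codon
(UAA/UAG/UGA), stop included in the interval. Each ORF on an annotated
transcript is placed into exactly one category by its position relative to
the transcript's own annotated ORF (aORF = the CDS of that isoform):

* ``annotated``  — identical interval to the aORF
* ``truncated``  — same stop codon, start downstream of the aORF start
* ``extended``   — same stop codon, start upstream
* ``internal``   — overlaps the aORF without sharing its stop (off-frame)
* ``uorf``/``dorf`` — entirely upstream / downstream of the aORF
* ``unannotated`` — any ORF on a transcript with no CDS annotation

ORFs shorter than 300 nt carry the small-ORF flag (``is_sorf``).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .annotation_io import (
    GenomeSequence,
    TranscriptModel,
    TranscriptSequence,
    extract_sequence,
)

log = logging.getLogger(__name__)

START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: sORF threshold in nt, stop codon included in the length.
SORF_THRESHOLD_NT = 300


class OrfCategory(str, Enum):
    ANNOTATED = "annotated"
    TRUNCATED = "truncated"
    EXTENDED = "extended"
    INTERNAL = "internal"
    UORF = "uorf"
    DORF = "dorf"
    UNANNOTATED = "unannotated"


@dataclass
class Orf:
    """One AUG->stop interval in transcript coordinates (stop included)."""

    transcript_id: str
    start: int
    end: int
    category: OrfCategory | None = None

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def is_sorf(self) -> bool:
        return self.length_nt < SORF_THRESHOLD_NT

    @property
    def orf_id(self) -> str:
        cat = self.category.value if self.category else "uncategorized"
        return f"{self.transcript_id}:{self.start}-{self.end}:{cat}"


def enumerate_orfs(
    sequence: TranscriptSequence, sorf_threshold: int = SORF_THRESHOLD_NT
) -> list[Orf]:
    """Emit one ORF per AUG, ending at the nearest downstream in-frame stop.

    Linear scan: stop-codon positions are indexed per frame once, then each
    AUG takes the first in-frame stop after it by bisection. AUGs with no
    downstream in-frame stop within the transcript emit nothing. Codons
    containing N never match AUG or a stop. Output sorted by start then end.
    """
    seq = sequence.sequence
    n = len(seq)
    stops_by_frame: tuple[list[int], list[int], list[int]] = ([], [], [])
    starts: list[int] = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon == START_CODON:
            starts.append(i)
        elif codon in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    orfs: list[Orf] = []
    for a in starts:
        frame_stops = stops_by_frame[a % 3]
        j = bisect.bisect_left(frame_stops, a + 3)
        if j < len(frame_stops):
            orfs.append(Orf(sequence.transcript_id, a, frame_stops[j] + 3))
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def categorize(orf: Orf, model: TranscriptModel) -> OrfCategory:
    """Assign the ORF to its category relative to the model's aORF.

    The decision cascade runs in a fixed order so the categories partition
    the output: unannotated, annotated, same-stop (truncated/extended),
    any overlap (internal), then fully upstream (uorf) / downstream (dorf).
    """
    if orf.start < 0 or orf.end > model.length:
        raise ValueError(
            f"ORF [{orf.start}, {orf.end}) outside transcript "
            f"{model.transcript_id} of length {model.length}"
        )
    aorf = model.cds_transcript_interval()
    if aorf is None:
        return OrfCategory.UNANNOTATED
    a_start, a_end = aorf
    if (orf.start, orf.end) == (a_start, a_end):
        return OrfCategory.ANNOTATED
    if orf.end == a_end:
        return OrfCategory.TRUNCATED if orf.start > a_start else OrfCategory.EXTENDED
    if orf.start < a_end and orf.end > a_start:
        return OrfCategory.INTERNAL
    if orf.end <= a_start:
        return OrfCategory.UORF
    return OrfCategory.DORF


def scan_transcriptome(
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    sorf_threshold: int = SORF_THRESHOLD_NT,
    min_length: int = 6,
) -> pd.DataFrame:
    """Enumerate and categorize every ORF on every transcript.

    Returns a table with one row per ORF; per-category counts go to the
    run log.
    """
    if isinstance(models, Mapping):
        models = list(models.values())
    rows = []
    for model in models:
        seq = extract_sequence(model, genome)
        for orf in enumerate_orfs(seq):
            if orf.length_nt < min_length:
                continue
            orf.category = categorize(orf, model)
            rows.append(
                {
                    "orf_id": orf.orf_id,
                    "transcript_id": model.transcript_id,
                    "gene_id": model.gene_id,
                    "start": orf.start,
                    "end": orf.end,
                    "frame": orf.frame,
                    "category": orf.category.value,
                    "length_nt": orf.length_nt,
                    "is_sorf": orf.length_nt < sorf_threshold,
                }
            )
    columns = [
        "orf_id",
        "transcript_id",
        "gene_id",
        "start",
        "end",
        "frame",
        "category",
        "length_nt",
        "is_sorf",
    ]
    table = pd.DataFrame(rows, columns=columns)
    counts = table["category"].value_counts().to_dict() if len(table) else {}
    log.info(
        "scanned %d transcripts: %d ORFs (%s)",
        len(models),
        len(table),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none",
    )
    return table


def orfs_to_bed12(
    table: pd.DataFrame, models: Mapping[str, TranscriptModel]
) -> list[str]:
    """Project ORFs back to genome coordinates as BED12 lines."""
    lines = []
    for row in table.itertuples():
        m = models[row.transcript_id]
        gpos = sorted(m.transcript_to_genome(t) for t in range(row.start, row.end))
        blocks: list[tuple[int, int]] = []
        for p in gpos:
            if blocks and blocks[-1][1] == p:
                blocks[-1] = (blocks[-1][0], p + 1)
            else:
                blocks.append((p, p + 1))
        chrom_start, chrom_end = blocks[0][0], blocks[-1][1]
        sizes = ",".join(str(e - s) for s, e in blocks)
        offsets = ",".join(str(s - chrom_start) for s, _ in blocks)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    m.chrom,
                    chrom_start,
                    chrom_end,
                    row.orf_id,
                    0,
                    m.strand,
                    chrom_start,
                    chrom_end,
                    "0,0,0",
                    len(blocks),
                    sizes,
                    offsets,
                )
            )
        )
    return lines
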