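"""P-site offset inference and per-transcript signal tracks.

For each footprint length L, the 5' distance from read ends to annotated
start codons is collected over reads landing in a window upstream of a
start codon; the per-length mode of that distance (restricted to
0 <= d < L) is the P-site offset. Applying offset(L) to every read of
length L yields one count per read at its inferred P-site, accumulated
into per-nucleotide transcript tracks.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .annotation_io import TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 40
DEFAULT_MIN_SUPPORT = 10


@dataclass(frozen=True)
class AlignedRead:
    """One footprint on a transcript: 5' end offset and read length."""

    transcript_id: str
    five_prime: int
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.five_prime < 0:
            raise ValueError("five_prime must be >= 0")


@dataclass
class PsiteOffsets:
    """Per-read-length 5'-end -> P-site offsets with supporting read counts."""

    offsets: dict[int, int] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValueError(
                    f"offset {off} out of range for read length {length}"
                )

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class SignalTrack:
    """Per-nucleotide counts along one transcript."""

    transcript_id: str
    values: np.ndarray
    source: str = "psite"  # raw | psite | denoised

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("track values must be non-negative")
        if self.source not in ("raw", "psite", "denoised"):
            raise ValueError(f"unknown track source {self.source!r}")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def infer_offsets(
    reads: Iterable[AlignedRead],
    models: Mapping[str, TranscriptModel],
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> PsiteOffsets:
    """Infer the per-length P-site offset from reads near start codons.

    For each read whose 5' end lies within ``window`` nt upstream of (or
    on) an annotated start codon, record d = start_codon - five_prime.
    offset(L) is the mode of d over reads of length L with 0 <= d < L;
    ties break toward the smaller offset. Lengths supported by fewer than
    ``min_support`` such reads are omitted.
    """
    starts: dict[str, int] = {}
    for tid, model in models.items():
        iv = model.cds_transcript_interval()
        if iv is not None:
            starts[tid] = iv[0]
    if not starts:
        raise ValueError("no annotated CDS among the transcript models")

    dists: dict[int, Counter[int]] = defaultdict(Counter)
    for read in reads:
        s = starts.get(read.transcript_id)
        if s is None:
            continue
        d = s - read.five_prime
        if 0 <= d <= window and d < read.read_length:
            dists[read.read_length][d] += 1

    offsets: dict[int, int] = {}
    support: dict[int, int] = {}
    for length, counter in dists.items():
        n = sum(counter.values())
        if n < min_support:
            continue
        best = max(counter.values())
        offsets[length] = min(d for d, c in counter.items() if c == best)
        support[length] = n
    return PsiteOffsets(offsets=offsets, support=support)


def build_track(
    reads: Iterable[AlignedRead],
    offsets: PsiteOffsets,
    models: Mapping[str, TranscriptModel],
) -> dict[str, SignalTrack]:
    """Accumulate P-site counts into one track per transcript.

    Each read of a length with an offset entry adds 1 at
    ``five_prime + offset(L)``. Reads of unlisted lengths, on unknown
    transcripts, or whose P-site falls past the 3' end are dropped and
    counted in the log.
    """
    if not offsets.offsets:
        raise ValueError("offset table is empty")
    arrays = {
        tid: np.zeros(model.length, dtype=float) for tid, model in models.items()
    }
    skipped_length = skipped_bounds = skipped_tid = 0
    for read in reads:
        off = offsets.offsets.get(read.read_length)
        if off is None:
            skipped_length += 1
            continue
        arr = arrays.get(read.transcript_id)
        if arr is None:
            skipped_tid += 1
            continue
        p = read.five_prime + off
        if p >= arr.shape[0]:
            skipped_bounds += 1
            continue
        arr[p] += 1
    if skipped_length or skipped_bounds or skipped_tid:
        log.info(
            "build_track skipped %d reads of unlisted lengths, %d past the "
            "3' end, %d on unknown transcripts",
            skipped_length,
            skipped_bounds,
            skipped_tid,
        )
    return {
        tid: SignalTrack(tid, arr, source="psite") for tid, arr in arrays.items()
    }


# -- alignment input -------------------------------------------------------


def read_alignments_tsv(path: str | Path) -> list[AlignedRead]:
    """Read the 3-column transcript-space format (transcript_id, five_prime, read_length)."""
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["transcript_id", "five_prime", "read_length"]:
            raise ValueError(
                "expected header transcript_id/five_prime/read_length, "
                f"got {header!r}"
            )
        for line in fh:
            tid, fp, rl = line.rstrip("\n").split("\t")[:3]
            reads.append(AlignedRead(tid, int(fp), int(rl)))
    return reads


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tfive_prime\tread_length\n")
        for r in reads:
            fh.write(f"{r.transcript_id}\t{r.five_prime}\t{r.read_length}\n")


def read_alignments_sam(
    path: str | Path, models: Mapping[str, TranscriptModel]
) -> list[AlignedRead]:
    """Convert genomic SAM/BAM alignments to transcript-space reads.

    The read's 5' end in transcript orientation is its leftmost aligned
    base on + strand transcripts and rightmost on - strand. Reads that are
    not fully exonic in a model, or that overlap no model, are dropped
    with a logged count. A read overlapping several isoforms contributes
    one AlignedRead per compatible isoform.
    """
    by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for model in models.values():
        by_chrom[model.chrom].append(model)
    reads: list[AlignedRead] = []
    dropped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            ref_positions = aln.get_reference_positions()
            if not ref_positions:
                continue
            hit = False
            for model in by_chrom.get(aln.reference_name, []):
                tpos = [model.genome_to_transcript(p) for p in ref_positions]
                if any(t is None for t in tpos):
                    continue  # spliced read crossing an intron of this isoform
                five_prime = min(tpos)  # type: ignore[type-var]
                reads.append(
                    AlignedRead(
                        model.transcript_id,
                        five_prime,
                        aln.infer_read_length() or len(ref_positions),
                    )
                )
                hit = True
            if not hit:
                dropped += 1
    if dropped:
        log.info("read_alignments_sam dropped %d non-exonic alignments", dropped)
    return reads


def write_offsets_tsv(offsets: PsiteOffsets, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_length\toffset\tsupport\n")
        for length in sorted(offsets.offsets):
            fh.write(
                f"{length}\t{offsets.offsets[length]}\t"
                f"{offsets.support.get(length, 0)}\n"
            )


def read_offsets_tsv(path: str | Path) -> PsiteOffsets:
    offsets: dict[int, int] = {}
    support: dict[int, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            length, off, sup = line.split("\t")
            offsets[int(length)] = int(off)
            support[int(length)] = int(sup)
    return PsiteOffsets(offsets=offsets, support=support)


def write_tracks_tsv(tracks: Mapping[str, SignalTrack], path: str | Path) -> None:
    """Sparse per-transcript track dump (zero positions omitted)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tcount\tsource\n")
        for tid in sorted(tracks):
            tr = tracks[tid]
            for pos in np.nonzero(tr.values)[0]:
                fh.write(f"{tid}\t{pos}\t{tr.values[pos]:g}\t{tr.source}\n")


def read_tracks_tsv(
    path: str | Path, models: Mapping[str, TranscriptModel]
) -> dict[str, SignalTrack]:
    arrays = {
        tid: np.zeros(model.length, dtype=float) for tid, model in models.items()
    }
    sources: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            tid, pos, count, source = line.rstrip("\n").split("\t")
            arrays[tid][int(pos)] = float(count)
            sources[tid] = source
    return {
        tid: SignalTrack(tid, arr, source=sources.get(tid, "psite"))
        for tid, arr in arrays.items()
    }


def tracks_to_bedgraph(
    tracks: Mapping[str, SignalTrack],
    models: Mapping[str, TranscriptModel],
    path: str | Path,
) -> None:
    """Project transcript tracks to genome coordinates as bedGraph."""
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            tr, model = tracks[tid], models[tid]
            for pos in np.nonzero(tr.values)[0]:
                g = model.transcript_to_genome(int(pos))
                fh.write(f"{model.chrom}\t{g}\t{g + 1}\t{tr.values[pos]:g}\n")
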