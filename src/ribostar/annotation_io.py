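"""Genome/annotation I/O and genome<->transcript coordinate arithmetic.

All internal coordinates are 0-based half-open. GTF input (1-based
inclusive) is converted on read; BED input is used natively. Transcript
coordinates always run 5'->3' regardless of genomic strand, so downstream
ORF and P-site logic never needs to look at the strand again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pyfaidx

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass
class GenomeSequence:
    """One chromosome: an identifier and a DNA string over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"chromosome {self.name!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Slice [start, end); out-of-bounds lookups are errors."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise IndexError(
                f"[{start}, {end}) outside chromosome {self.name!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (possibly line-wrapped) FASTA into chromosome records.

    Uses pyfaidx, so an existing ``.fai`` sidecar is honored and one is
    created otherwise.
    """
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: GenomeSequence(name, str(fa[name][:])) for name in fa.keys()}


@dataclass
class TranscriptModel:
    """Exon structure, strand and optional annotated CDS of one isoform.

    ``exons`` are genomic 0-based half-open intervals sorted by start and
    pairwise non-overlapping.  ``cds`` is the genomic span from the first
    to one past the last annotated CDS base (stop codon included for the
    gencode dialect); its spliced length must be a positive multiple of 3.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    biotype: str = ""
    _cum: list[int] = field(init=False, repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {s1, e1} and {s2, e2}"
                )
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
        self.exons = exons
        cum = [0]
        for s, e in exons:
            cum.append(cum[-1] + (e - s))
        self._cum = cum
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")
            clen = self.cds_spliced_length()
            if clen == 0 or clen % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS spliced length {clen} not a "
                    "positive multiple of 3"
                )

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        return self._cum[-1]

    def cds_spliced_length(self) -> int:
        if self.cds is None:
            return 0
        cs, ce = self.cds
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)

    # -- coordinate mapping ------------------------------------------------

    def genome_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to a 5'-anchored transcript offset.

        Returns None for intronic or out-of-range positions (an absent
        result is a value, not an error).
        """
        off = None
        for (s, e), base in zip(self.exons, self._cum):
            if s <= gpos < e:
                off = base + (gpos - s)
                break
        if off is None:
            return None
        return off if self.strand == "+" else self.length - 1 - off

    def transcript_to_genome(self, tpos: int) -> int:
        """Inverse of :meth:`genome_to_transcript` on exonic positions."""
        if not 0 <= tpos < self.length:
            raise IndexError(
                f"transcript position {tpos} outside [0, {self.length})"
            )
        off = tpos if self.strand == "+" else self.length - 1 - tpos
        for (s, e), base in zip(self.exons, self._cum):
            if base <= off < base + (e - s):
                return s + (off - base)
        raise AssertionError("unreachable: cumulative offsets cover the length")

    def cds_transcript_interval(self) -> tuple[int, int] | None:
        """Annotated ORF as a half-open interval in transcript coordinates."""
        if self.cds is None:
            return None
        cs, ce = self.cds
        a = self.genome_to_transcript(cs)
        b = self.genome_to_transcript(ce - 1)
        if a is None or b is None:
            raise ValueError(f"{self.transcript_id}: CDS edge falls in an intron")
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1


@dataclass
class TranscriptSequence:
    """Spliced transcript sequence, 5'->3', RNA alphabet."""

    transcript_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def extract_sequence(
    model: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
    alphabet: str = "rna",
) -> TranscriptSequence:
    """Concatenate exon sequence; reverse-complement minus-strand models.

    ``alphabet='rna'`` transcribes T->U; ``'dna'`` keeps the DNA alphabet
    (applied uniformly — every consumer sees the same convention).
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} missing from genome")
    chrom = genome[model.chrom]
    seq = "".join(chrom.fetch(s, e) for s, e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    if alphabet == "rna":
        seq = seq.replace("T", "U").replace("t", "u")
    elif alphabet != "dna":
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return TranscriptSequence(model.transcript_id, seq.upper())


# -- GTF -------------------------------------------------------------------

_EXONIC = {"exon", "CDS", "stop_codon"}


def parse_gtf(
    path: str | Path, dialect: str = "gencode"
) -> dict[str, TranscriptModel]:
    """Read a GTF into transcript models keyed by transcript_id.

    The ``gencode`` dialect appends the stop_codon feature to the CDS span
    (Gencode CDS records exclude the stop); ``generic`` uses CDS lines
    as-is.  Transcripts whose merged CDS spliced length is not a positive
    multiple of 3 keep their exon structure but have the CDS dropped with
    a logged warning.  Malformed lines raise :class:`GtfParseError` naming
    the line number.
    """
    if dialect not in ("gencode", "generic"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            if feat.featuretype not in _EXONIC:
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"line {lineno}: missing transcript_id attribute"
                ) from exc
            if tid not in meta:
                meta[tid] = {
                    "gene_id": _attr(feat, "gene_id", tid),
                    "gene_name": _attr(feat, "gene_name", _attr(feat, "gene_id", tid)),
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": _attr(
                        feat, "transcript_type", _attr(feat, "gene_type", "")
                    ),
                }
            iv = (feat.start - 1, feat.end)  # 1-based inclusive -> half-open
            if feat.featuretype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feat.featuretype == "CDS":
                cds.setdefault(tid, []).append(iv)
            else:
                stops.setdefault(tid, []).append(iv)

    models: dict[str, TranscriptModel] = {}
    for tid, m in meta.items():
        if tid not in exons:
            continue
        spans = list(cds.get(tid, []))
        if dialect == "gencode":
            spans += stops.get(tid, [])
        cds_span = None
        if spans:
            cds_span = (min(s for s, _ in spans), max(e for _, e in spans))
        try:
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=sorted(set(exons[tid])),
                cds=cds_span,
                biotype=m["biotype"],
            )
        except ValueError as exc:
            if cds_span is None:
                raise
            log.warning("dropping CDS of %s: %s", tid, exc)
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=sorted(set(exons[tid])),
                cds=None,
                biotype=m["biotype"],
            )
    return models


def _attr(feat, key: str, default: str) -> str:
    vals = feat.attributes.get(key)
    return vals[0] if vals else default


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models back to Gencode-dialect GTF (stop codon split off the CDS).

    Round-trips with :func:`parse_gtf`: parse -> write -> parse is the
    identity on the model set.
    """
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id)):
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}";'
            )
            if m.biotype:
                attrs += f' transcript_type "{m.biotype}";'
            rows: list[tuple[str, int, int]] = [("exon", s, e) for s, e in m.exons]
            if m.cds is not None:
                rows += [
                    ("CDS", s, e) for s, e in _split_cds(m, include_stop=False)
                ]
                rows += [("stop_codon", s, e) for s, e in _stop_codon_intervals(m)]
            for feature, s, e in rows:
                fh.write(
                    f"{m.chrom}\tribostar\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def _cds_exon_chunks(m: TranscriptModel) -> list[tuple[int, int]]:
    cs, ce = m.cds  # type: ignore[misc]
    out = []
    for s, e in m.exons:
        lo, hi = max(s, cs), min(e, ce)
        if lo < hi:
            out.append((lo, hi))
    return out


def _stop_codon_intervals(m: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals of the last 3 spliced CDS bases (the stop codon)."""
    lo, hi = m.cds_transcript_interval()  # type: ignore[misc]
    gpos = sorted(m.transcript_to_genome(t) for t in range(hi - 3, hi))
    out: list[tuple[int, int]] = []
    for p in gpos:
        if out and out[-1][1] == p:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def _split_cds(m: TranscriptModel, include_stop: bool) -> list[tuple[int, int]]:
    chunks = _cds_exon_chunks(m)
    if include_stop:
        return chunks
    stop = _stop_codon_intervals(m)
    out: list[tuple[int, int]] = []
    for s, e in chunks:
        for ss, se in stop:
            lo, hi = max(s, ss), min(e, se)
            if lo < hi:
                if s < lo:
                    out.append((s, lo))
                s = hi
        if s < e:
            out.append((s, e))
    return out


def write_models_tsv(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Flat TSV summary of transcript models (one row per transcript)."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tgene_name\tchrom\tstrand\tn_exons\t"
            "length\tcds_start\tcds_end\tbiotype\n"
        )
        for m in models:
            cs, ce = m.cds if m.cds is not None else ("NA", "NA")
            fh.write(
                f"{m.transcript_id}\t{m.gene_id}\t{m.gene_name}\t{m.chrom}\t"
                f"{m.strand}\t{len(m.exons)}\t{m.length}\t{cs}\t{ce}\t{m.biotype}\n"
            )
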