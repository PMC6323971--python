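"""Deterministic synthetic-data generator with recorded ground truth.

Produces a mini-genome, Gencode-style GTF, transcript-space Ribo-seq
alignments (optionally genomic SAM), RNA counts, CLIP binding sites,
crosstalk feature tracks and FASTQ reads — all from one integer seed and
all written as ordinary standard-format text files, so every module's
I/O path is exercised by the tests that consume them.

Ground truth is computed by deliberately naive reference routines kept in
this module (quadratic all-pairs ORF enumeration, a standalone interval
categorizer, per-base hotspot unions) that share no code with the
production scanners they exist to check.

One hand-designed coding transcript plants every ORF category relative
to its annotated ORF — an upstream ORF in the 5'UTR, an in-frame start
upstream of the CDS (extended), an in-frame internal start (truncated),
an off-frame start/stop pair inside the CDS (internal), and a downstream
ORF in the 3'UTR — and a designed non-coding transcript supplies the
unannotated class. Remaining transcripts are random.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import (
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    write_gtf,
)
from .fastq_filter import ReadRecord
from .psite import AlignedRead
from .rbp_sites import BindingSite, Feature, GeneSpan

_STOPS_DNA = ("TAA", "TAG", "TGA")
_SAFE_CODONS = ("GCT", "GCC", "GAC", "GAA", "AAA", "CTT", "TCC", "GGA")


@dataclass
class FixtureSpec:
    """All knobs of the generator; same seed -> byte-identical outputs."""

    seed: int = 7
    n_transcripts: int = 12
    length_range: tuple[int, int] = (300, 1500)
    fraction_coding: float = 0.7
    psite_offsets: dict[int, int] = field(default_factory=lambda: {28: 12, 29: 13})
    noise_fraction: float = 0.05
    init_peak_fraction: float = 0.1
    n_reads: int = 10_000
    te_per_transcript: dict[str, float] = field(default_factory=dict)
    n_binding_sites: int = 200
    n_rbps: int = 12
    n_features_per_kind: int = 30
    n_fastq_reads: int = 10_000

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo < 6 and self.fraction_coding > 0:
            raise ValueError(
                "infeasible spec: coding transcripts need length >= 6 nt"
            )
        if lo > hi or lo < 1:
            raise ValueError(f"bad length range {self.length_range}")
        if not 0 <= self.fraction_coding <= 1:
            raise ValueError("fraction_coding must be in [0, 1]")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be in [0, 1]")
        for length, off in self.psite_offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} invalid for read length {length}")


# -- independent reference routines ---------------------------------------


def brute_force_orfs(sequence: str) -> list[tuple[int, int]]:
    """Quadratic all-(AUG, stop)-pairs enumeration keeping the nearest stop.

    Reference oracle: for every AUG, walk downstream codon by codon until
    the first in-frame stop; emit nothing when none exists. Accepts RNA or
    DNA alphabet.
    """
    seq = sequence.upper().replace("U", "T")
    out = []
    for a in range(len(seq) - 2):
        if seq[a : a + 3] != "ATG":
            continue
        j = a + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in _STOPS_DNA:
                out.append((a, j + 3))
                break
            j += 3
    return sorted(out)


def naive_categorize(
    start: int, end: int, aorf: tuple[int, int] | None
) -> str:
    """Standalone interval categorizer (no shared code with the scanner)."""
    if aorf is None:
        return "unannotated"
    a_start, a_end = aorf
    if start == a_start and end == a_end:
        return "annotated"
    if end == a_end:
        return "truncated" if start > a_start else "extended"
    if start < a_end and end > a_start:
        return "internal"
    if end <= a_start:
        return "uorf"
    return "dorf"


def reference_orf_table(
    models: Mapping[str, TranscriptModel],
    spliced: Mapping[str, str],
    sorf_threshold: int = 300,
) -> pd.DataFrame:
    """Ground-truth ORF table from the naive routines above."""
    rows = []
    for tid in models:
        model = models[tid]
        aorf = model.cds_transcript_interval()
        for start, end in brute_force_orfs(spliced[tid]):
            category = naive_categorize(start, end, aorf)
            rows.append(
                {
                    "orf_id": f"{tid}:{start}-{end}:{category}",
                    "transcript_id": tid,
                    "gene_id": model.gene_id,
                    "start": start,
                    "end": end,
                    "frame": start % 3,
                    "category": category,
                    "length_nt": end - start,
                    "is_sorf": (end - start) < sorf_threshold,
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
    return pd.DataFrame(rows, columns=columns)


# -- transcript sequence design -------------------------------------------


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _safe_body(rng: random.Random, n_codons: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons))


def designed_coding_sequence(rng: random.Random) -> tuple[str, tuple[int, int]]:
    """DNA sequence planting u/extended/annotated/truncated/internal/dORFs.

    Returns (sequence, aORF transcript interval, stop included).
    """
    utr5 = "GC" * 5 + "ATGAAATAA" + "GC" * 3  # uORF, no other starts
    ext = "ATG" + "GCC"  # in-frame start upstream of the CDS
    body = (
        _safe_body(rng, 12)
        + "ATGGCC"  # in-frame internal start -> truncated ORF
        + _safe_body(rng, 12)
        + "CATGCC"  # off-frame ATG (frame +1) -> internal ORF
        + _safe_body(rng, 12)
        + "TTAAGC"  # off-frame stop (frame +1) closing the internal ORF
        + _safe_body(rng, 12)
    )
    aorf_seq = "ATG" + body + "TAA"
    utr3 = "GC" * 3 + "ATGCCCTAA" + "GC" * 5  # dORF
    seq = utr5 + ext + aorf_seq + utr3
    a_start = len(utr5) + len(ext)
    return seq, (a_start, a_start + len(aorf_seq))


def designed_noncoding_sequence() -> str:
    """Short transcript with one ORF and no CDS annotation (unannotated)."""
    return "GC" * 4 + "ATGGACGAAAAATAA" + "GC" * 4


# -- transcriptome assembly ------------------------------------------------


@dataclass
class Transcriptome:
    genome: dict[str, GenomeSequence]
    models: dict[str, TranscriptModel]
    spliced: dict[str, str]  # DNA, transcript orientation
    truth_orfs: pd.DataFrame


def _pick_cds(seq: str, min_start: int = 18, min_len: int = 60) -> tuple[int, int] | None:
    """Longest naive ORF usable as an annotated CDS, or None.

    Margins at both transcript ends leave room for footprint 5' extents
    upstream of the start codon and read bodies past the stop.
    """
    best = None
    for start, end in brute_force_orfs(seq):
        if start < min_start or end - start < min_len or end > len(seq) - 20:
            continue
        if best is None or (end - start) > (best[1] - best[0]):
            best = (start, end)
    return best


def _split_exons(rng: random.Random, spliced_len: int) -> list[int]:
    """Random transcript-order exon lengths summing to the spliced length."""
    n_exons = rng.randint(1, 4) if spliced_len >= 40 else 1
    cuts = sorted(rng.sample(range(1, spliced_len), n_exons - 1)) if n_exons > 1 else []
    bounds = [0] + cuts + [spliced_len]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _layout_exons(
    rng: random.Random, chrom_cursor: int, gen_lengths: Sequence[int]
) -> list[tuple[int, int]]:
    """Genomic exon intervals (ascending) with random padding and introns.

    ``gen_lengths`` are exon lengths in ascending genomic order — the
    transcript order for + strand, reversed for - strand.
    """
    exons = []
    pos = chrom_cursor + rng.randint(30, 100)
    for length in gen_lengths:
        exons.append((pos, pos + length))
        pos += length + rng.randint(20, 200)
    return exons


def make_transcriptome(spec: FixtureSpec) -> Transcriptome:
    """Genome + transcript models + spliced sequences + true ORF table."""
    spec.validate()
    rng = random.Random(spec.seed)
    chrom_name = "chrS"
    segments: list[str] = []
    cursor = 0
    models: dict[str, TranscriptModel] = {}
    spliced: dict[str, str] = {}

    plan: list[tuple[str, bool]] = []  # (kind, wants_cds)
    for i in range(spec.n_transcripts):
        if i == 0:
            plan.append(("designed_coding", True))
        elif i == 1:
            plan.append(("designed_noncoding", False))
        else:
            plan.append(("random", rng.random() < spec.fraction_coding))

    for i, (kind, wants_cds) in enumerate(plan):
        tid = f"TX{i:03d}"
        if kind == "designed_coding":
            seq, cds_tx = designed_coding_sequence(rng)
            biotype = "protein_coding"
        elif kind == "designed_noncoding":
            seq, cds_tx = designed_noncoding_sequence(), None
            biotype = "lncRNA"
        else:
            seq = _random_dna(rng, rng.randint(*spec.length_range))
            cds_tx = _pick_cds(seq) if wants_cds else None
            biotype = "protein_coding" if cds_tx else "lncRNA"
        strand = rng.choice("+-")
        tx_lengths = _split_exons(rng, len(seq))
        gen_lengths = tx_lengths if strand == "+" else tx_lengths[::-1]
        exons = _layout_exons(rng, cursor, gen_lengths)
        new_cursor = exons[-1][1]

        # fill the chromosome: padding, then exon chunks with intron filler
        genomic = seq if strand == "+" else reverse_complement(seq)
        chunks, p = [], 0
        for length in gen_lengths:
            chunks.append(genomic[p : p + length])
            p += length
        segments.append(_random_dna(rng, exons[0][0] - cursor))
        for j, ((s, e), chunk) in enumerate(zip(exons, chunks)):
            segments.append(chunk)
            if j + 1 < len(exons):
                segments.append(_random_dna(rng, exons[j + 1][0] - e))
        cursor = new_cursor

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i:03d}",
            gene_name=f"GENE{i:03d}",
            chrom=chrom_name,
            strand=strand,
            exons=exons,
            cds=None,
            biotype=biotype,
        )
        if cds_tx is not None:
            gpos = [model.transcript_to_genome(t) for t in range(cds_tx[0], cds_tx[1])]
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=f"G{i:03d}",
                gene_name=f"GENE{i:03d}",
                chrom=chrom_name,
                strand=strand,
                exons=exons,
                cds=(min(gpos), max(gpos) + 1),
                biotype=biotype,
            )
        models[tid] = model
        spliced[tid] = seq

    segments.append(_random_dna(rng, 50))
    genome_seq = "".join(segments)
    genome = (
        {chrom_name: GenomeSequence(chrom_name, genome_seq)} if genome_seq else {}
    )
    truth = reference_orf_table(models, spliced)
    return Transcriptome(genome=genome, models=models, spliced=spliced, truth_orfs=truth)


# -- Ribo-seq simulation ---------------------------------------------------


@dataclass
class RiboseqTruth:
    reads: list[AlignedRead]
    true_offsets: dict[int, int]
    true_te: dict[str, float]  # per coding transcript
    rna_counts: dict[str, float]  # per transcript, expectation-level
    psites: dict[str, list[int]]  # realized P-site positions per transcript


def make_riboseq(spec: FixtureSpec, transcriptome: Transcriptome) -> RiboseqTruth:
    """Footprints whose P-sites tile each annotated ORF 3-nt periodically.

    Read depth per ORF is proportional to TE x RNA level x ORF length; an
    initiation-peak fraction of each ORF's reads sits exactly on the
    start codon (the metagene anchor real libraries provide), and a noise
    fraction is placed uniformly along the transcript.
    """
    spec.validate()
    rng = random.Random(spec.seed + 1)
    lengths = sorted(spec.psite_offsets)
    coding = [
        tid
        for tid in transcriptome.models
        if transcriptome.models[tid].cds is not None
    ]
    te: dict[str, float] = {}
    for rank, tid in enumerate(coding):
        te[tid] = spec.te_per_transcript.get(tid, 2.0 if rank == 0 else 1.0)

    rna_counts = {
        tid: float(transcriptome.models[tid].length)
        for tid in transcriptome.models
    }

    weights = []
    for tid in coding:
        a = transcriptome.models[tid].cds_transcript_interval()
        weights.append(te[tid] * (a[1] - a[0]))
    total_w = sum(weights)

    reads: list[AlignedRead] = []
    psites: dict[str, list[int]] = {tid: [] for tid in transcriptome.models}
    if not coding or total_w == 0 or not lengths:
        return RiboseqTruth(reads, dict(spec.psite_offsets), te, rna_counts, psites)

    all_tids = list(transcriptome.models)
    for _ in range(spec.n_reads):
        read_length = rng.choice(lengths)
        if rng.random() < spec.noise_fraction:
            tid = rng.choice(all_tids)
            model = transcriptome.models[tid]
            if model.length <= read_length:
                continue
            fp = rng.randrange(0, model.length - read_length)
            reads.append(AlignedRead(tid, fp, read_length))
            p = fp + spec.psite_offsets[read_length]
            if p < model.length:
                psites[tid].append(p)
            continue
        tid = rng.choices(coding, weights=weights, k=1)[0]
        model = transcriptome.models[tid]
        a_start, a_end = model.cds_transcript_interval()
        if rng.random() < spec.init_peak_fraction:
            psite = a_start
        else:
            psite = a_start + 3 * rng.randrange(0, (a_end - a_start) // 3)
        fp = psite - spec.psite_offsets[read_length]
        if fp < 0 or fp + read_length > model.length:
            continue
        reads.append(AlignedRead(tid, fp, read_length))
        psites[tid].append(psite)
    return RiboseqTruth(reads, dict(spec.psite_offsets), te, rna_counts, psites)


# -- CLIP simulation -------------------------------------------------------


@dataclass
class ClipTruth:
    gene: GeneSpan
    sites: list[BindingSite]
    true_bin_counts: list[int]  # per-base brute-force distinct-RBP unions
    features: list[Feature]


def _per_base_bin_truth(
    sites: Sequence[BindingSite], gene: GeneSpan, bin_width: int = 20
) -> list[int]:
    """Per-base reference: mark every covered base with its RBPs, then take
    the union over each bin's bases."""
    length = gene.end - gene.start
    per_base: list[set[str]] = [set() for _ in range(length)]
    for site in sites:
        if site.chrom != gene.chrom:
            continue
        if site.strand != "." and site.strand != gene.strand:
            continue
        for g in range(max(site.start, gene.start), min(site.end, gene.end)):
            off = (g - gene.start) if gene.strand != "-" else (gene.end - 1 - g)
            per_base[off].add(site.rbp)
    counts = []
    for b in range(0, length, bin_width):
        union: set[str] = set()
        for cell in per_base[b : b + bin_width]:
            union |= cell
        counts.append(len(union))
    return counts


def make_clip(spec: FixtureSpec, transcriptome: Transcriptome) -> ClipTruth:
    """Binding sites over the first gene's precursor plus feature tracks."""
    spec.validate()
    rng = random.Random(spec.seed + 2)
    if transcriptome.models:
        first = next(iter(transcriptome.models.values()))
        gene = GeneSpan(
            gene_id=first.gene_id,
            chrom=first.chrom,
            start=first.exons[0][0],
            end=first.exons[-1][1],
            strand=first.strand,
        )
    else:
        gene = GeneSpan("G000", "chrS", 0, 400, "+")
    rbps = [f"RBP{i:02d}" for i in range(spec.n_rbps)]
    methods = ["Piranha", "PARalyzer", "CIMS"]
    samples = ["HeLa", "HEK293", "K562"]
    sites = []
    span = gene.end - gene.start
    for _ in range(spec.n_binding_sites):
        width = rng.randint(10, 40)
        start = gene.start + rng.randint(-50, span + 10)
        start = max(0, start)
        strand = gene.strand if rng.random() < 0.8 else "."
        sites.append(
            BindingSite(
                chrom=gene.chrom,
                start=start,
                end=start + width,
                strand=strand,
                rbp=rng.choice(rbps),
                method=rng.choice(methods),
                sample=rng.choice(samples),
            )
        )
    features = []
    for kind in ("miRNA_target", "modification", "editing", "SNV", "GWAS", "somatic"):
        point = kind in ("SNV", "GWAS", "somatic")
        for j in range(spec.n_features_per_kind):
            start = gene.start + rng.randint(-30, span)
            start = max(0, start)
            width = 1 if point else rng.randint(5, 25)
            features.append(
                Feature(
                    chrom=gene.chrom,
                    start=start,
                    end=start + width,
                    name=f"{kind}_{j}",
                    kind=kind,
                )
            )
    return ClipTruth(
        gene=gene,
        sites=sites,
        true_bin_counts=_per_base_bin_truth(sites, gene),
        features=features,
    )


# -- FASTQ simulation ------------------------------------------------------


@dataclass
class FastqTruth:
    reads: list[ReadRecord]
    duplication_spectrum: dict[str, int]  # unique sequence -> multiplicity


def make_fastq(spec: FixtureSpec) -> FastqTruth:
    """Adaptor-trimmed reads with a known duplication spectrum and a mix of
    qualities and lengths spanning both filter boundaries."""
    spec.validate()
    rng = random.Random(spec.seed + 3)
    uniques: list[str] = []
    spectrum: dict[str, int] = {}
    budget = spec.n_fastq_reads
    while budget > 0:
        length = rng.randint(10, 40)
        seq = _random_dna(rng, length)
        if seq in spectrum:
            continue
        mult = min(budget, 1 + int(rng.expovariate(0.7)))
        spectrum[seq] = mult
        uniques.append(seq)
        budget -= mult
    copies: list[str] = []
    for seq in uniques:
        copies.extend([seq] * spectrum[seq])
    rng.shuffle(copies)
    reads = []
    for i, seq in enumerate(copies):
        good = rng.random() < 0.8
        quals = tuple(
            rng.randint(25, 40) if (good or rng.random() < 0.5) else rng.randint(2, 20)
            for _ in seq
        )
        reads.append(ReadRecord(f"read{i:05d}", seq, quals))
    return FastqTruth(reads=reads, duplication_spectrum=spectrum)


def write_reads_sam(
    reads: Sequence[AlignedRead],
    models: Mapping[str, TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    path: str | Path,
) -> None:
    """Project transcript-space reads to a genomic SAM file.

    Spliced reads get M/N CIGARs; minus-strand transcripts produce
    reverse-strand alignments. Used to exercise the genomic-alignment
    ingestion path on data with known transcript-space truth.
    """
    import pysam

    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(reads):
            model = models[read.transcript_id]
            tpos = range(read.five_prime, read.five_prime + read.read_length)
            gpos = sorted(model.transcript_to_genome(t) for t in tpos)
            blocks: list[tuple[int, int]] = []
            for p in gpos:
                if blocks and blocks[-1][1] == p:
                    blocks[-1] = (blocks[-1][0], p + 1)
                else:
                    blocks.append((p, p + 1))
            cigar = []
            for j, (s, e) in enumerate(blocks):
                if j:
                    cigar.append((3, s - blocks[j - 1][1]))  # N
                cigar.append((0, e - s))  # M
            a = pysam.AlignedSegment()
            a.query_name = f"r{i:06d}"
            a.reference_id = chroms.index(model.chrom)
            a.reference_start = blocks[0][0]
            a.mapping_quality = 255
            a.cigartuples = cigar
            a.flag = 16 if model.strand == "-" else 0
            seq = "".join(genome[model.chrom].fetch(s, e) for s, e in blocks)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


# -- file emission ---------------------------------------------------------


def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the standard-format files.

    Returns a map of artifact name -> path. Consumers are expected to go
    through the package's public readers.
    """
    from .fastq_filter import write_fastq
    from .psite import write_alignments_tsv
    from .rbp_sites import write_features_bed, write_sites_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tr = make_transcriptome(spec)
    ribo = make_riboseq(spec, tr)
    clip = make_clip(spec, tr)
    fastq = make_fastq(spec)

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "truth_orfs": outdir / "truth_orfs.tsv",
        "ribo_reads": outdir / "ribo_reads.tsv",
        "rna_counts": outdir / "rna_counts.tsv",
        "sites": outdir / "clip_sites.bed",
        "features": outdir / "crosstalk_features.bed",
        "fastq": outdir / "reads.fastq",
    }
    with open(paths["genome"], "w") as fh:
        for name in sorted(tr.genome):
            fh.write(f">{name}\n")
            seq = tr.genome[name].sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_gtf(tr.models.values(), paths["gtf"])
    tr.truth_orfs.to_csv(paths["truth_orfs"], sep="\t", index=False)
    write_alignments_tsv(ribo.reads, paths["ribo_reads"])
    with open(paths["rna_counts"], "w") as fh:
        fh.write("transcript_id\tcount\n")
        for tid in sorted(ribo.rna_counts):
            fh.write(f"{tid}\t{ribo.rna_counts[tid]:g}\n")
    write_sites_bed(clip.sites, paths["sites"])
    write_features_bed(clip.features, paths["features"])
    write_fastq(fastq.reads, paths["fastq"])
    return paths
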