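"""RBP-binding-site profiles: 20-nt hotspot bins, element assignment, and
intersection with crosstalk/variation tracks.

A hotspot profile counts, for every 20-nt bin along a gene's precursor
(the unspliced primary transcript, introns included, binned 5'->3' in
transcription orientation), the number of *distinct* RBPs with a binding
site overlapping the bin by at least one nucleotide — proteins, not
peaks, so duplicated site records never change a count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import TranscriptModel

log = logging.getLogger(__name__)

BIN_WIDTH = 20

DEFAULT_ELEMENT_PRIORITY = (
    "CDS",
    "3'UTR",
    "5'UTR",
    "lncRNA_exon",
    "other_exon",
    "intron",
    "intergenic",
)

FEATURE_KINDS = ("miRNA_target", "modification", "editing", "SNV", "GWAS", "somatic")


@dataclass(frozen=True)
class BindingSite:
    """One strand-aware genomic CLIP peak labeled with RBP, method, sample."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (matches both)
    rbp: str
    method: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class GeneSpan:
    """Precursor interval of a gene in transcription orientation."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class HotspotProfile:
    """Distinct-RBP counts per 20-nt bin along a gene's precursor.

    Bin k covers precursor offsets [20k, 20k+20) counted from the gene's
    5' end; the final partial bin is retained.
    """

    gene_id: str
    precursor: GeneSpan
    bins: list[tuple[int, int]]  # (bin_index, distinct_rbp_count)
    bin_width: int = BIN_WIDTH

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.bins]


def n_bins(span_length: int, bin_width: int = BIN_WIDTH) -> int:
    return (span_length + bin_width - 1) // bin_width


def compute_hotspots(
    sites: Iterable[BindingSite],
    gene: GeneSpan,
    bin_width: int = BIN_WIDTH,
    key_by_sample: bool = False,
) -> HotspotProfile:
    """Per-bin distinct-RBP counts over the gene's precursor.

    Sites on other chromosomes are skipped with a logged count; strand '.'
    matches both gene strands. By default distinctness keys on the RBP
    name alone (methods and samples pooled); ``key_by_sample`` switches to
    (rbp, sample) keys.
    """
    length = gene.end - gene.start
    nb = n_bins(length, bin_width)
    per_bin: list[set] = [set() for _ in range(nb)]
    skipped = 0
    for site in sites:
        if site.chrom != gene.chrom:
            skipped += 1
            continue
        if site.strand != "." and gene.strand != "." and site.strand != gene.strand:
            continue
        lo = max(site.start, gene.start)
        hi = min(site.end, gene.end)
        if lo >= hi:
            continue
        # genomic overlap -> precursor offsets in 5'->3' gene orientation
        if gene.strand == "-":
            off_lo = gene.end - hi
            off_hi = gene.end - lo
        else:
            off_lo = lo - gene.start
            off_hi = hi - gene.start
        key = (site.rbp, site.sample) if key_by_sample else site.rbp
        for b in range(off_lo // bin_width, (off_hi - 1) // bin_width + 1):
            per_bin[b].add(key)
    if skipped:
        log.info("compute_hotspots skipped %d sites on other chromosomes", skipped)
    return HotspotProfile(
        gene_id=gene.gene_id,
        precursor=gene,
        bins=[(i, len(s)) for i, s in enumerate(per_bin)],
        bin_width=bin_width,
    )


# -- genomic element assignment --------------------------------------------


def build_element_index(
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
) -> dict[str, IntervalTree]:
    """Index genomic element intervals (per chromosome) from transcript models.

    Coding transcripts contribute CDS, 5'UTR, 3'UTR (exonic, split by the
    CDS span in transcript orientation) and introns; non-coding
    transcripts contribute lncRNA_exon (biotype containing 'lncRNA') or
    other_exon, plus introns.
    """
    if isinstance(models, Mapping):
        models = list(models.values())
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for m in models:
        for (s1, e1), (s2, _) in zip(m.exons, m.exons[1:]):
            trees[m.chrom].addi(e1, s2, "intron")
        if m.cds is None:
            label = "lncRNA_exon" if "lncRNA" in m.biotype else "other_exon"
            for s, e in m.exons:
                trees[m.chrom].addi(s, e, label)
            continue
        cs, ce = m.cds
        # genomic left of the CDS is the 5'UTR on +, the 3'UTR on -
        left, right = ("5'UTR", "3'UTR") if m.strand == "+" else ("3'UTR", "5'UTR")
        for s, e in m.exons:
            if s < cs:
                trees[m.chrom].addi(s, min(e, cs), left)
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                trees[m.chrom].addi(lo, hi, "CDS")
            if e > ce:
                trees[m.chrom].addi(max(s, ce), e, right)
    return dict(trees)


def assign_elements(
    site: BindingSite,
    element_index: dict[str, IntervalTree],
    priority: Sequence[str] = DEFAULT_ELEMENT_PRIORITY,
) -> str:
    """Label a site with the highest-priority genomic element it overlaps."""
    tree = element_index.get(site.chrom)
    hits = {iv.data for iv in tree.overlap(site.start, site.end)} if tree else set()
    for element in priority:
        if element in hits:
            return element
    return "intergenic"


# -- track intersection ----------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One crosstalk/variation record (miRNA target, modification, editing,
    SNV, GWAS or somatic variant). Point features are 1-nt intervals."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str
    strand: str = "."


def intersect_tracks(
    sites: Sequence[BindingSite], features: Sequence[Feature]
) -> pd.DataFrame:
    """All (site, feature) pairs overlapping by >= 1 nt (half-open; a
    feature abutting a site end produces no pair)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, f in enumerate(features):
        end = f.end if f.end > f.start else f.start + 1  # point feature
        trees[f.chrom].addi(f.start, end, idx)
    rows = []
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(site.start, site.end)):
            f = features[iv.data]
            rows.append(
                {
                    "chrom": site.chrom,
                    "site_start": site.start,
                    "site_end": site.end,
                    "rbp": site.rbp,
                    "method": site.method,
                    "sample": site.sample,
                    "feature_start": f.start,
                    "feature_end": f.end,
                    "feature_name": f.name,
                    "feature_kind": f.kind,
                }
            )
    columns = [
        "chrom",
        "site_start",
        "site_end",
        "rbp",
        "method",
        "sample",
        "feature_start",
        "feature_end",
        "feature_name",
        "feature_kind",
    ]
    return pd.DataFrame(rows, columns=columns)


# -- BED I/O ---------------------------------------------------------------


def read_sites_bed(path: str | Path) -> list[BindingSite]:
    """BED6 + 3 extra columns (rbp, method, sample); rbp falls back to the
    BED name field when the extra columns are absent."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: expected >= 6 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            sites.append(
                BindingSite(
                    chrom=cols[0],
                    start=start,
                    end=end,
                    strand=cols[5],
                    rbp=cols[6] if len(cols) > 6 else cols[3],
                    method=cols[7] if len(cols) > 7 else "",
                    sample=cols[8] if len(cols) > 8 else "",
                )
            )
    return sites


def write_sites_bed(sites: Iterable[BindingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.rbp}\t0\t{s.strand}\t"
                f"{s.rbp}\t{s.method}\t{s.sample}\n"
            )


def read_features_bed(path: str | Path, kind: str | None = None) -> list[Feature]:
    """BED records with a kind label: column 7 if present, else ``kind``."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            k = cols[6] if len(cols) > 6 else kind
            if k is None:
                raise ValueError(f"line {lineno}: no kind column and no default kind")
            features.append(
                Feature(
                    chrom=cols[0],
                    start=start,
                    end=end,
                    name=cols[3] if len(cols) > 3 else f"feature{lineno}",
                    kind=k,
                    strand=cols[5] if len(cols) > 5 else ".",
                )
            )
    return features


def write_features_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\t{f.kind}\n"
            )


def write_hotspots_tsv(profile: HotspotProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbin_index\tbin_start_offset\tdistinct_rbps\n")
        for idx, count in profile.bins:
            fh.write(
                f"{profile.gene_id}\t{idx}\t{idx * profile.bin_width}\t{count}\n"
            )


def hotspots_to_bedgraph(profile: HotspotProfile, path: str | Path) -> None:
    """Genomic bedGraph of per-bin counts over the precursor."""
    g = profile.precursor
    with open(path, "w") as fh:
        for idx, count in profile.bins:
            off_lo = idx * profile.bin_width
            off_hi = min(off_lo + profile.bin_width, g.end - g.start)
            if g.strand == "-":
                lo, hi = g.end - off_hi, g.end - off_lo
            else:
                lo, hi = g.start + off_lo, g.start + off_hi
            fh.write(f"{g.chrom}\t{lo}\t{hi}\t{count}\n")
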