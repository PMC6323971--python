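"""RPKM, translation efficiency (TE) and translation density per ORF.

TE is the ratio of Ribo-seq RPKM to RNA-seq RPKM for an ORF under one
condition; translation density is the per-nucleotide P-site signal over
the ORF. Both are computed identically from raw or externally denoised
tracks, with the source recorded per record. An ORF's Ribo-seq count is
the number of P-sites falling in [start, end); the RNA denominator is the
transcript-level count supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orf_finder import Orf
from .psite import SignalTrack


def rpkm(count: float, length_nt: int, library_size: int | float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_nt <= 0:
        raise ValueError(f"length_nt must be positive, got {length_nt}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return count / ((length_nt / 1000.0) * (library_size / 1e6))


def translation_efficiency(ribo_rpkm: float, rna_rpkm: float) -> float:
    """Ribo RPKM / RNA RPKM; NaN (reported NA) when the RNA RPKM is zero."""
    if ribo_rpkm < 0 or rna_rpkm < 0:
        raise ValueError("RPKM inputs must be non-negative")
    if rna_rpkm == 0:
        return math.nan
    return ribo_rpkm / rna_rpkm


def translation_density(track: SignalTrack, orf: Orf | "OrfSpan") -> float:
    """Signal summed over the ORF divided by ORF length (counts per nt)."""
    if orf.start < 0 or orf.end > track.values.shape[0]:
        raise ValueError(
            f"ORF [{orf.start}, {orf.end}) outside track of length "
            f"{track.values.shape[0]}"
        )
    return float(track.values[orf.start : orf.end].sum()) / (orf.end - orf.start)


@dataclass(frozen=True)
class OrfSpan:
    """Minimal ORF view used by quantification (a row of the ORF table)."""

    orf_id: str
    transcript_id: str
    start: int
    end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class QuantRecord:
    orf_id: str
    condition: str
    ribo_count: float
    rna_count: float
    ribo_rpkm: float
    rna_rpkm: float
    te: float  # NaN = undefined (RNA RPKM zero)
    density: float
    signal_source: str


def quantify(
    orfs: pd.DataFrame | Iterable[OrfSpan],
    ribo_tracks: Mapping[str, Mapping[str, Mapping[str, SignalTrack]]],
    rna_counts: Mapping[str, Mapping[str, float]],
    transcript_lengths: Mapping[str, int],
    conditions: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """One QuantRecord per ORF x condition x signal source.

    ``ribo_tracks[condition][source][transcript_id]`` holds the Ribo-seq
    signal (source in {raw, denoised}; both are quantified when both are
    supplied). ``rna_counts[condition][transcript_id]`` holds RNA-seq
    counts. Library sizes are the totals of the respective track set /
    count table, not raw sequencing depth. ``pseudocount`` (off by
    default) is added to both counts before RPKM.
    """
    if conditions is None:
        conditions = sorted(ribo_tracks)
    if len(set(conditions)) != len(conditions):
        dupes = sorted({c for c in conditions if list(conditions).count(c) > 1})
        raise ValueError(f"duplicated condition labels: {dupes}")
    missing = [c for c in conditions if c not in ribo_tracks or c not in rna_counts]
    if missing:
        raise ValueError(
            "conditions without matching ribo tracks and rna counts: "
            + ", ".join(missing)
        )

    spans = _as_spans(orfs)
    rows = []
    for condition in conditions:
        rna = rna_counts[condition]
        rna_lib = sum(rna.values())
        for source, tracks in sorted(ribo_tracks[condition].items()):
            ribo_lib = sum(t.total for t in tracks.values())
            for span in spans:
                track = tracks.get(span.transcript_id)
                ribo_count = (
                    float(track.values[span.start : span.end].sum())
                    if track is not None
                    else 0.0
                )
                rna_count = float(rna.get(span.transcript_id, 0.0))
                ribo_rpkm = (
                    rpkm(ribo_count + pseudocount, span.length_nt, ribo_lib)
                    if ribo_lib > 0
                    else 0.0
                )
                tx_len = transcript_lengths[span.transcript_id]
                rna_rpkm = (
                    rpkm(rna_count + pseudocount, tx_len, rna_lib)
                    if rna_lib > 0
                    else 0.0
                )
                rows.append(
                    QuantRecord(
                        orf_id=span.orf_id,
                        condition=condition,
                        ribo_count=ribo_count,
                        rna_count=rna_count,
                        ribo_rpkm=ribo_rpkm,
                        rna_rpkm=rna_rpkm,
                        te=translation_efficiency(ribo_rpkm, rna_rpkm),
                        density=ribo_count / span.length_nt,
                        signal_source=source,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])


def _as_spans(orfs: pd.DataFrame | Iterable[OrfSpan]) -> list[OrfSpan]:
    if isinstance(orfs, pd.DataFrame):
        return [
            OrfSpan(r.orf_id, r.transcript_id, int(r.start), int(r.end))
            for r in orfs.itertuples()
        ]
    return list(orfs)


def write_quant_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """TSV with the NA string for undefined TE."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
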