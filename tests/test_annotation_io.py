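"""GTF/FASTA parsing, spliced-sequence extraction and coordinate mapping."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribostar.annotation_io import (
    GenomeSequence,
    GtfParseError,
    TranscriptModel,
    extract_sequence,
    parse_gtf,
    read_fasta,
    reverse_complement,
    write_gtf,
)


def _gtf(tmp_path, lines):
    path = tmp_path / "test.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


ATTRS = 'gene_id "g1"; transcript_id "t1"; gene_name "G1";'


class TestParseGtf:
    def test_coordinate_conversion_single_exon_cds(self, tmp_path):
        # GTF 1-based inclusive exon 1..90, CDS 10..42 -> 0-based half-open
        path = _gtf(
            tmp_path,
            [
                f"chr1\tsrc\texon\t1\t90\t.\t+\t.\t{ATTRS}",
                f"chr1\tsrc\tCDS\t10\t42\t.\t+\t.\t{ATTRS}",
            ],
        )
        models = parse_gtf(path, dialect="generic")
        m = models["t1"]
        assert m.exons == [(0, 90)]
        assert m.cds == (9, 42)
        assert m.cds_spliced_length() == 33

    def test_gencode_dialect_appends_stop_codon(self, tmp_path):
        path = _gtf(
            tmp_path,
            [
                f"chr1\tsrc\texon\t1\t90\t.\t+\t.\t{ATTRS}",
                f"chr1\tsrc\tCDS\t10\t39\t.\t+\t.\t{ATTRS}",
                f"chr1\tsrc\tstop_codon\t40\t42\t.\t+\t.\t{ATTRS}",
            ],
        )
        assert parse_gtf(path, dialect="gencode")["t1"].cds == (9, 42)

    def test_transcript_without_cds_has_no_annotated_orf(self, tmp_path):
        path = _gtf(tmp_path, [f"chr1\tsrc\texon\t1\t90\t.\t+\t.\t{ATTRS}"])
        assert parse_gtf(path)["t1"].cds is None

    def test_minus_strand_exons_sorted_by_genomic_start(self, tmp_path):
        path = _gtf(
            tmp_path,
            [
                f"chr1\tsrc\texon\t31\t60\t.\t-\t.\t{ATTRS}",
                f"chr1\tsrc\texon\t1\t10\t.\t-\t.\t{ATTRS}",
            ],
        )
        m = parse_gtf(path)["t1"]
        assert m.exons == [(0, 10), (30, 60)]
        assert m.strand == "-"

    def test_malformed_attribute_column_names_line(self, tmp_path):
        path = _gtf(
            tmp_path,
            [
                f"chr1\tsrc\texon\t1\t90\t.\t+\t.\t{ATTRS}",
                "chr1\tsrc\texon\t1\t90\t.\t+\t.",  # missing column
            ],
        )
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gtf(path)

    def test_cds_not_multiple_of_three_dropped_with_warning(self, tmp_path, caplog):
        path = _gtf(
            tmp_path,
            [
                f"chr1\tsrc\texon\t1\t90\t.\t+\t.\t{ATTRS}",
                f"chr1\tsrc\tCDS\t10\t41\t.\t+\t.\t{ATTRS}",
            ],
        )
        with caplog.at_level("WARNING"):
            models = parse_gtf(path, dialect="generic")
        assert models["t1"].cds is None
        assert any("dropping CDS" in r.message for r in caplog.records)

    def test_write_back_round_trip_is_idempotent(self, transcriptome, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(transcriptome.models.values(), p1)
        first = parse_gtf(p1)
        write_gtf(first.values(), p2)
        assert p1.read_text() == p2.read_text()
        second = parse_gtf(p2)
        for tid, m in transcriptome.models.items():
            assert second[tid].exons == m.exons
            assert second[tid].cds == m.cds
            assert second[tid].strand == m.strand


class TestExtractSequence:
    def test_plus_strand_spliced_and_transcribed(self):
        genome = {"c": GenomeSequence("c", "ATGCCCAAATTT")}
        m = TranscriptModel("t", "g", "g", "c", "+", [(0, 3), (6, 9)])
        assert extract_sequence(m, genome).sequence == "ATGAAA".replace("T", "U")

    def test_minus_strand_reverse_complement(self):
        genome = {"c": GenomeSequence("c", "CATCAT")}
        m = TranscriptModel("t", "g", "g", "c", "-", [(0, 6)])
        assert extract_sequence(m, genome).sequence == "AUGAUG"

    def test_exon_beyond_chromosome_is_error(self):
        genome = {"c": GenomeSequence("c", "ACGT")}
        m = TranscriptModel("t", "g", "g", "c", "+", [(0, 10)])
        with pytest.raises(IndexError):
            extract_sequence(m, genome)

    def test_missing_chromosome_is_error(self):
        m = TranscriptModel("t", "g", "g", "nope", "+", [(0, 4)])
        with pytest.raises(KeyError):
            extract_sequence(m, {"c": GenomeSequence("c", "ACGT")})

    def test_minus_extraction_is_revcomp_of_plus(self, transcriptome):
        for m in transcriptome.models.values():
            flipped = TranscriptModel(
                m.transcript_id, m.gene_id, m.gene_name, m.chrom,
                "-" if m.strand == "+" else "+", m.exons,
            )
            a = extract_sequence(m, transcriptome.genome, alphabet="dna").sequence
            b = extract_sequence(flipped, transcriptome.genome, alphabet="dna").sequence
            assert a == reverse_complement(b)


class TestCoordinateMapping:
    def test_plus_strand_first_exonic_base(self):
        m = TranscriptModel("t", "g", "g", "c", "+", [(10, 20)])
        assert m.genome_to_transcript(10) == 0

    def test_minus_strand_last_genomic_base_is_five_prime(self):
        m = TranscriptModel("t", "g", "g", "c", "-", [(10, 20)])
        assert m.genome_to_transcript(19) == 0

    def test_intronic_position_maps_to_none(self):
        m = TranscriptModel("t", "g", "g", "c", "+", [(10, 20)])
        assert m.genome_to_transcript(25) is None

    @given(
        seed=st.integers(0, 10_000),
        strand=st.sampled_from("+-"),
        n_exons=st.integers(1, 5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip_identity_on_all_exonic_positions(self, seed, strand, n_exons):
        rng = random.Random(seed)
        exons, pos = [], rng.randint(0, 50)
        for _ in range(n_exons):
            length = rng.randint(1, 60)
            exons.append((pos, pos + length))
            pos += length + rng.randint(1, 40)
        m = TranscriptModel("t", "g", "g", "c", strand, exons)
        seen = set()
        for s, e in exons:
            for g in range(s, e):
                t = m.genome_to_transcript(g)
                assert t is not None and m.transcript_to_genome(t) == g
                seen.add(t)
        assert seen == set(range(m.length))


def test_read_fasta_line_wrapped(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">chrA\nACGTAC\nGTAA\n>chrB\nTTTT\n")
    genome = read_fasta(path)
    assert genome["chrA"].sequence == "ACGTACGTAA"
    assert genome["chrB"].fetch(0, 4) == "TTTT"
    with pytest.raises(IndexError):
        genome["chrB"].fetch(0, 5)
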