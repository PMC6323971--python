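"""Hotspot binning, genomic-element assignment and track intersection."""

import random

import pytest

from ribostar import fixtures as fx
from ribostar.annotation_io import TranscriptModel
from ribostar.rbp_sites import (
    BindingSite,
    Feature,
    GeneSpan,
    assign_elements,
    build_element_index,
    compute_hotspots,
    intersect_tracks,
    read_features_bed,
    read_sites_bed,
    write_features_bed,
    write_sites_bed,
)

GENE = GeneSpan("g", "chr1", 0, 200, "+")


def _site(start, end, rbp, strand="+", chrom="chr1", **kw):
    return BindingSite(chrom=chrom, start=start, end=end, strand=strand, rbp=rbp, **kw)


class TestHotspots:
    def test_counts_distinct_proteins_not_peaks(self):
        three = [_site(0, 10, f"R{i}") for i in range(3)]
        assert compute_hotspots(three, GENE).counts[0] == 3
        five_same = [_site(i, i + 5, "R0") for i in range(5)]
        assert compute_hotspots(five_same, GENE).counts[0] == 1

    def test_duplicate_site_records_never_change_counts(self):
        sites = [_site(5, 30, "A"), _site(25, 60, "B")]
        base = compute_hotspots(sites, GENE).counts
        assert compute_hotspots(sites * 3, GENE).counts == base

    def test_bin_boundary_half_open_convention(self):
        # [20, 40) touches bin 1 only; [19, 21) touches bins 0 and 1
        assert compute_hotspots([_site(20, 40, "A")], GENE).counts[:3] == [0, 1, 0]
        assert compute_hotspots([_site(19, 21, "A")], GENE).counts[:3] == [1, 1, 0]

    def test_minus_strand_gene_bins_from_its_five_prime_end(self):
        gene = GeneSpan("g", "chr1", 0, 100, "-")
        profile = compute_hotspots([_site(95, 100, "A", strand="-")], gene)
        assert profile.counts[0] == 1 and sum(profile.counts) == 1

    def test_strand_matching_dot_matches_both(self):
        gene = GeneSpan("g", "chr1", 0, 100, "+")
        assert sum(compute_hotspots([_site(0, 5, "A", strand="-")], gene).counts) == 0
        assert sum(compute_hotspots([_site(0, 5, "A", strand=".")], gene).counts) == 1

    def test_chromosome_mismatch_skipped(self):
        assert sum(compute_hotspots([_site(0, 5, "A", chrom="chr2")], GENE).counts) == 0

    def test_final_partial_bin_retained(self):
        gene = GeneSpan("g", "chr1", 0, 45, "+")
        profile = compute_hotspots([_site(42, 44, "A")], gene)
        assert len(profile.bins) == 3 and profile.counts[2] == 1

    def test_matches_per_base_brute_force_on_random_fixtures(self):
        for seed in range(10):
            rng = random.Random(seed)
            gene = GeneSpan("g", "chrZ", 100, 100 + rng.randint(150, 800), "+")
            sites = []
            for _ in range(200):
                start = rng.randint(0, gene.end + 40)
                sites.append(
                    _site(start, start + rng.randint(5, 45),
                          f"RBP{rng.randrange(12)}", chrom="chrZ")
                )
            got = compute_hotspots(sites, gene).counts
            assert got == fx._per_base_bin_truth(sites, gene)

    def test_counts_bounded_by_distinct_rbp_total(self, clip):
        profile = compute_hotspots(clip.sites, clip.gene)
        n_rbps = len({s.rbp for s in clip.sites})
        assert all(0 <= c <= n_rbps for c in profile.counts)

    def test_key_by_sample_refines_counts(self):
        sites = [
            _site(0, 10, "A", sample="HeLa"),
            _site(2, 12, "A", sample="K562"),
        ]
        assert compute_hotspots(sites, GENE).counts[0] == 1
        assert compute_hotspots(sites, GENE, key_by_sample=True).counts[0] == 2


@pytest.fixture(scope="module")
def index():
    coding = TranscriptModel(
        "t1", "g1", "g1", "chr1", "+",
        exons=[(0, 100), (200, 400)], cds=(50, 300), biotype="protein_coding",
    )
    lnc = TranscriptModel(
        "t2", "g2", "g2", "chr1", "+", exons=[(600, 700)], biotype="lncRNA",
    )
    return build_element_index([coding, lnc])


class TestAssignElements:
    def test_cds_hit(self, index):
        assert assign_elements(_site(60, 70, "A"), index) == "CDS"

    def test_utr_beats_intron_under_default_priority(self, index):
        # [90, 110) overlaps the 5'UTR? no: CDS starts at 50 -> [90,100) is CDS.
        # Use the 3' side: [290, 310) overlaps CDS; [310, 330) is pure 3'UTR.
        assert assign_elements(_site(310, 330, "A"), index) == "3'UTR"
        # a site spanning 3'UTR exon and intron of another isoform keeps the UTR
        intronic_isoform = TranscriptModel(
            "t3", "g3", "g3", "chr1", "+", exons=[(250, 260), (500, 520)]
        )
        merged = build_element_index(
            [
                TranscriptModel(
                    "t1", "g1", "g1", "chr1", "+",
                    exons=[(0, 100), (200, 400)], cds=(50, 300),
                ),
                intronic_isoform,
            ]
        )
        assert assign_elements(_site(310, 330, "A"), merged) == "3'UTR"

    def test_five_prime_utr(self, index):
        assert assign_elements(_site(10, 30, "A"), index) == "5'UTR"

    def test_intron(self, index):
        assert assign_elements(_site(120, 150, "A"), index) == "intron"

    def test_lncrna_exon(self, index):
        assert assign_elements(_site(650, 660, "A"), index) == "lncRNA_exon"

    def test_intergenic_when_outside_all_models(self, index):
        assert assign_elements(_site(900, 950, "A"), index) == "intergenic"


class TestIntersect:
    def test_snv_inside_site_gives_one_pair(self):
        sites = [_site(95, 105, "A")]
        snv = [Feature("chr1", 100, 101, "rs1", "SNV")]
        assert len(intersect_tracks(sites, snv)) == 1

    def test_half_open_touch_gives_no_pair(self):
        sites = [_site(0, 10, "A")]
        touch = [Feature("chr1", 10, 15, "m1", "modification")]
        assert intersect_tracks(sites, touch).empty

    def test_zero_length_feature_treated_as_point(self):
        sites = [_site(95, 105, "A")]
        point = [Feature("chr1", 100, 100, "rs1", "SNV")]
        assert len(intersect_tracks(sites, point)) == 1

    def test_matches_quadratic_oracle_on_random_records(self):
        rng = random.Random(3)
        sites, features = [], []
        for i in range(300):
            s = rng.randint(0, 2000)
            sites.append(_site(s, s + rng.randint(1, 40), f"R{i % 7}",
                               chrom=rng.choice(["chr1", "chr2"])))
        kinds = ("miRNA_target", "modification", "editing", "SNV", "GWAS", "somatic")
        for i in range(300):
            s = rng.randint(0, 2000)
            w = 1 if i % 3 == 0 else rng.randint(1, 30)
            features.append(Feature(rng.choice(["chr1", "chr2"]), s, s + w,
                                    f"f{i}", kinds[i % 6]))
        got = intersect_tracks(sites, features)
        brute = sum(
            1
            for s in sites
            for f in features
            if s.chrom == f.chrom and s.start < f.end and f.start < s.end
        )
        assert len(got) == brute


class TestBedIO:
    def test_sites_round_trip(self, clip, tmp_path):
        path = tmp_path / "sites.bed"
        write_sites_bed(clip.sites, path)
        assert read_sites_bed(path) == clip.sites

    def test_features_round_trip(self, clip, tmp_path):
        path = tmp_path / "features.bed"
        write_features_bed(clip.features, path)
        assert read_features_bed(path) == clip.features

    def test_malformed_bed_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\tA\t0\t+\n" + "chr1\tnope\t10\tB\t0\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            read_sites_bed(path)
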