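"""IO contracts: BED regions, FASTA access, VCF decomposition, TSV tables."""

import pytest
from hypothesis import given, settings, strategies as st

from capmut.formats import (
    CatalogueEntry,
    FormatError,
    GeneModel,
    RegionSet,
    Segment,
    SegmentTrack,
    TargetRegion,
    read_catalogue,
    read_fasta,
    read_gene_models,
    read_regions,
    read_segments,
    read_vcf_pairs,
    write_catalogue,
    write_gene_models,
    write_segments,
)


# ---------------------------------------------------------------------------
# regions


class TestRegions:
    def test_invalid_interval_rejected(self):
        with pytest.raises(FormatError):
            TargetRegion("chr1", 200, 100, "CDS")
        with pytest.raises(FormatError):
            TargetRegion("chr1", 100, 200, "exon")  # not in the vocabulary

    def test_read_plain_region(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tCDS|GENE1\n")
        rs = read_regions(bed, flank=0)
        assert list(rs) == [TargetRegion("chr1", 100, 200, "CDS", "GENE1")]
        assert len(rs.regions[0]) == 100

    def test_flank_extension_adds_intronic_flank(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tCDS|GENE1\n")
        rs = read_regions(bed, flank=30)
        spans = {(r.start, r.end): r.region_class for r in rs}
        assert spans == {
            (70, 100): "intronic_flank",
            (100, 200): "CDS",
            (200, 230): "intronic_flank",
        }

    def test_same_class_overlap_merged(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tCDS\nchr1\t150\t250\tCDS\n")
        rs = read_regions(bed, flank=0)
        assert [(r.start, r.end) for r in rs] == [(100, 250)]

    def test_bad_coordinates_fatal_with_line(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tCDS\nchr1\t300\t300\tCDS\n")
        with pytest.raises(FormatError, match=":2"):
            read_regions(bed)

    def test_unknown_class_fatal(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t200\tpromoter\n")
        with pytest.raises(FormatError, match="promoter"):
            read_regions(bed)

    def test_classify_uses_precedence(self):
        rs = RegionSet(
            [
                TargetRegion("chr1", 100, 200, "upstream", "A"),
                TargetRegion("chr1", 150, 250, "CDS", "B"),
            ]
        )
        assert rs.classify("chr1", 120) == "upstream"
        assert rs.classify("chr1", 180) == "CDS"  # CDS outranks upstream
        assert rs.classify("chr1", 50) is None
        assert rs.stratum_of("chr1", 180) == "coding"
        assert rs.stratum_of("chr1", 120) == "non_coding"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_bed_roundtrip_is_identity(self, tmp_path_factory, data):
        classes = ["CDS", "UTR5", "UTR3", "upstream"]
        regions = []
        cursor = 0
        for i in range(data.draw(st.integers(1, 8))):
            gap = data.draw(st.integers(1, 50))
            length = data.draw(st.integers(1, 100))
            cls = data.draw(st.sampled_from(classes))
            regions.append(
                TargetRegion("chr1", cursor + gap, cursor + gap + length, cls, f"G{i}")
            )
            cursor += gap + length
        rs = RegionSet(regions)
        bed = tmp_path_factory.mktemp("rt") / "rt.bed"
        rs.to_bed(bed)
        assert read_regions(bed, flank=0) == rs


# ---------------------------------------------------------------------------
# fasta


class TestFasta:
    def test_fetch_uppercases_and_bounds(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">chr1\nacgt\n>chr2\nNNNAC\n")
        ref = read_fasta(fa)
        assert ref.fetch("chr1", 0, 3) == "ACG"
        assert ref.fetch("chr2", 0, 5) == "NNNAC"
        with pytest.raises(FormatError):
            ref.fetch("chr1", 0, 5)
        with pytest.raises(FormatError):
            ref.fetch("chrX", 0, 1)


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=HRun,Number=1,Type=Integer,Description="HRun">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="RPRS">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUM\tNRM
"""


class TestVcf:
    def _write(self, tmp_path, body: str):
        path = tmp_path / "x.vcf"
        path.write_text(VCF_HEADER + body)
        return path

    def test_field_mapping(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t100\t.\tC\tT\t55.5\t.\tQD=7.5;FS=3.2\tGT:AD\t0/1:7,5\t0/0:12,0\n",
        )
        (call,) = read_vcf_pairs(path, "TUM", "NRM")
        assert (call.tumor_alt_reads, call.normal_alt_reads) == (5, 0)
        assert (call.tumor_ref_reads, call.normal_ref_reads) == (7, 12)
        assert call.tumor_genotype == ("C", "T")
        assert call.normal_genotype == ("C", "C")
        assert call.qd == pytest.approx(7.5)
        assert call.fs == pytest.approx(3.2)
        assert call.hrun is None  # absent annotation stays absent, not zero
        assert call.read_pos_rank_sum is None
        assert call.pos == 100

    def test_multiallelic_decomposition(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t100\t.\tC\tT,G\t50\t.\tQD=9\tGT:AD\t1/2:2,5,6\t0/0:12,0,0\n",
        )
        calls = read_vcf_pairs(path, "TUM", "NRM")
        assert [(c.pos, c.alt) for c in calls] == [(100, "T"), (100, "G")]
        assert [c.tumor_alt_reads for c in calls] == [5, 6]

    def test_empty_body(self, tmp_path):
        path = self._write(tmp_path, "")
        assert read_vcf_pairs(path, "TUM", "NRM") == []

    def test_missing_sample_fatal(self, tmp_path):
        path = self._write(tmp_path, "")
        with pytest.raises(FormatError, match="NOPE"):
            read_vcf_pairs(path, "TUM", "NOPE")

    def test_malformed_genotype_skipped_and_collected(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t100\t.\tC\tT\t50\t.\t.\tGT:AD\t./.:.,.\t0/0:10,0\n"
            "chr1\t200\t.\tG\tA\t50\t.\t.\tGT:AD\t0/1:4,6\t0/0:9,0\n",
        )
        errors: list[str] = []
        calls = read_vcf_pairs(path, "TUM", "NRM", errors=errors)
        assert [c.pos for c in calls] == [200]
        assert len(errors) == 1 and "chr1:100" in errors[0]

    def test_decomposition_conserves_allele_count(self, tmp_path):
        body = (
            "chr1\t10\t.\tC\tT\t50\t.\t.\tGT:AD\t0/1:5,5\t0/0:9,0\n"
            "chr1\t20\t.\tA\tG,T\t50\t.\t.\tGT:AD\t1/2:1,4,5\t0/0:9,0,0\n"
            "chr1\t30\t.\tG\tA\t50\t.\t.\tGT:AD\t./.:.,.\t0/0:9,0\n"
        )
        errors: list[str] = []
        calls = read_vcf_pairs(self._write(tmp_path, body), "TUM", "NRM", errors=errors)
        n_alt_alleles = 1 + 2 + 1
        assert len(calls) == n_alt_alleles - len(errors)


# ---------------------------------------------------------------------------
# gene models, catalogue, segments


class TestTables:
    def test_gene_model_roundtrip(self, tmp_path):
        model = GeneModel(
            gene="G1", transcript_id="G1.1", chrom="chr1", strand="+",
            exons=((100, 250), (300, 420)), cds_start=150, cds_end=390,
        )
        path = tmp_path / "gm.tsv"
        write_gene_models([model], path)
        assert read_gene_models(path) == [model]
        assert model.cds_exons == ((150, 250), (300, 390))
        assert model.cds_length == 190
        assert model.introns == ((250, 300),)

    def test_gene_model_invariants(self):
        with pytest.raises(FormatError):
            GeneModel("G", "G.1", "chr1", "+", ((100, 50),), 0, 0)
        with pytest.raises(FormatError):
            GeneModel("G", "G.1", "chr1", "+", ((100, 200),), 50, 150)  # CDS outside

    def test_catalogue_roundtrip_with_dash_alleles(self, tmp_path):
        entries = [
            CatalogueEntry("chr1", 100, "C", "T", "G1", "COSM1"),
            CatalogueEntry("chr2", 50, "CT", "", "G2", "COSM2"),
        ]
        path = tmp_path / "cat.tsv"
        write_catalogue(entries, path)
        assert read_catalogue(path) == entries

    def test_segment_track_lookup(self, tmp_path):
        track = SegmentTrack(
            [Segment("chr1", 0, 100, 0.0), Segment("chr1", 100, 200, 2.5)]
        )
        assert track.lookup("chr1", 150).log2 == 2.5
        assert track.lookup("chr1", 250) is None
        assert track.lookup("chr2", 10) is None
        path = tmp_path / "seg.tsv"
        write_segments(track, path)
        assert [s.log2 for s in read_segments(path)] == [0.0, 2.5]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(FormatError):
            SegmentTrack([Segment("chr1", 0, 100, 0.0), Segment("chr1", 50, 150, 1.0)])
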