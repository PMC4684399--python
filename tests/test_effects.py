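"""Effect categorization: codon logic, region classes, strand handling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from capmut.effects import (
    EFFECT_CATEGORIES,
    annotate_effect,
    is_non_silent,
)
from capmut.formats import GeneModel
from conftest import DictReference

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def plus_gene(cds: str, offset: int = 50, pad: int = 500) -> tuple[DictReference, GeneModel]:
    """Single-exon plus-strand gene whose exon is entirely CDS."""
    seq = "A" * offset + cds + "A" * pad
    ref = DictReference({"chr1": seq})
    model = GeneModel(
        gene="G1", transcript_id="G1.1", chrom="chr1", strand="+",
        exons=((offset, offset + len(cds)),),
        cds_start=offset, cds_end=offset + len(cds),
    )
    return ref, model


class TestCodonLogic:
    def test_stopgain_caa_to_taa(self):
        # codon CAA, C->T at codon position 1 gives TAA (stop)
        ref, model = plus_gene("ATGCAATAA")
        ann = annotate_effect(("chr1", 50 + 3 + 1, "C", "T"), [model], ref)
        assert ann.category == "stopgain_SNV"
        assert ann.hgvs_c == "c.C4T"
        assert ann.hgvs_p == "p.Q2*"

    def test_synonymous_third_position(self):
        # CTA -> CTG, both Leu
        ref, model = plus_gene("ATGCTATAA")
        ann = annotate_effect(("chr1", 50 + 6, "A", "G"), [model], ref)
        assert ann.category == "synonymous_SNV"

    def test_stoploss(self):
        ref, model = plus_gene("ATGCAATAA")
        ann = annotate_effect(("chr1", 50 + 7, "A", "C"), [model], ref)  # TAA->TCA
        assert ann.category == "stoploss_SNV"

    def test_indel_frameshift_rule(self):
        ref, model = plus_gene("ATGCAACTGTAA")
        pos = 50 + 3  # anchored deletions inside the CDS
        anchor = ref.fetch("chr1", pos - 1, pos)
        del2 = (
            "chr1", pos, anchor + ref.fetch("chr1", pos, pos + 2), anchor
        )
        del3 = (
            "chr1", pos, anchor + ref.fetch("chr1", pos, pos + 3), anchor
        )
        assert annotate_effect(del2, [model], ref).category == "frameshift_deletion"
        assert annotate_effect(del3, [model], ref).category == "nonframeshift_deletion"

    def test_minus_strand_codon(self):
        # plus-strand genome holds revcomp(ATG CAA TAA); mutate the base that
        # is codon 2 position 1 on the coding (minus) strand
        cds_rc = revcomp("ATGCAATAA")
        seq = "G" * 50 + cds_rc + "G" * 500
        ref = DictReference({"chr1": seq})
        model = GeneModel(
            gene="G1", transcript_id="G1.1", chrom="chr1", strand="-",
            exons=((50, 50 + 9),), cds_start=50, cds_end=50 + 9,
        )
        # coding C at CDS index 3 sits at genomic pos0 = cds_end-1-3 as G
        gpos0 = (50 + 9) - 1 - 3
        assert ref.fetch("chr1", gpos0, gpos0 + 1) == "G"
        ann = annotate_effect(("chr1", gpos0 + 1, "G", "A"), [model], ref)  # C->T coding
        assert ann.category == "stopgain_SNV"


class TestRegions:
    def _two_exon_gene(self):
        # exon1 [50,110): UTR5 [50,80) + CDS [80,110); intron [110,170);
        # exon2 [170,260): CDS [170,230) + UTR3 [230,260)
        cds = "ATG" + "CAT" * 28 + "TAA"  # 90 bases
        seq = (
            "A" * 50 + "C" * 30 + cds[:30] + "G" * 60 + cds[30:] + "T" * 30 + "A" * 1200
        )
        ref = DictReference({"chr1": seq})
        model = GeneModel(
            gene="G2", transcript_id="G2.1", chrom="chr1", strand="+",
            exons=((50, 110), (170, 260)), cds_start=80, cds_end=230,
        )
        return ref, model

    @pytest.mark.parametrize(
        "pos0,expected",
        [
            (110, "splicing"),  # 1 bp into the intron after an exon
            (111, "splicing"),
            (112, "intronic"),  # outside the 2 bp window
            (168, "splicing"),  # acceptor side
            (60, "UTR5"),
            (240, "UTR3"),
            (49, "upstream"),
            (1300, "intergenic"),
        ],
    )
    def test_region_classes(self, pos0, expected):
        ref, model = self._two_exon_gene()
        base = ref.fetch("chr1", pos0, pos0 + 1)
        alt = "T" if base != "T" else "G"
        ann = annotate_effect(("chr1", pos0 + 1, base, alt), [model], ref)
        assert ann.category == expected

    def test_upstream_window_limit(self):
        ref, model = self._two_exon_gene()
        # put the gene far enough in: here tx_start=50, so pos0 < 50 is
        # upstream only within 1000 bp, which all of [0,50) is
        ann = annotate_effect(("chr1", 1, "A", "G"), [model], ref)
        assert ann.category == "upstream"

    def test_noncoding_transcript_is_ncrna(self):
        ref, _ = self._two_exon_gene()
        model = GeneModel(
            gene="NC1", transcript_id="NC1.1", chrom="chr1", strand="+",
            exons=((50, 110),), cds_start=50, cds_end=50,
        )
        ann = annotate_effect(("chr1", 61, "C", "T"), [model], ref)
        assert ann.category == "ncRNA"

    def test_most_severe_category_across_transcripts(self):
        ref, coding = self._two_exon_gene()
        nc = GeneModel(
            gene="NC1", transcript_id="NC1.1", chrom="chr1", strand="+",
            exons=((40, 300),), cds_start=40, cds_end=40,
        )
        base = ref.fetch("chr1", 60, 61)
        ann = annotate_effect(("chr1", 61, base, "T" if base != "T" else "G"), [coding, nc], ref)
        assert ann.category == "UTR5"  # outranks ncRNA

    def test_outside_reference_fatal(self):
        ref, model = self._two_exon_gene()
        with pytest.raises(ValueError):
            annotate_effect(("chr1", 10_000_000, "A", "G"), [model], ref)


class TestNonSilent:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("nonsynonymous_SNV", True),
            ("stopgain_SNV", True),
            ("stoploss_SNV", True),
            ("frameshift_deletion", True),
            ("frameshift_insertion", True),
            ("nonframeshift_deletion", True),
            ("nonframeshift_insertion", True),
            ("splicing", True),
            ("synonymous_SNV", False),
            ("UTR3", False),
            ("UTR5", False),
            ("upstream", False),
            ("intronic", False),
            ("intergenic", False),
            ("ncRNA", False),
            ("unknown", False),
        ],
    )
    def test_vocabulary(self, category, expected):
        assert is_non_silent(category) is expected

    def test_unknown_label_fatal(self):
        with pytest.raises(ValueError):
            is_non_silent("missense")


class TestProperties:
    def _random_gene(self, rng, strand="+"):
        n_codons = int(rng.integers(5, 40))
        codons = ["ATG"]
        for _ in range(n_codons - 2):
            codons.append("".join(rng.choice(list("ACGT"), size=3)))
        codons.append(rng.choice(["TAA", "TAG", "TGA"]))
        cds = "".join(codons)
        offset = int(rng.integers(20, 60))
        pad = int(rng.integers(20, 60))
        flank = "".join(rng.choice(list("ACGT"), size=offset + pad))
        if strand == "+":
            seq = flank[:offset] + cds + flank[offset:]
        else:
            seq = flank[:offset] + revcomp(cds) + flank[offset:]
        ref = DictReference({"chr1": seq})
        model = GeneModel(
            gene="R", transcript_id="R.1", chrom="chr1", strand=strand,
            exons=((offset, offset + len(cds)),),
            cds_start=offset, cds_end=offset + len(cds),
        )
        return ref, model, cds

    @staticmethod
    def _oracle_category(cds_before: str, cds_after: str) -> str:
        """Brute force: translate the full CDS before and after."""
        p0 = str(Seq(cds_before).translate())
        p1 = str(Seq(cds_after).translate())
        if p0 == p1:
            return "synonymous_SNV"
        if p1.count("*") > p0.count("*"):
            return "stopgain_SNV"
        if p1.count("*") < p0.count("*"):
            return "stoploss_SNV"
        return "nonsynonymous_SNV"

    def test_cds_snv_agrees_with_full_translation(self):
        """1000 random single-base CDS mutations against the brute-force
        whole-CDS translation oracle, both strands."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            strand = "+" if rng.random() < 0.5 else "-"
            ref, model, cds = self._random_gene(rng, strand)
            for _ in range(10):
                ci = int(rng.integers(len(cds)))
                old = cds[ci]
                new = "ACGT".replace(old, "")[int(rng.integers(3))]
                cds_after = cds[:ci] + new + cds[ci:][1:]
                if strand == "+":
                    gpos0 = model.cds_start + ci
                    g_old, g_new = old, new
                else:
                    gpos0 = model.cds_end - 1 - ci
                    g_old, g_new = revcomp(old), revcomp(new)
                ann = annotate_effect(("chr1", gpos0 + 1, g_old, g_new), [model], ref)
                assert ann.category == self._oracle_category(cds, cds_after)
                checked += 1

    def test_strand_symmetry(self):
        """Annotating the reverse-complemented construct yields the same
        category for the mirrored variant."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            ref, model, cds = self._random_gene(rng, "+")
            L = ref.length("chr1")
            seq_rc = revcomp(ref.fetch("chr1", 0, L))
            ref_rc = DictReference({"chr1": seq_rc})
            model_rc = GeneModel(
                gene="R", transcript_id="R.1", chrom="chr1", strand="-",
                exons=tuple(sorted((L - e, L - s) for s, e in model.exons)),
                cds_start=L - model.cds_end, cds_end=L - model.cds_start,
            )
            pos0 = int(rng.integers(L))
            old = ref.fetch("chr1", pos0, pos0 + 1)
            new = "ACGT".replace(old, "")[int(rng.integers(3))]
            fwd = annotate_effect(("chr1", pos0 + 1, old, new), [model], ref)
            mirrored_pos0 = L - 1 - pos0
            rev = annotate_effect(
                ("chr1", mirrored_pos0 + 1, revcomp(old), revcomp(new)),
                [model_rc], ref_rc,
            )
            assert fwd.category == rev.category

    def test_every_variant_gets_exactly_one_category(self):
        rng = np.random.default_rng(5)
        ref, model, _ = self._random_gene(rng, "+")
        for pos0 in range(ref.length("chr1")):
            old = ref.fetch("chr1", pos0, pos0 + 1)
            ann = annotate_effect(("chr1", pos0 + 1, old, "ACGT".replace(old, "")[0]), [model], ref)
            assert ann.category in EFFECT_CATEGORIES
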