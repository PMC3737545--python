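"""Flank extraction, the flank FASTA dialect, and anchor-relative
coordinate mapping."""

import pytest

from g4scan import (
    AnchoredMatch,
    FlankRegion,
    GeneRecord,
    PQSMatch,
    anchor_matches,
    extract_flanks,
    read_flank_fasta,
    read_genes_bed,
    read_genes_gff3,
    reverse_complement,
    scan_both_strands,
    write_flank_fasta,
)

MOTIF = "GGGTGGGTGGGTGGG"


def make_chrom(n=3000, base="A"):
    return base * n


class TestExtractFlanks:
    def test_plus_strand_tss_upstream(self):
        genome = {"c": make_chrom()}
        g = GeneRecord("g1", "c", 1000, 2000, "+")
        (f,) = extract_flanks(genome, [g], "TSS", 500)
        assert f.seq == genome["c"][500:1000]
        assert f.side == "upstream" and not f.truncated

    def test_minus_strand_tss_upstream_is_revcomp_right_flank(self):
        chrom = "A" * 2000 + "ACGTG" * 100 + "A" * 500
        g = GeneRecord("g1", "c", 1000, 2000, "-")
        (f,) = extract_flanks({"c": chrom}, [g], "TSS", 500)
        assert f.seq == reverse_complement(chrom[2000:2500])

    def test_minus_strand_tes_downstream(self):
        chrom = "T" * 500 + "CCGTA" * 100 + "T" * 2000
        g = GeneRecord("g1", "c", 1000, 2000, "-")
        (f,) = extract_flanks({"c": chrom}, [g], "TES", 500)
        assert f.seq == reverse_complement(chrom[500:1000])

    def test_truncation_at_chromosome_edge(self):
        g = GeneRecord("g1", "c", 100, 600, "+")
        (f,) = extract_flanks({"c": make_chrom(1000)}, [g], "TSS", 500)
        assert f.truncated and f.realized_length == 100

    def test_duplicate_gene_ids_rejected(self):
        gs = [GeneRecord("g1", "c", 100, 200, "+"), GeneRecord("g1", "c", 300, 400, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            extract_flanks({"c": make_chrom()}, gs, "TSS", 50)

    def test_gene_outside_chromosome_rejected(self):
        g = GeneRecord("g1", "c", 100, 5000, "+")
        with pytest.raises(ValueError, match="exceed"):
            extract_flanks({"c": make_chrom()}, [g], "TSS", 50)

    @pytest.mark.parametrize("gene_strand", ["+", "-"])
    @pytest.mark.parametrize("anchor", ["TSS", "TES"])
    def test_planted_motif_recovered_all_orientations(self, gene_strand, anchor):
        """A motif planted at a known anchor coordinate on the sense
        strand comes back at exactly that coordinate, as non-template,
        for every (gene strand x flank side) combination."""
        L, coord = 500, -100 if anchor == "TSS" else 101
        side = "upstream" if anchor == "TSS" else "downstream"
        offset = (L + coord) if side == "upstream" else (coord - 1)
        sense_flank = "A" * offset + MOTIF + "A" * (L - offset - len(MOTIF))
        body = "T" * 300
        if side == "upstream":
            unit = sense_flank + body + "T" * L
        else:
            unit = "T" * L + body + sense_flank
        chrom = unit if gene_strand == "+" else reverse_complement(unit)
        g = GeneRecord("g1", "c", L, L + 300, gene_strand)
        (f,) = extract_flanks({"c": chrom}, [g], anchor, L)
        anchored = anchor_matches(f, scan_both_strands(f.seq, None, "g1"))
        assert [(a.coord, a.span, a.strand_class) for a in anchored] == [
            (coord, 15, "non-template")
        ]


class TestAnchorMatches:
    def test_upstream_mapping(self):
        fl = FlankRegion("g", "TSS", "upstream", 5000, "A" * 5000, "+")
        a1 = anchor_matches(fl, [PQSMatch("g", 4450, 4465, "+", "A" * 15, 4)])[0]
        assert (a1.coord, a1.span, a1.strand_class) == (-550, 15, "non-template")
        a2 = anchor_matches(fl, [PQSMatch("g", 4985, 5000, "-", "A" * 15, 4)])[0]
        assert (a2.coord, a2.strand_class) == (-15, "template")

    def test_downstream_mapping(self):
        fl = FlankRegion("g", "TES", "downstream", 5000, "A" * 5000, "+")
        a = anchor_matches(fl, [PQSMatch("g", 0, 15, "+", "A" * 15, 4)])[0]
        assert a.coord == 1

    def test_truncated_flank_maps_from_anchor(self):
        # a truncated upstream flank still has its last base at -1
        fl = FlankRegion("g", "TSS", "upstream", 5000, "A" * 100, "+", truncated=True)
        a = anchor_matches(fl, [PQSMatch("g", 85, 100, "+", "A" * 15, 4)])[0]
        assert a.coord == -15

    def test_out_of_bounds_match_rejected(self):
        fl = FlankRegion("g", "TSS", "upstream", 100, "A" * 100, "+")
        with pytest.raises(ValueError, match="out of bounds"):
            anchor_matches(fl, [PQSMatch("g", 90, 105, "+", "A" * 15, 4)])

    def test_anchoring_injective(self):
        seq = ("GGGTGGGTGGGTGGG" + "A" * 10 + "CCCACCCACCCACCC" + "A" * 10) * 3
        fl = FlankRegion("g", "TSS", "upstream", len(seq), seq, "+")
        anchored = anchor_matches(fl, scan_both_strands(seq, None, "g"))
        keys = [(a.coord, a.strand_class) for a in anchored]
        assert len(keys) == len(set(keys)) and len(keys) == 6


class TestFlankFastaDialect:
    def test_round_trip(self, tmp_path):
        flanks = [
            FlankRegion("G1", "TSS", "upstream", 30, "ACGT" * 7 + "AC", "+"),
            FlankRegion("G2", "TES", "downstream", 30, "TTT" * 10, "-"),
            FlankRegion("G3", "TSS", "upstream", 30, "ACGTA", "+", truncated=True),
        ]
        p = tmp_path / "flanks.fa"
        write_flank_fasta(flanks, p)
        assert read_flank_fasta(p) == flanks

    def test_gzip_round_trip(self, tmp_path):
        flanks = [FlankRegion("G1", "TSS", "upstream", 8, "ACGTACGT", "+")]
        p = tmp_path / "flanks.fa.gz"
        write_flank_fasta(flanks, p)
        assert read_flank_fasta(p) == flanks

    def test_malformed_header_reports_record_index(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">G1|TSS|upstream|8|+\nACGTACGT\n>G2|TSS|upstream\nACGT\n")
        with pytest.raises(ValueError, match="record 1"):
            read_flank_fasta(p)

    def test_duplicate_flank_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">G1|TSS|upstream|4|+\nACGT\n>G1|TSS|upstream|4|+\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_flank_fasta(p)


class TestAnnotationReaders:
    def test_bed6(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t900\tgeneA\t0\t+\nchr1\t2000\t2500\tgeneB\t0\t-\n")
        genes = read_genes_bed(p)
        assert genes == [
            GeneRecord("geneA", "chr1", 100, 900, "+"),
            GeneRecord("geneB", "chr1", 2000, 2500, "-"),
        ]

    def test_gff3_converts_to_half_open(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t900\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tmRNA\t101\t900\t.\t+\t.\tID=t1;Parent=geneA\n"
            "chr1\tsrc\tgene\t2001\t2500\t.\t-\t.\tID=geneB\n"
        )
        genes = read_genes_gff3(p)
        assert genes == [
            GeneRecord("geneA", "chr1", 100, 900, "+"),
            GeneRecord("geneB", "chr1", 2000, 2500, "-"),
        ]


def test_anchored_match_validation():
    with pytest.raises(ValueError):
        AnchoredMatch("g", "TSS", "upstream", 5, 15, "template")
    with pytest.raises(ValueError):
        AnchoredMatch("g", "TES", "downstream", -5, 15, "template")
    with pytest.raises(ValueError):
        AnchoredMatch("g", "TSS", "upstream", -5, 15, "sense")
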