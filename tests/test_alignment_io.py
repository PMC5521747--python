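"""MAF/BED reading, gene assembly, block partitioning and their invariants."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ercov.alignment_io import (
    BedValidationError,
    BlockSet,
    GeneAlignment,
    GeneModel,
    GenomicInterval,
    MafParseError,
    assemble_gene_alignment,
    extract_block,
    partition_blocks,
    read_bed,
    read_fasta_alignment,
    read_maf,
    reverse_complement,
    write_fasta_alignment,
)


class TestReadMaf:
    def test_round_trip_two_taxa(self, maf_two_block):
        segments = read_maf(maf_two_block, "ref")
        assert len(segments) == 2
        seg = segments[0]
        assert seg.ref_chrom == "chr1"
        assert (seg.ref_start, seg.ref_size, seg.n_columns) == (100, 10, 10)
        assert seg.rows["ref"] == "ACGTACGTAC"
        assert seg.rows["sp2"] == "ACGTACGAAC"
        assert all(len(s) == 10 for s in seg.rows.values())

    def test_absent_taxon_recorded_missing(self, maf_two_block):
        segments = read_maf(maf_two_block, "ref")
        assert "sp3" in segments[0].rows
        assert "sp3" not in segments[1].rows

    def test_reverse_strand_reference_converted_to_forward(self, tmp_path):
        # hand conversion: start' = srcSize - start - size = 20 - 4 - 6 = 10;
        # rows reverse-complemented: ACG-TT -> AA-CGT, ACGATT -> AATCGT
        text = textwrap.dedent(
            """\
            ##maf version=1
            a score=0.0
            s ref.chr1 4 6 - 20 ACG-TT
            s sp2.chrA 0 6 + 30 ACGATT
            """
        )
        path = tmp_path / "rev.maf"
        path.write_text(text)
        (seg,) = read_maf(path, "ref")
        assert seg.ref_start == 10
        assert seg.ref_size == 6
        assert seg.rows["ref"] == "AA-CGT"
        assert seg.rows["sp2"] == "AATCGT"

    def test_wrong_reference_taxon_raises(self, maf_two_block):
        with pytest.raises(MafParseError, match="reference taxon"):
            read_maf(maf_two_block, "sp2")


class TestReadBed:
    def test_two_exon_gene_coding_length(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr3R\t100\t200\tg1\t0\t+\nchr3R\t300\t360\tg1\t0\t+\n")
        models = read_bed(path)
        assert models["g1"].coding_length == 160
        assert models["g1"].strand == "+"

    def test_minus_strand_single_exon(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr2L\t10\t40\tg2\t0\t-\n")
        model = read_bed(path)["g2"]
        assert model.strand == "-"
        assert len(model.exons) == 1

    def test_overlapping_exons_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t10\t40\tg1\t0\t+\nchr1\t30\t60\tg1\t0\t+\n")
        with pytest.raises(BedValidationError, match="overlapping"):
            read_bed(path)

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t50\t40\tg1\t0\t+\n", "start"),
            ("chr1\t10\t40\tg1\t0\n", "6 BED columns"),
            ("chr1\t10\t40\tg1\t0\t*\n", "strand"),
        ],
    )
    def test_malformed_records_rejected(self, tmp_path, line, match):
        path = tmp_path / "bad.bed"
        path.write_text(line)
        with pytest.raises(BedValidationError, match=match):
            read_bed(path)

    def test_mixed_strands_within_gene_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t10\t40\tg1\t0\t+\nchr1\t50\t60\tg1\t0\t-\n")
        with pytest.raises(BedValidationError, match="mixed strands"):
            read_bed(path)


class TestAssemble:
    def test_plus_strand_two_exons_full_coverage(self, maf_two_block, bed_two_exons):
        segments = read_maf(maf_two_block, "ref")
        model = read_bed(bed_two_exons)["g1"]
        aln = assemble_gene_alignment(segments, model, ["ref", "sp2", "sp3"])
        assert aln.n_columns == model.coding_length == 14
        # exon1 = ref positions 100..108 (first 8 of block 1), exon2 = 110..116
        assert aln.rows["ref"] == "ACGTACGT" + "GGGTTT"
        assert aln.rows["sp2"] == "ACGTACGA" + "GGCTTT"
        # sp3 covers exon1 only; exon2 filled with N
        assert aln.rows["sp3"] == "ACCTACGT" + "NNNNNN"

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        text = textwrap.dedent(
            """\
            ##maf version=1
            a score=0.0
            s ref.chr1 0 6 + 100 ACGTTT
            s sp2.chrA 0 6 + 100 ACGTTA
            """
        )
        maf = tmp_path / "m.maf"
        maf.write_text(text)
        segments = read_maf(maf, "ref")
        model = GeneModel("g", (GenomicInterval("chr1", 0, 6, "-"),), "-")
        aln = assemble_gene_alignment(segments, model, ["ref", "sp2"])
        assert aln.rows["ref"] == "AAACGT"
        assert aln.rows["sp2"] == "TAACGT"

    def test_uncovered_span_warns_and_fills_n(self, maf_two_block, tmp_path):
        bed = tmp_path / "wide.bed"
        bed.write_text("chr1\t100\t120\tg1\t0\t+\n")  # MAF covers 100-116 only
        segments = read_maf(maf_two_block, "ref")
        model = read_bed(bed)["g1"]
        with pytest.warns(UserWarning, match="no MAF coverage"):
            aln = assemble_gene_alignment(segments, model, ["ref", "sp2"])
        assert aln.rows["ref"].endswith("NNNN")
        with pytest.raises(ValueError, match="no MAF coverage"):
            assemble_gene_alignment(segments, model, ["ref", "sp2"], strict=True)

    def test_reference_gap_columns_dropped(self, tmp_path):
        text = textwrap.dedent(
            """\
            ##maf version=1
            a score=0.0
            s ref.chr1 0 6 + 100 AC--GTTT
            s sp2.chrA 0 8 + 100 ACAAGTTT
            """
        )
        maf = tmp_path / "gap.maf"
        maf.write_text(text)
        segments = read_maf(maf, "ref")
        model = GeneModel("g", (GenomicInterval("chr1", 0, 6, "+"),), "+")
        aln = assemble_gene_alignment(segments, model, ["ref", "sp2"])
        assert aln.rows["ref"] == "ACGTTT"
        assert aln.rows["sp2"] == "ACGTTT"

    def test_exon_splitting_invariance(self, maf_two_block):
        """Splitting one exon into two adjacent BED records changes nothing."""
        segments = read_maf(maf_two_block, "ref")
        whole = GeneModel("g", (GenomicInterval("chr1", 100, 108, "+"),), "+")
        split = GeneModel(
            "g",
            (
                GenomicInterval("chr1", 100, 104, "+"),
                GenomicInterval("chr1", 104, 108, "+"),
            ),
            "+",
        )
        aln_whole = assemble_gene_alignment(segments, whole, ["ref", "sp2", "sp3"])
        aln_split = assemble_gene_alignment(segments, split, ["ref", "sp2", "sp3"])
        assert aln_whole.rows == aln_split.rows

    def test_strand_symmetry_round_trip(self, maf_two_block):
        """Minus-strand assembly equals reverse-complemented plus-strand assembly."""
        segments = read_maf(maf_two_block, "ref")
        plus = GeneModel("g", (GenomicInterval("chr1", 100, 108, "+"),), "+")
        minus = GeneModel("g", (GenomicInterval("chr1", 100, 108, "-"),), "-")
        aln_plus = assemble_gene_alignment(segments, plus, ["ref", "sp2", "sp3"])
        aln_minus = assemble_gene_alignment(segments, minus, ["ref", "sp2", "sp3"])
        for taxon in aln_plus.taxa:
            assert aln_minus.rows[taxon] == reverse_complement(aln_plus.rows[taxon])


class TestBlocks:
    @pytest.mark.parametrize(
        "n_cols, n_blocks, lengths",
        [
            (10, 4, [3, 3, 2, 2]),
            (12, 1, [12]),
            (12, 12, [1] * 12),
            (7, 3, [3, 2, 2]),
        ],
    )
    def test_partition_lengths(self, n_cols, n_blocks, lengths):
        aln = GeneAlignment("g", ("a", "b"), {"a": "A" * n_cols, "b": "A" * n_cols}, "a")
        blocks = partition_blocks(aln, n_blocks)
        assert [e - s for s, e in blocks.boundaries] == lengths
        assert blocks.n_columns == n_cols

    def test_paper_scale_block_counts(self):
        """4 blocks for the short gene, 250 for the long one, as in the study design."""
        short = GeneAlignment("cher", ("a", "b"), {"a": "A" * 2400, "b": "A" * 2400}, "a")
        long = GeneAlignment("sls", ("a", "b"), {"a": "A" * 17500, "b": "A" * 17500}, "a")
        assert partition_blocks(short, 4).n_blocks == 4
        assert partition_blocks(long, 250).n_blocks == 250

    def test_too_many_blocks_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="n_blocks"):
            partition_blocks(toy_alignment, 13)

    def test_extract_identity_and_substring(self, toy_alignment):
        full = extract_block(toy_alignment, (0, 12))
        assert full.rows == toy_alignment.rows
        sub = extract_block(toy_alignment, (3, 6))
        assert sub.n_columns == 3
        assert sub.rows["t1"] == "TAC"

    @pytest.mark.parametrize("interval", [(3, 3), (5, 3), (-1, 4), (0, 13)])
    def test_extract_bad_interval_rejected(self, toy_alignment, interval):
        with pytest.raises(ValueError):
            extract_block(toy_alignment, interval)

    @settings(max_examples=50, deadline=None)
    @given(
        n_cols=st.integers(min_value=1, max_value=200),
        data=st.data(),
    )
    def test_block_concatenation_reconstructs_alignment(self, n_cols, data):
        """Column conservation: blocks concatenated in order rebuild the gene."""
        n_blocks = data.draw(st.integers(min_value=1, max_value=n_cols))
        rng_row = data.draw(
            st.text(alphabet="ACGTN-", min_size=n_cols, max_size=n_cols)
        )
        aln = GeneAlignment(
            "g", ("a", "b"), {"a": rng_row, "b": rng_row[::-1]}, "a"
        )
        blocks = partition_blocks(aln, n_blocks)
        assert blocks.n_blocks == n_blocks
        for taxon in aln.taxa:
            rebuilt = "".join(
                extract_block(aln, iv).rows[taxon] for iv in blocks.boundaries
            )
            assert rebuilt == aln.rows[taxon]


class TestFasta:
    def test_fasta_round_trip(self, toy_alignment, tmp_path):
        path = tmp_path / "toy.fasta"
        write_fasta_alignment(toy_alignment, path)
        back = read_fasta_alignment(path, gene_id="toy")
        assert back.taxa == toy_alignment.taxa
        assert back.rows == toy_alignment.rows

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            GeneAlignment("g", ("a", "b"), {"a": "ACGT", "b": "ACG"}, "a")

    def test_blockset_must_tile_columns(self):
        with pytest.raises(ValueError, match="contiguous"):
            BlockSet("g", ((0, 3), (4, 6)))
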