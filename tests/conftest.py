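"""Shared fixtures: small hand-built alignments and on-disk MAF/BED inputs."""

from __future__ import annotations

import textwrap

import pytest

from ercov.alignment_io import GeneAlignment


@pytest.fixture
def toy_alignment() -> GeneAlignment:
    """Four taxa, 12 gapless columns, small hand-checkable divergence."""
    return GeneAlignment(
        gene_id="toy",
        taxa=("t1", "t2", "t3", "t4"),
        rows={
            "t1": "ACGTACGTACGT",
            "t2": "ACGTACGTACGA",
            "t3": "ACGTGCGTACGT",
            "t4": "ATGTACGTTCGT",
        },
        reference_taxon="t1",
    )


@pytest.fixture
def maf_two_block(tmp_path):
    """MAF with two reference-anchored blocks; taxon sp3 absent from block 2."""
    text = textwrap.dedent(
        """\
        ##maf version=1
        a score=0.0
        s ref.chr1 100 10 + 1000 ACGTACGTAC
        s sp2.chrA  50 10 + 2000 ACGTACGAAC
        s sp3.chrB  10 10 +  500 ACCTACGTAC

        a score=0.0
        s ref.chr1 110 6 + 1000 GGGTTT
        s sp2.chrA  60 6 + 2000 GGCTTT
        """
    )
    path = tmp_path / "two_block.maf"
    path.write_text(text)
    return path


@pytest.fixture
def bed_two_exons(tmp_path):
    """BED6 with a two-exon plus-strand gene spanning the MAF fixture."""
    path = tmp_path / "genes.bed"
    path.write_text(
        "chr1\t100\t108\tg1\t0\t+\n"
        "chr1\t110\t116\tg1\t0\t+\n"
    )
    return path
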