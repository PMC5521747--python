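"""Reading alignments and gene models; assembling per-gene coding alignments.

Coordinate conventions
----------------------
BED intervals are 0-based half-open on the forward genome strand.  MAF
segments whose reference row is on the minus strand are converted to
forward-strand coordinates on read (``start' = srcSize - start - size``,
rows reverse-complemented), so every stored segment is anchored forward.
Alignment columns where the reference carries a gap are dropped during
assembly, which makes reference genome coordinates index coding-alignment
columns one-to-one and keeps block boundaries reproducible from the BED
annotation alone.

Missing data: taxa absent from a MAF block, and reference positions not
covered by any MAF segment, are filled with ``N``.  Downstream distance
computation treats ``N`` (and ``-``) as a missing site for that pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneAlignment",
    "BlockSet",
    "MafSegment",
    "MafParseError",
    "BedValidationError",
    "read_maf",
    "read_bed",
    "assemble_gene_alignment",
    "partition_blocks",
    "extract_block",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "reverse_complement",
]

ALPHABET = "ACGTN-"
_COMPLEMENT = str.maketrans("ACGTN-acgtn", "TGCAN-tgcan")

# byte-value -> code lookup for fast row encoding (A=0 C=1 G=2 T=3 N=4 -=5)
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N,-} alphabet (case preserved as upper)."""
    return seq.translate(_COMPLEMENT)[::-1].upper()


def encode_row(seq: str) -> np.ndarray:
    """Encode a gapped sequence as uint8 codes A=0 C=1 G=2 T=3 N=4 gap=5.

    Raises ``ValueError`` on symbols outside the alphabet.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"unknown symbol {bad!r} in sequence")
    return codes


class MafParseError(ValueError):
    """Raised when a MAF file is structurally malformed."""


class BedValidationError(ValueError):
    """Raised when BED records violate gene-model invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """An exon chain for one gene; exons stored in genomic (ascending) order."""

    gene_id: str
    exons: tuple[GenomicInterval, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise BedValidationError(
                f"gene {self.gene_id}: exons span multiple chromosomes {sorted(chroms)}"
            )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start < prev.end:
                raise BedValidationError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
        object.__setattr__(self, "exons", tuple(ordered))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def coding_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class GeneAlignment:
    """A per-gene gapped multiple alignment of coding sequence, transcription order.

    ``rows`` maps taxon name to its gapped sequence; all rows share the same
    length ``n_columns``.  ``reference_taxon`` names the species whose genome
    coordinates anchor the columns (may be absent for simulated data, in which
    case the first taxon is the anchor by convention).
    """

    gene_id: str
    taxa: tuple[str, ...]
    rows: dict[str, str]
    reference_taxon: str
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if set(self.rows) != set(self.taxa):
            raise ValueError("rows and taxa disagree")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if self.reference_taxon not in self.taxa:
            raise ValueError(f"reference taxon {self.reference_taxon!r} not among taxa")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def matrix(self) -> np.ndarray:
        """uint8 code matrix, shape (n_taxa, n_columns); cached."""
        if self._matrix is None:
            self._matrix = np.vstack([encode_row(self.rows[t]) for t in self.taxa])
        return self._matrix

    def slice_columns(self, start: int, end: int, gene_id: str | None = None) -> "GeneAlignment":
        if not (0 <= start < end <= self.n_columns):
            raise ValueError(
                f"column interval [{start}, {end}) out of range for "
                f"{self.n_columns}-column alignment"
            )
        return GeneAlignment(
            gene_id=gene_id or self.gene_id,
            taxa=self.taxa,
            rows={t: s[start:end] for t, s in self.rows.items()},
            reference_taxon=self.reference_taxon,
        )


@dataclass(frozen=True)
class BlockSet:
    """Contiguous half-open column intervals exactly covering a gene alignment."""

    gene_id: str
    boundaries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.boundaries:
            raise ValueError("empty block set")
        pos = 0
        for start, end in self.boundaries:
            if start != pos or end <= start:
                raise ValueError(
                    f"blocks must be contiguous non-empty half-open intervals; "
                    f"got {self.boundaries}"
                )
            pos = end
        object.__setattr__(self, "boundaries", tuple(map(tuple, self.boundaries)))

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)

    @property
    def n_columns(self) -> int:
        return self.boundaries[-1][1]


@dataclass(frozen=True)
class MafSegment:
    """One MAF alignment block, forward-strand reference anchored.

    ``rows`` includes the reference taxon; taxa present in the file but not in
    this block simply have no entry (recorded missing).
    """

    ref_chrom: str
    ref_start: int  # forward-strand 0-based
    ref_size: int  # ungapped reference length
    n_columns: int
    rows: Mapping[str, str]
    reference_taxon: str

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_size


def _maf_taxon(record_id: str) -> tuple[str, str]:
    """Split a MAF src field 'species.chrom' into (species, chrom)."""
    if "." in record_id:
        sp, chrom = record_id.split(".", 1)
        return sp, chrom
    return record_id, record_id


def read_maf(path: str | Path, reference_taxon: str) -> list[MafSegment]:
    """Read a MAF file into reference-anchored segments.

    Each returned segment carries the reference chrom/start/size on the
    forward strand and one gapped row per taxon present in that block.
    Blocks whose first sequence line is not the reference taxon raise a
    configuration error, mirroring the reference-anchored MAF convention.
    """
    path = Path(path)
    try:
        blocks = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise MafParseError(f"{path}: malformed MAF: {exc}") from exc

    segments: list[MafSegment] = []
    for block_idx, block in enumerate(blocks):
        if len(block) == 0:
            continue
        widths = {len(rec.seq) for rec in block}
        if len(widths) != 1:
            raise MafParseError(
                f"{path}: block {block_idx}: inconsistent row lengths {sorted(widths)}"
            )
        first_sp, ref_chrom = _maf_taxon(block[0].id)
        if first_sp != reference_taxon:
            raise MafParseError(
                f"{path}: block {block_idx}: first sequence is {first_sp!r}, "
                f"expected reference taxon {reference_taxon!r}"
            )
        ann = block[0].annotations
        start = int(ann["start"])
        size = int(ann["size"])
        strand = ann.get("strand", 1)
        src_size = int(ann.get("srcSize", 0))
        rows: dict[str, str] = {}
        for rec in block:
            sp, _ = _maf_taxon(rec.id)
            rows[sp] = str(rec.seq).upper()
        if strand in (-1, "-"):
            # MAF minus-strand starts count from the reverse-complemented source
            start = src_size - start - size
            rows = {sp: reverse_complement(s) for sp, s in rows.items()}
        for sp, s in rows.items():
            try:
                encode_row(s)
            except ValueError as exc:
                raise MafParseError(
                    f"{path}: block {block_idx}: taxon {sp}: {exc}"
                ) from exc
        segments.append(
            MafSegment(
                ref_chrom=ref_chrom,
                ref_start=start,
                ref_size=size,
                n_columns=len(block[0].seq),
                rows=rows,
                reference_taxon=reference_taxon,
            )
        )
    return segments


def read_bed(path: str | Path) -> dict[str, GeneModel]:
    """Read a BED6 file of exon intervals into one GeneModel per name field."""
    path = Path(path)
    by_gene: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise BedValidationError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedValidationError(
                    f"{path}:{lineno}: start {start} >= end {end} for {name}"
                )
            if strand not in ("+", "-"):
                raise BedValidationError(f"{path}:{lineno}: bad strand {strand!r}")
            by_gene.setdefault(name, []).append(GenomicInterval(chrom, start, end, strand))
            strands.setdefault(name, set()).add(strand)

    models: dict[str, GeneModel] = {}
    for name, exons in by_gene.items():
        if len(strands[name]) != 1:
            raise BedValidationError(f"gene {name}: mixed strands {sorted(strands[name])}")
        models[name] = GeneModel(gene_id=name, exons=tuple(exons), strand=strands[name].pop())
    return models


def assemble_gene_alignment(
    segments: Iterable[MafSegment],
    gene_model: GeneModel,
    taxa: Sequence[str],
    strict: bool = False,
) -> GeneAlignment:
    """Stitch MAF segments into a per-gene coding alignment in transcription order.

    Exon sub-alignments are concatenated in genomic order; columns where the
    reference row carries a gap are dropped so reference genome positions map
    one-to-one onto output columns.  For minus-strand genes the concatenated
    alignment is then reverse-complemented, which both reverses exon order and
    complements every row.  Reference positions not covered by any segment are
    filled with ``N`` (all rows); with ``strict=True`` this is a hard error.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no MAF segments supplied")
    reference_taxon = segments[0].reference_taxon
    taxa = list(taxa)
    if reference_taxon not in taxa:
        taxa = [reference_taxon] + taxa

    length = gene_model.coding_length
    # genomic position -> coding index (genomic-order concatenation)
    offsets: list[tuple[int, int, int]] = []  # (exon_start, exon_end, cum_offset)
    cum = 0
    for exon in gene_model.exons:
        offsets.append((exon.start, exon.end, cum))
        cum += exon.length

    cols = {t: np.full(length, ord("N"), dtype=np.uint8) for t in taxa}
    covered = np.zeros(length, dtype=bool)

    for seg in segments:
        if seg.ref_chrom != gene_model.chrom:
            continue
        ref_row = seg.rows[reference_taxon]
        ref_codes = encode_row(ref_row)
        nongap = ref_codes != 5
        # genomic positions of the reference's ungapped columns in this segment
        positions = seg.ref_start + np.cumsum(nongap) - 1
        col_idx = np.flatnonzero(nongap)
        for exon_start, exon_end, off in offsets:
            mask = (positions[col_idx] >= exon_start) & (positions[col_idx] < exon_end)
            if not mask.any():
                continue
            use_cols = col_idx[mask]
            out_idx = positions[use_cols] - exon_start + off
            for t in taxa:
                row = seg.rows.get(t)
                if row is None:
                    continue
                row_bytes = np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)
                vals = row_bytes[use_cols]
                vals = np.where(vals == ord("-"), ord("N"), vals)  # ref is ungapped here
                cols[t][out_idx] = vals
            covered[out_idx] = True

    if not covered.all():
        n_missing = int((~covered).sum())
        msg = (
            f"gene {gene_model.gene_id}: {n_missing}/{length} reference coding "
            "positions have no MAF coverage"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; filled with N", stacklevel=2)

    rows = {t: cols[t].tobytes().decode("ascii") for t in taxa}
    if gene_model.strand == "-":
        rows = {t: reverse_complement(s) for t, s in rows.items()}
    return GeneAlignment(
        gene_id=gene_model.gene_id,
        taxa=tuple(taxa),
        rows=rows,
        reference_taxon=reference_taxon,
    )


def partition_blocks(gene_alignment: GeneAlignment, n_blocks: int) -> BlockSet:
    """Partition aligned coding columns into ``n_blocks`` contiguous blocks.

    Lengths are as equal as possible: the first ``n_columns mod n_blocks``
    blocks get the extra column.
    """
    n_cols = gene_alignment.n_columns
    if not (1 <= n_blocks <= n_cols):
        raise ValueError(
            f"n_blocks must be in [1, {n_cols}] for a {n_cols}-column alignment, "
            f"got {n_blocks}"
        )
    base, extra = divmod(n_cols, n_blocks)
    boundaries = []
    pos = 0
    for i in range(n_blocks):
        width = base + (1 if i < extra else 0)
        boundaries.append((pos, pos + width))
        pos += width
    return BlockSet(gene_id=gene_alignment.gene_id, boundaries=tuple(boundaries))


def extract_block(gene_alignment: GeneAlignment, block_interval: tuple[int, int]) -> GeneAlignment:
    """Restrict an alignment to the columns of one half-open block interval."""
    start, end = block_interval
    return gene_alignment.slice_columns(start, end)


def read_fasta_alignment(
    path: str | Path,
    gene_id: str | None = None,
    reference_taxon: str | None = None,
) -> GeneAlignment:
    """Read a per-gene multiple alignment from FASTA (taxa = record ids)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    taxa = tuple(rec.id for rec in records)
    rows = {rec.id: str(rec.seq).upper() for rec in records}
    return GeneAlignment(
        gene_id=gene_id or path.stem,
        taxa=taxa,
        rows=rows,
        reference_taxon=reference_taxon or taxa[0],
    )


def write_fasta_alignment(aln: GeneAlignment, path: str | Path) -> None:
    """Write a gene alignment to FASTA, taxa in stored order."""
    records = [
        SeqRecord(Seq(aln.rows[t]), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")
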