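"""Normalize per-block distance vectors against a reference rate signature.

The raw distance vector of any block is dominated by the shared phylogeny:
close species pairs are close in every block.  Dividing (or regressing) each
block's per-pair distance by a reference signature removes that shared
component, leaving block-specific rate variation — the quantity whose
correlation between two genes constitutes the covariation signal.

Two normalization modes are provided and kept explicitly distinct:

``ratio``
    r(pair) = d_block(pair) / d_ref(pair).  The literal reading of a
    "relative distance"; the default.

``residual``
    r(pair) = d_block(pair) - beta * d_ref(pair), with beta the
    least-squares slope through the origin over the block's present pairs.
    Through-origin because two identical sequences (reference distance 0)
    must have expected block distance 0.

The default reference is the distance signature of the column-wise
concatenation of all analyzed gene alignments — a download-free surrogate
for a genome-wide average rate per species pair; a user-supplied alignment
may stand in for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment_io import GeneAlignment
from .distances import PairDistanceTable, SpeciesPair, block_distance_table

__all__ = [
    "ReferenceSignature",
    "RelativeRateTable",
    "build_reference",
    "relative_rate_table",
    "concatenate_alignments",
    "relrate_tables_to_tsv",
    "relrate_tables_from_tsv",
    "MODES",
]

MODES = ("ratio", "residual")


@dataclass(frozen=True)
class ReferenceSignature:
    """Per-pair reference distances (> 0) used as the normalizer."""

    entries: dict[SpeciesPair, float]
    source: str = "concatenation-of-all-blocks"

    def __post_init__(self) -> None:
        bad = {p: d for p, d in self.entries.items() if not d > 0}
        if bad:
            raise ValueError(f"reference distances must be > 0; offending pairs: {sorted(bad)}")


@dataclass
class RelativeRateTable:
    """Per-pair relative rates for one block (missing entries are ``None``)."""

    gene_id: str
    block_index: int
    mode: str
    entries: dict[SpeciesPair, float | None]
    reference_source: str = "concatenation-of-all-blocks"

    def present(self) -> dict[SpeciesPair, float]:
        return {p: v for p, v in self.entries.items() if v is not None}

    def n_missing(self) -> int:
        return sum(1 for v in self.entries.values() if v is None)


def concatenate_alignments(gene_alignments: Sequence[GeneAlignment]) -> GeneAlignment:
    """Column-wise concatenation over the union of taxa; absent rows fill with N."""
    if not gene_alignments:
        raise ValueError("no alignments to concatenate")
    taxa: list[str] = []
    for aln in gene_alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    for aln in gene_alignments:
        n = aln.n_columns
        for t in taxa:
            rows[t].append(aln.rows.get(t, "N" * n))
    ref = gene_alignments[0].reference_taxon
    return GeneAlignment(
        gene_id="+".join(a.gene_id for a in gene_alignments),
        taxa=tuple(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        reference_taxon=ref if ref in taxa else taxa[0],
    )


def build_reference(
    gene_alignments: Sequence[GeneAlignment],
    model: str = "k80",
    min_sites: int = 30,
) -> ReferenceSignature:
    """Distance signature of the concatenation of all analyzed gene alignments.

    Pairs whose concatenated distance is missing or zero are excluded from
    the signature; blocks normalized against it report those pairs missing.
    """
    concat = concatenate_alignments(gene_alignments)
    table = block_distance_table(concat, model=model, min_sites=min_sites)
    entries = {
        pair: d for pair, (d, _) in table.entries.items() if d is not None and d > 0
    }
    if not entries:
        raise ValueError("reference signature is empty: all pairs missing or zero")
    return ReferenceSignature(entries=entries)


def _origin_slope(pairs: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope through the origin for (x, y) = (reference, block)."""
    sxy = sum(x * y for x, y in pairs)
    sxx = sum(x * x for x, _ in pairs)
    return sxy / sxx


def relative_rate_table(
    pair_distance_table: PairDistanceTable,
    reference: ReferenceSignature,
    mode: str = "ratio",
) -> RelativeRateTable:
    """Transform one block's distances into relative rates against a reference.

    Missingness propagates: an entry is missing when the block distance is
    missing or the reference lacks (or excluded) the pair.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    entries: dict[SpeciesPair, float | None] = {}
    paired: list[tuple[float, float]] = []
    for pair, (d, _) in pair_distance_table.entries.items():
        ref = reference.entries.get(pair)
        if d is None or ref is None:
            entries[pair] = None
        else:
            entries[pair] = d / ref if mode == "ratio" else d  # residual filled below
            paired.append((ref, d))
    if mode == "residual":
        if paired:
            beta = _origin_slope(paired)
            for pair in entries:
                if entries[pair] is not None:
                    entries[pair] = (
                        pair_distance_table.entries[pair][0]
                        - beta * reference.entries[pair]
                    )
    return RelativeRateTable(
        gene_id=pair_distance_table.gene_id,
        block_index=pair_distance_table.block_index,
        mode=mode,
        entries=entries,
        reference_source=reference.source,
    )


def relrate_tables_to_tsv(tables: Iterable[RelativeRateTable], path: str | Path) -> None:
    """TSV export: gene, block, species_a, species_b, rate, mode, reference."""
    rows = []
    for tab in tables:
        for pair, v in sorted(tab.entries.items()):
            rows.append(
                {
                    "gene": tab.gene_id,
                    "block": tab.block_index,
                    "species_a": pair.a,
                    "species_b": pair.b,
                    "rate": "" if v is None else format(v, ".10g"),
                    "mode": tab.mode,
                    "reference": tab.reference_source,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def relrate_tables_from_tsv(path: str | Path) -> list[RelativeRateTable]:
    """Inverse of :func:`relrate_tables_to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"rate": str})
    tables: list[RelativeRateTable] = []
    for (gene, block, mode, ref), grp in df.groupby(
        ["gene", "block", "mode", "reference"], sort=True
    ):
        entries: dict[SpeciesPair, float | None] = {}
        for row in grp.itertuples():
            v = None if pd.isna(row.rate) or row.rate == "" else float(row.rate)
            entries[SpeciesPair(row.species_a, row.species_b)] = v
        tables.append(
            RelativeRateTable(
                gene_id=str(gene),
                block_index=int(block),
                mode=str(mode),
                entries=entries,
                reference_source=str(ref),
            )
        )
    tables.sort(key=lambda t: (t.gene_id, t.block_index))
    return tables
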