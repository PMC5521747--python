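"""End-to-end ERC runs: inputs -> blocks -> distances -> relative rates ->
covariation matrix -> peak, with every stage written to disk.

A run is driven by a single :class:`RunConfig` (YAML/JSON-serializable);
identical config + inputs reproduce byte-identical TSV/JSON outputs, which
is asserted in the test suite.  Floats are printed with 10 significant
digits for cross-platform byte stability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment_io import (
    GeneAlignment,
    assemble_gene_alignment,
    extract_block,
    partition_blocks,
    read_bed,
    read_fasta_alignment,
    read_maf,
    write_fasta_alignment,
)
from .covariation import (
    CovariationMatrix,
    PeakRegion,
    covariation_matrix,
    find_peak,
    matrix_to_tsv,
    peak_to_json,
    plot_heatmap,
)
from .distances import MODELS, block_distance_table, distance_tables_to_tsv
from .relative_rates import (
    MODES,
    build_reference,
    relative_rate_table,
    relrate_tables_to_tsv,
)
from .synthetic_data import RateModel, simulate_gene_pair, write_truth

__all__ = ["GeneInput", "SimulateSpec", "RunConfig", "RunResult", "validate_config", "run_pipeline"]

log = logging.getLogger("ercov")


@dataclass
class GeneInput:
    """Where one gene's alignment comes from: a FASTA, or a MAF + BED pair."""

    gene_id: str
    n_blocks: int
    fasta: str | None = None
    maf: str | None = None
    bed: str | None = None
    reference_taxon: str | None = None


@dataclass
class SimulateSpec:
    """Parameters for a simulate-then-analyze run (no external inputs)."""

    block_lengths_a: list[int] = field(default_factory=lambda: [600] * 4)
    block_lengths_b: list[int] = field(default_factory=lambda: [300] * 30)
    sigma_shared: float = 0.6
    tau_private: float = 0.1
    coevolving_pairs: list[list[int]] = field(default_factory=list)
    kappa: float = 2.0
    newick: str | None = None  # None -> packaged 12-taxon fixture tree


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    out_dir: str
    gene_a: GeneInput | None = None
    gene_b: GeneInput | None = None
    simulate: SimulateSpec | None = None
    taxa: list[str] | None = None
    model: str = "k80"
    min_sites: int = 30
    min_pairs: int = 8
    mode: str = "ratio"
    reference: str = "concat"  # "concat" or path to a FASTA alignment
    peak_threshold: float = 0.8
    seed: int = 0
    heatmap: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("gene_a", "gene_b"):
            if d.get(key) is not None and not isinstance(d[key], GeneInput):
                d[key] = GeneInput(**d[key])
        if d.get("simulate") is not None and not isinstance(d["simulate"], SimulateSpec):
            d["simulate"] = SimulateSpec(**d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Check every config invariant; returns violations (empty list = ok)."""
    v: list[str] = []
    if config.simulate is None:
        for name, gi in (("gene_a", config.gene_a), ("gene_b", config.gene_b)):
            if gi is None:
                v.append(f"{name}: required unless 'simulate' is set")
                continue
            if gi.n_blocks < 1:
                v.append(f"{name}.n_blocks: must be >= 1, got {gi.n_blocks}")
            if gi.fasta is None and (gi.maf is None or gi.bed is None):
                v.append(f"{name}: need either 'fasta' or both 'maf' and 'bed'")
            if gi.maf is not None and gi.reference_taxon is None:
                v.append(f"{name}.reference_taxon: required for MAF input")
    else:
        sim = config.simulate
        if any(x < 1 for x in sim.block_lengths_a + sim.block_lengths_b):
            v.append("simulate.block_lengths: all must be >= 1")
        if sim.sigma_shared < 0 or sim.tau_private < 0:
            v.append("simulate.sigma_shared/tau_private: must be >= 0")
        for pair in sim.coevolving_pairs:
            if len(pair) != 2:
                v.append(f"simulate.coevolving_pairs: {pair} is not a pair")
            elif not (
                0 <= pair[0] < len(sim.block_lengths_a)
                and 0 <= pair[1] < len(sim.block_lengths_b)
            ):
                v.append(f"simulate.coevolving_pairs: {pair} out of block range")
    if config.model not in MODELS:
        v.append(f"model: unknown {config.model!r}, choose from {MODELS}")
    if config.mode not in MODES:
        v.append(f"mode: unknown {config.mode!r}, choose from {MODES}")
    if config.min_sites < 1:
        v.append(f"min_sites: must be >= 1, got {config.min_sites}")
    if config.min_pairs < 2:
        v.append(f"min_pairs: must be >= 2, got {config.min_pairs}")
    if not (-1.0 <= config.peak_threshold <= 1.5):
        v.append(f"peak_threshold: {config.peak_threshold} outside sensible range")
    if config.seed < 0:
        v.append(f"seed: must be >= 0, got {config.seed}")
    return v


@dataclass
class RunResult:
    """Objects and file paths produced by one pipeline run."""

    matrix: CovariationMatrix
    peak: PeakRegion
    out_dir: Path
    files: dict[str, Path]


def _load_gene(gi: GeneInput, taxa: list[str] | None) -> GeneAlignment:
    if gi.fasta is not None:
        aln = read_fasta_alignment(gi.fasta, gene_id=gi.gene_id, reference_taxon=gi.reference_taxon)
    else:
        segments = read_maf(gi.maf, gi.reference_taxon)
        models = read_bed(gi.bed)
        if gi.gene_id not in models:
            raise ValueError(f"gene {gi.gene_id!r} not found in {gi.bed}")
        aln = assemble_gene_alignment(
            segments, models[gi.gene_id], taxa or [gi.reference_taxon]
        )
    return aln


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full block-covariation analysis described by ``config``.

    Writes per-stage TSVs, the score matrix, a peak JSON, the resolved config
    and a log file into ``config.out_dir`` and returns the in-memory results.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    log.info("run %s starting (ercov %s)", _config_hash(config), __version__)

    # --- stage: obtain gene alignments -------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        rate_model = RateModel(
            sigma_shared=sim.sigma_shared,
            tau_private=sim.tau_private,
            coevolving_pairs=tuple(tuple(p) for p in sim.coevolving_pairs),
            kappa=sim.kappa,
            base_model="k80" if config.model == "k80" else "jc69",
        )
        kwargs = {} if sim.newick is None else {"newick": sim.newick}
        aln_a, aln_b, truth = simulate_gene_pair(
            rate_model, sim.block_lengths_a, sim.block_lengths_b, config.seed, **kwargs
        )
        n_blocks_a = len(sim.block_lengths_a)
        n_blocks_b = len(sim.block_lengths_b)
        for aln, tag in ((aln_a, "geneA"), (aln_b, "geneB")):
            files[f"fasta_{tag}"] = out / f"{tag}.fasta"
            write_fasta_alignment(aln, files[f"fasta_{tag}"])
        files["truth"] = out / "truth.json"
        write_truth(truth, files["truth"])
        log.info("simulated %s (%d cols) and %s (%d cols), %d planted pair(s)",
                 aln_a.gene_id, aln_a.n_columns, aln_b.gene_id, aln_b.n_columns,
                 len(rate_model.coevolving_pairs))
    else:
        aln_a = _load_gene(config.gene_a, config.taxa)
        aln_b = _load_gene(config.gene_b, config.taxa)
        n_blocks_a = config.gene_a.n_blocks
        n_blocks_b = config.gene_b.n_blocks
        log.info("loaded %s (%d cols) and %s (%d cols)",
                 aln_a.gene_id, aln_a.n_columns, aln_b.gene_id, aln_b.n_columns)

    # --- stage: blocks and distances ---------------------------------------
    tables = {}
    for aln, n_blocks in ((aln_a, n_blocks_a), (aln_b, n_blocks_b)):
        blocks = partition_blocks(aln, n_blocks)
        tabs = [
            block_distance_table(
                extract_block(aln, iv),
                model=config.model,
                min_sites=config.min_sites,
                block_index=i,
            )
            for i, iv in enumerate(blocks.boundaries)
        ]
        tables[aln.gene_id] = tabs
        n_missing = sum(t.n_missing() for t in tabs)
        log.info("distances %s: %d blocks, %d missing entries", aln.gene_id, n_blocks, n_missing)
    files["distances"] = out / "distances.tsv"
    distance_tables_to_tsv(tables[aln_a.gene_id] + tables[aln_b.gene_id], files["distances"])

    # --- stage: reference + relative rates ----------------------------------
    if config.reference == "concat":
        reference = build_reference([aln_a, aln_b], model=config.model, min_sites=config.min_sites)
    else:
        ref_aln = read_fasta_alignment(config.reference)
        reference = build_reference([ref_aln], model=config.model, min_sites=config.min_sites)
        reference = type(reference)(entries=reference.entries, source=str(config.reference))
    relrates = {
        gid: [relative_rate_table(t, reference, mode=config.mode) for t in tabs]
        for gid, tabs in tables.items()
    }
    files["relrates"] = out / "relative_rates.tsv"
    relrate_tables_to_tsv(
        relrates[aln_a.gene_id] + relrates[aln_b.gene_id], files["relrates"]
    )
    for gid, tabs in relrates.items():
        log.info("relative rates %s: %d missing entries", gid, sum(t.n_missing() for t in tabs))

    # --- stage: covariation + peak ------------------------------------------
    matrix = covariation_matrix(
        relrates[aln_a.gene_id], relrates[aln_b.gene_id], min_pairs=config.min_pairs
    )
    peak = find_peak(matrix, peak_threshold=config.peak_threshold)
    files["matrix"] = out / "covariation_matrix.tsv"
    matrix_to_tsv(matrix, files["matrix"])
    files["peak"] = out / "peak.json"
    peak_to_json(peak, files["peak"])
    if config.heatmap:
        files["heatmap"] = out / "covariation_heatmap.png"
        plot_heatmap(matrix, files["heatmap"])
    files["config"] = out / "config.yaml"
    config.to_yaml(files["config"])
    log.info(
        "matrix %dx%d, %d present scores; peak cell %s score %.4f",
        *matrix.shape, int(matrix.present_mask().sum()), peak.cell, peak.score,
    )

    run_log = out / "run.log"
    with open(run_log, "w") as fh:
        fh.write(f"ercov {__version__}\nconfig_hash {_config_hash(config)}\n")
        fh.write(f"matrix_shape {matrix.shape[0]}x{matrix.shape[1]}\n")
        fh.write(f"present_scores {int(matrix.present_mask().sum())}\n")
        fh.write(f"peak_cell {peak.cell[0]},{peak.cell[1]}\n")
        fh.write(f"peak_score {peak.score:.10g}\n")
    files["log"] = run_log
    return RunResult(matrix=matrix, peak=peak, out_dir=out, files=files)
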