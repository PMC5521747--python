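# Methods

## The model and its assumptions

`ercov` treats coevolution between two gene regions as correlated variation
in their evolutionary rates across a shared phylogeny. The observable is,
per alignment block, the vector of pairwise evolutionary distances indexed
by unordered species pairs (66 entries for 12 taxa). Because all blocks
evolve on the same tree, raw distance vectors of any two blocks are highly
correlated regardless of function; the analysis therefore works on
*relative* rates — each block's distances normalized by a reference
signature — and interprets a high Pearson correlation between the relative
rate vectors of a block of gene A and a block of gene B as evidence that
the two regions accelerated and decelerated together.

Assumptions worth keeping in mind:

- Distances are nucleotide-level and model-corrected (JC69/K80); no codon
  structure, selection, or rate heterogeneity across sites within a block.
- Blocks are contiguous, equal-length column windows. They may split
  codons and domain boundaries; block resolution, not domain annotation,
  drives localization.
- Species-pair vectors are not independent observations: pairs share tree
  paths, so the effective degrees of freedom behind a 66-entry correlation
  are far fewer than 66. Scores are descriptive; no p-values are attached,
  and the pipeline reports the peak, not significance.

## Pipeline stages and numerical choices

**Alignment assembly** (MAF + BED route). BED is 0-based half-open; MAF
minus-strand reference rows are converted to forward coordinates
(`start' = srcSize − start − size`, rows reverse-complemented) on read.
Exon sub-alignments are concatenated in genomic order and, for minus-strand
genes, the concatenation is reverse-complemented, which yields
transcription order. Columns where the reference row has a gap are dropped,
so reference genome coordinates index alignment columns 1:1 and block
boundaries are reproducible from the BED alone. Uncovered reference spans
and absent taxa are filled with `N` (a warning by default, an error in
strict mode).

**Blocks.** `n_columns mod n_blocks` leading blocks get the extra column;
every block has ≥ 1 column. Equal-length contiguous partitioning is the
only policy offered: it is the minimal assumption when only block *counts*
are specified.

**Distances.** A site enters a pair's tally only when both rows have an
unambiguous base (pairwise deletion). Transitions are A↔G and C↔T.
Estimators: p (raw proportion), JC69 (d = −¾ ln(1 − 4p/3)), K80
(d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)). K80 is the default because the
standard distance tool in this literature defaults to it. Saturation
(p ≥ ¾ for JC69; non-positive log arguments for K80) and entries with
fewer than `min_sites` comparable sites (default 30) are *missing* —
clamping saturated estimates to a constant would manufacture correlation
across blocks. Missing entries propagate and never decrease through the
pipeline.

**Reference signature.** Default: distances of the column-wise
concatenation of both analyzed genes' alignments — a download-free
surrogate for a genome-wide average rate per species pair. A user-supplied
alignment can replace it. Pairs with missing or zero concatenation distance
are excluded (division guard); blocks then report those pairs missing.

**Relative rates.** Ratio mode (default): r = d_block / d_ref, the literal
"relative distance"; scale-equivariant. Residual mode: r = d_block −
β̂·d_ref with β̂ the least-squares slope *through the origin* over the
block's present pairs — through the origin because identical sequences
(zero reference distance) must imply zero expected block distance; the
slope absorbs any global rescaling of the reference. Both modes are
first-class so the normalization choice is auditable; mixing modes or
references between the two genes is a configuration error.

**Covariation and peak.** Pearson r over pairwise-complete species-pair
keys, via `scipy.stats.pearsonr`, requiring `min_pairs` (default 8 of 66)
joint entries; constant vectors give a missing score, not 0. The peak is
the argmax over present scores with lexicographic (row-major) tie-breaking,
plus all cells at or above `peak_threshold` (default 0.8 — a reporting
convenience, not an inferred quantity; the peak cell is reported
regardless). Output floats are printed with 10 significant digits so
reruns are byte-identical.

## The synthetic-data generator

The simulator stands in for the multi-species whole-genome alignments the
analysis normally consumes. It emulates: 12 taxa on a fixed balanced tree
(four clades of three; branch lengths 0.05–0.16 substitutions/site, within
[0.02, 0.3]); two genes partitioned into blocks (defaults 4 × 600 nt and
30 × 300 nt — the original 4 × 250-block geometry at reduced column count
so a full study runs in seconds); and block-specific rate variation with a
planted correlation structure.

Rates: on branch e, a coevolving group shares u_e ~ N(0, σ²_shared), and
each member block multiplies its branch length by exp(u_e + ε),
ε ~ N(0, τ²_private); every other block uses an independent
exp(v), v ~ N(0, σ²_shared + τ²_private). All blocks thus share one
marginal multiplier distribution — only the planted pair is correlated,
with log-rate correlation σ²/(σ² + τ²) (≈ 0.97 at the defaults σ = 0.6,
τ = 0.1, a strong but not degenerate signal). Sequences evolve
site-independently under the exact JC69/K80 transition probabilities (root
uniform on {A,C,G,T}); one integer seed drives all randomness, and
replicate k of a batch uses seed base + k.

What the generator does *not* emulate: indels and alignment error, missing
taxa/coverage gaps (gap handling is tested on hand-built fixtures instead),
codon structure, among-site rate variation, GC bias, and linkage between
adjacent blocks. Passing recovery tests therefore demonstrate that the
pipeline detects correlated rate variation when it exists and is correctly
plumbed end to end — not that real MultiZ alignments are free of the
artifacts listed above.

## Problem sizes and observed behavior

The validation geometry is 4 × 600 nt vs 30 × 300 nt on the 12-taxon tree
(11,400 columns total per replicate); a batch of 20 replicates runs in a
few seconds. At the default signal (σ_shared = 0.6, τ_private = 0.1, ratio
mode, K80) the peak cell recovers the planted pair in roughly 9 of 10
replicates, and with no planted pair the mean absolute score of the
4 × 30 matrix stays near 0.22 — nonzero because species pairs share tree
paths. The acceptance script also runs one 4 × 250-block design
(70 nt blocks) to exercise the original study's matrix shape; at that
block length individual scores are noisy, which is why the headline
recovery uses 300 nt blocks.

## Design choices where the design was open

- **Topology of the fixture tree**: balanced. Ladder-like topologies
  maximize shared path segments between species pairs, inflating the
  correlation between unrelated blocks' rate vectors; a balanced tree is
  both the stated design and the friendlier geometry for pairwise methods.
- **Reference from concatenation** rather than a genome-wide alignment:
  keeps the pipeline self-contained; the reference source is recorded in
  every relative-rate table and both options are exposed.
- **UTR trimming**: BED intervals are taken as given; no CDS-trimming
  heuristics.
- **Dropped-taxa policy**: none beyond per-entry `min_sites`; poor-coverage
  taxa surface as missing pairs, which `min_pairs` then gates.

## Known limitations

- No statistical calibration (permutation/FDR) of scores; the output is a
  ranked map, and thresholds are descriptive.
- Pairwise distances, not branch-specific rates: tree-aware projections
  would use the phylogeny more efficiently but are out of scope.
- K80 saturation on deep pairs under strong rate multipliers produces
  missing entries; with very short blocks this can thin the matrix.
- The MAF reader loads segments into memory; it is meant for per-gene
  extracts, not whole-genome MAF files.
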