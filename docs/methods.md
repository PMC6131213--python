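# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the simulator does and does not emulate, and the known limits.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. GFF3 is written 1-based
inclusive and BED 0-based half-open, per the format standards. Gene "rank"
is the 0-based index of a gene on its chromosome ordered by start; all
gene-distance rules operate on ranks, strand-agnostic, matching the MCScan
convention.

## Synthetic genomes

The simulator's default preset emulates a seven-chromosome, repeat-rich
rosid genome at desk scale. Real chromosomes of this kind are tens of
megabases; we use 1 Mb chromosomes so that a full pipeline run takes seconds
while preserving every structural relationship the analyses exploit. The
scaled-down knobs and their rationale:

| parameter | default | rationale |
|---|---|---|
| `n_chromosomes` | 7 | haploid count of the emulated genome |
| `chrom_length` | 1 Mb | desk-scale stand-in for ~40 Mb chromosomes |
| `telomere_motif`, copies | `TTTAGGG` × 40 | Arabidopsis-type plant telomere; track length ≈ 280 bp |
| `centromere_monomer_length` | 317 bp | the centromeric satellite unit length being modeled |
| `centromere_copy_range` | 110–320 | the low end of observed copy numbers (110–1,204), so arrays occupy a realistic fraction of a 1 Mb chromosome |
| `monomer_divergence` | 0.11 | produces ≈89% element-vs-consensus identity |
| `ltr_field_density` | 0.9 | pericentromeric LTR fields clear the 0.85 calling threshold with realistic margin |
| `pericentromere_length` | 100 kb per side | defines the centromeric domain with the array |
| `n_genes_per_chrom` | 60 | enough ranks for arm-sized inversions and 26-member arrays |
| `tandem_array_spec` | 26, 12, 8, 5, 3, 2 members at 5% divergence | spans the observed 2–26 copy range |

The preset plants telomere tracks at both ends of chromosomes 2, 3, 5 and 7
and one end of 1 and 4 (ten tracks), and leaves chromosome 6 acentric with
four stray monomers — the configuration the analyses must reproduce,
including the honest no-call.

Background sequence is i.i.d. uniform ACGT: the simplest null for
homology-based detection, deliberately free of the low-complexity and
compositional structure of real DNA. Mutations are substitutions only (no
indels), so planted elements stay in phase; the scanners nevertheless use
edit-distance alignment and do not rely on this. `TruthSet.centromeres`
records the full planted centromeric *domain* (satellite array plus both
pericentromeric fields) — the object the caller estimates — while
`TruthSet.centromere_arrays` records the satellite array proper, the object
the array scanner recovers.

The degraded ("V1-like") derivative excises whole gene bodies plus
intergenic spacers from collapsed tandem arrays, shifting downstream
coordinates left, which mimics short-read assembly collapse. Inversions are
gene-bounded segments that avoid planted tracks and excision junctions;
bounded resampling (100 tries per inversion) raises an error when placement
is impossible. The ortholog genome preserves gene order per chromosome,
mutates gene sequences at a configurable substitution rate (default 0.1,
roughly two diverged rosid relatives), applies per-family array expansions
or contractions, and reverses arm-sized gene runs for inversions. Inversion
runs cover just over half a chromosome's genes: smaller runs can be bridged
by a collinear chain stepping across the inversion's corner anchors within
the default rank-gap cap, which would misattribute the planted structure.
Inversions are placed starting from the last chromosome because the first
chromosomes carry the largest tandem arrays, whose near-identical members
make anchor order inherently ambiguous.

Hi-C contacts decay as `scale·(1+d)^(−α)` with `d` the bin distance
(α = 1 by default, the standard intra-chromosomal decay), multiplied by a
depression factor (default 0.3) for bin pairs touching the centromeric
domain. Noise is gamma-Poisson (negative binomial) with inverse-size
`noise_dispersion`; zero disables noise. Matrices are symmetric integer
counts.

Expression counts are negative binomial around FPKM-implied means with
gene lengths from the annotation and a 20 M-fragment library: large enough
that the FPKM = 1 boundary sits at ~40 counts for a 2 kb gene, so planted
relationships survive count noise. Planted tissue-specific genes target
FPKM 5–50 in one tissue and 0.05 elsewhere; broadly expressed genes draw a
base level of 3–100 FPKM with ±30% tissue variation; silent genes sit at
0.02 FPKM.

What passing recovery tests does **not** show about real data: the
simulator has no indels, no nested or truncated repeats, no segmental
duplication beyond what is planted, no GC or mappability structure, and
telomere/centromere sequence evolves only by point substitution. Recovery
rates here are upper bounds for real assemblies.

## Assembly statistics and telomeres

`nX` walks lengths longest-first and returns the length crossing the
fraction boundary; an exact half-total boundary returns the crossing length
(standard N50 convention). Telomere search uses exact Hamming matching of
motif-length frames (the allowed per-copy mismatch count is
`floor(max_divergence × motif length)`, zero for the 7-mer default), chains
frames at motif-length spacing, and reports the longest run per end over
both strands. Defaults — `min_copies` 10, `terminal_window` 10 kb,
`max_divergence` 0.1 — are conservative and configurable; windows longer
than the chromosome are clipped with a warning.

## Repeat landscape

Monomer discovery counts k-mer recurrence distances (k = 13) in
`[min_period, max_period]`; a period needs `min_support` = 10 votes, far
above the random expectation at desk scale (< 1 vote for 10 kb of random
sequence). The consensus is phased from the first voting position, so it is
exact on a sequence that begins at a monomer boundary and a cyclic rotation
of the planted monomer otherwise — rotation does not affect downstream
scanning. Array scanning strides one monomer length, aligns the monomer in
infix mode (edlib) within each window, merges matches separated by
≤ `max_gap` (default 2 monomers), then phases each region into consecutive
monomer-length frames anchored at the best first match, counting frames with
identity ≥ `min_identity` (default 70%). Identity is element-vs-consensus by
default; the all-pairs reading of "element homology" is available as
`pairwise_mean_identity`. Windowed densities use 50 kb windows on a 25 kb
step; the last window is truncated, values are coverage fractions of the
interval union.

## Centromere calling

The relative interaction statistic is the diagonal-excluded row sum,
smoothed by a centered running mean (3 bins) and divided by the chromosome
median — scale-free by construction. Candidate depression regions are
contiguous runs below `depression_threshold` = 0.6 containing the global
minimum; the default separates planted depression factors of 0.2–0.5 from
noise with margin. The call seed is the union of repeat arrays overlapping
the depression region; when the two disagree, repeat arrays win and the
seed is the largest array. Borders extend outward over LTR-density windows
lying fully outside the current interval (so the LTR-free satellite array
itself never dilutes a border window), while density exceeds
`ltr_threshold` = 0.85, tolerating one sub-threshold window. A call requires
array evidence, or both LTR and Hi-C evidence; otherwise `no_call`.
Raising `ltr_threshold` can only shrink calls; scaling the contact matrix
leaves them unchanged.

## Homology and tandem arrays

The reference aligner is Smith–Waterman with affine gaps via
`Bio.Align.PairwiseAligner` (match +1, mismatch −2, gap open 5, extend 2, a
length-`L` gap costing `5 + 2L`). Bit scores use the ungapped Karlin–Altschul
lambda solved numerically for the scoring scheme and K = 0.46 (the published
gapped value for these parameters); e-values are `K·m·n·2^(−bits)` with `n`
the database length. For all-vs-all scans a fast path is used: a strided
11-mer fingerprint prefilter (either orientation), a banded edit-distance
cutoff at 50% identity, then the best-scoring contiguous segment (Kadane)
of the global edit alignment under the same scoring — a lower bound on the
Smith–Waterman score that is tight for high-identity pairs, which are the
only pairs that survive the prefilters. Gene sequences are extracted in
transcript orientation and both orientations are compared, so opposite-strand
duplicates are found.

Tandem arrays are connected components (union-find) over qualifying pairs
(e-value ≤ 1e-5, rank distance ≤ 10); single linkage is transitive, so two
genes 11 ranks apart join the same array through an intermediate member.
Cross-assembly comparison matches each new array to the old array sharing
the most mapped members (ties by chromosome and leftmost member); gene-level
Venn counts and per-class mean percent gains (`size_class_gain`, classes on
the new size) are reported, with an empty class returned as None, never 0.

## Synteny

Anchors keep the top-k hits per query *and* per subject (k = 1 gives a
partial matching). Chaining is an `O(n²)` DP per chromosome pair, strictly
monotone in both genomes (increasing for forward, decreasing for inverted),
rank gaps ≤ 25 on both sides, scoring +1 per anchor minus 0.01 per rank-gap
unit (anchor count dominates; the penalty only breaks ties toward compact
chains). Overlapping chains are resolved greedily by score with anchors of
accepted chains removed — deterministic, forward preferred on exact ties.
Depth is reported with both denominators (percent of blocks and percent of
block-covered bases) since either reading of "1:1 fraction" is defensible.
Array conservation follows anchors: an array is conserved when a member's
anchored partner belongs to an array in the other genome; lineage-specific
arrays with more than 10 copies whose partners collapse onto ≤ 1 gene are
tallied as large-vs-single-copy events.

## Expression

FPKM uses fragment counts; library sizes default to column sums but can be
fixed externally. The tissue-specific filter uses strict inequalities on
both sides (a tissue at exactly FPKM 1 disqualifies); `inclusive_low`
relaxes the lower comparison to ≤ for sensitivity analyses. The heatmap
matrix is `log2(FPKM + 1)` (pseudocount 1 keeps zeros at 0), rows ordered by
maximum expression, with a top-N slice for the highest-expression view.

## Problem sizes

The default test and acceptance runs use the 7 × 1 Mb preset (60 genes per
chromosome, ≈420 genes per genome), three simulation seeds for sequence-level
centromere recovery plus 50 randomized caller-level layouts, 500 random
instances for the clustering oracle, 200 for the chaining oracle, 1,000 for
the nX oracle, and a 9,301-gene atlas for the detectability count. These
sizes were chosen so the full suite completes in well under a minute of CPU
while every statistic is measured rather than assumed.

## Known limitations

- The centromere caller reports one interval per chromosome; split or
  dicentric signals collapse to the strongest candidate region.
- The fast homology path underestimates Smith–Waterman scores for pairs
  with identity near the prefilter boundary; such pairs are far below the
  e-value threshold either way, but borderline biology (very old
  duplications) should use `pairwise_homology` or an external hit table.
- Monomer discovery assumes the satellite is the dominant periodicity in
  the scanned window; mixed satellite families report the strongest only.
- Depth classification counts block-span overlaps; anchors are not
  re-assigned, so a truly duplicated region inside an otherwise 1:1 block is
  attributed to the whole block.
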