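# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Coordinates and overlap semantics

All intervals are BED-convention: 0-based, half-open `[start, end)`,
strandless for peaks. Two intervals *overlap* iff they share at least one
base; touching intervals (`[a,b)` and `[b,c)`) do **not** overlap but are
fused by `merge`, which smooths bookkeeping without inventing shared
bases. Duplicate identical peaks are collapsed on input (with a warning)
so sharing fractions never double-count a site.

Two accountings of three-set overlap are provided, because published
Venn/percentage figures rarely state which they used: *region-level*
(merge the union of all three sets, label each merged region by which
inputs contribute ≥ 1 bp) and *directed peak-level sharing*
(fraction of A's peaks overlapping ≥ 1 peak of B; asymmetric when set
sizes differ). On the synthetic data, where shared peaks are
coordinate-identical, both agree with the planted truth exactly.

## Feature annotation

A binding site receives exactly one label, decided by its **midpoint**
(`(start+end)//2`). The promoter is the 500 bp immediately upstream of
the TSS, strand-aware and upstream-only: `[TSS-500, TSS)` on the plus
strand, `[TSS+1, TSS+501)` on the minus strand. Labels are resolved with
priority promoter > exon > intron across all genes of the chromosome;
everything else is intergenic. Midpoint classification was chosen over
any-overlap because it yields mutually exclusive labels (fractions sum
to 1) matching a single-label-per-site accounting; the promoter-first
priority reflects the promoter being the category of interest in
promoter-vs-distal comparisons. Peaks on chromosomes absent from the
catalog are intergenic with a warning rather than an error, since real
catalogs routinely lack scaffolds.

Target genes are assigned by the nearest TSS within ±25 kb of the peak
midpoint (boundary inclusive), ties broken by lexicographically smaller
gene id. TSS distance (not gene-body edge) is used because the TSS is
the regulatory anchor of the promoter definition; the signed distance is
negative upstream of the TSS relative to gene strand.

## Tag densities

Tags are single genomic positions; strand is carried through I/O but
ignored by counting, and no fragment extension is applied. The
normalization is

    density(region) = (count / region_length_kb) / library_total × 100

i.e. a 1 kb-equivalent count as a percent of the library. This makes
library sizes comparable and gives an exact conservation law — any
exhaustive, disjoint 1 kb tiling of the genome sums to 100% — used as a
test invariant. Density matrices use ±5 kb around the peak midpoint in
100 bins by default (typical display scale; both configurable; per-library
normalization, with descending row-sum ordering only applied for heatmap
export). Coverage tracks average per-bp tag counts over consecutive
non-overlapping 10 bp windows; a trailing partial window uses its actual
span so total mass equals the library total exactly.

## Motif scanning

PWMs are per-position base probabilities with a pseudocount (default
0.01) mixed in and rows renormalized, so log-odds are finite; background
defaults to uniform 0.25. Windows are scored in log₂ odds; `N` bases
contribute 0 bits. The hit threshold is a *fraction of the matrix's
maximum achievable score* (default 0.9), which self-calibrates across
matrices of different lengths and information content without per-matrix
tuning. The minus strand is scored on the reverse complement, with
offsets reported on the forward sequence. The bundled RUNX1/SPI1/GATA1/
TAL1/CEBPA matrices are **synthetic** consensus-style matrices (dominant
base 0.85) built from each factor's canonical core sequence; they are
stand-ins for empirically derived matrices, which can be substituted via
JASPAR-format files. Absolute percent-with-motif values therefore
characterize the synthetic benchmark, not any particular cell line.

## Expression comparison

Matrices are genes × samples on the linear scale; the scale is declared
in a `#scale=` header and log2 input is exponentiated on load, so "fold
change" is always a ratio of linear means. The group comparison behind a
significance flag is a two-sided Wilcoxon signed-rank test pairing each
gene's group mean with its reference-group (CD34⁺) mean, α = 0.05; a
paired nonparametric test is robust to the heavy-tailed baseline and to
the strong per-gene coupling between groups. An unpaired Mann–Whitney
alternative is provided. Identical vectors short-circuit to p = 1.

DE between two conditions is a transparent fold-change rule:
`(mean_case + 1) / (mean_control + 1) ≥ fc` or `≤ 1/fc` (default 1.5).
No variance model is fitted — the rule keeps the DE-set overlap
statistic well-defined and exactly testable; it is not a substitute for
count-based DE inference on real sequencing data.

## Enrichment

Over-representation of an unranked query list in each GMT set:
hypergeometric upper tail `P(X ≥ k)` with `X ~ Hypergeom(N, m, n)`,
BH-adjusted within the collection, sorted by (q, p, name). The universe
defaults to the gene catalog. Over-representation was chosen over
rank-based enrichment because the pipeline's queries are unranked
target-gene lists.

## Signature discovery

Per gene and subtype, FC(s) = (mean over s samples + 1) / (mean over the
*other AML subtypes'* samples + 1); a discovery candidate needs FC ≥ 8 in
exactly one subtype. The other-subtypes reference (rather than normal
cells) targets subtype-*discriminating* markers; it is configurable. The
pseudocount ε = 1 stabilizes FCs at low expression. Validation in the
second cohort requires the candidate's maximal-FC subtype to match its
discovery subtype with FC ≥ 2 — the screening cohort confirms direction
and subtype rather than re-imposing the stringent discovery threshold.
Genes absent from cohort 2 fail with reason "absent". The exported
heatmap is per-gene z-scored group means; constant genes map to zero
rows.

## Synthetic data generator

All randomness flows from one seed through named substreams (genome,
genes, peaks, tags, motifs, effects, cohort1, cohort2), so outputs are
byte-identical under a fixed seed and single stages can be regenerated.

* **Genome/genes**: uniform random bases, 2 × 25 Mb by default; genes
  (2–10 kb, 1–4 exons, random strand) are placed one per slot on an even
  grid, so spans never overlap and infeasible requests fail with an
  explicit message. The default density (500 genes, 3000 peaks over
  50 Mb ≈ one site per 18 kb) keeps binding sites sparse relative to the
  ±25 kb target window, so per-factor target-gene sets overlap partially
  instead of trivially coinciding.
* **Peaks**: Venn category counts are derived from the pairwise/triple
  fractions (`round(f·n)`), so directed sharing fractions are recovered
  *exactly*; shared peaks are coordinate-identical across factors and
  distinct regions occupy separate 3×width slots (> 1 width apart),
  making the planted labels unambiguous. The default sharing structure
  is 20% for AML1-ETO↔PML-RARA and 5%/6% for the CBFB-MYH11 pairs, with
  2% three-way.
* **Tags**: per peak Poisson(enrichment) positions from a triangular
  kernel (half-width = peak_width/2, mode at the midpoint — unimodal and
  analytically checkable); the remainder is uniform background, so the
  emitted total is exactly `tags_per_library`.
* **Motifs**: exactly `round(fraction × n_peaks)` peaks get the
  consensus at a random internal offset, half on the minus strand
  (rounded down). Chance consensus occurrences inside *all* peak spans
  are scrubbed first (center-base mutation, re-scanned), so at scan
  threshold 1.0 the planted flags and the scanner agree exactly. With
  fraction 0 the genome is untouched.
* **Expression**: per-gene log-normal baselines (median 100, σ = 1 on
  the log scale) with multiplicative log-normal noise (σ = 0.3; at 20
  samples/group this puts ≈ 7% sampling noise on a group-mean ratio).
  Signature genes get a subtype-exclusive fold change drawn log-uniformly
  from [8, 32], identical in both cohorts — emulating a population of
  marker genes upregulated *at least* 8-fold, the way real markers
  exceed a screening cutoff, rather than a point mass sitting exactly on
  the discovery threshold where any noise would randomize recovery.
  Common-target genes get a ×2 shift in the three AML subtypes only, so
  CMP/GMP remain at baseline like CD34⁺. True group means (including the
  log-normal mean factor e^{σ²/2}) are recorded in the ground truth.

What the generator does **not** emulate: read-length/error models,
fragment-size effects, diploid genomes, GC or mappability bias,
probe-level microarray artifacts, batch effects, or correlated gene
expression. Passing tests therefore demonstrate the *algorithms'*
correctness and exact parameter recovery under clean conditions, not
robustness to those real-data pathologies.

## Numerical and degenerate-input conventions

Empty peak sets give NaN sharing fractions with a warning (never a
silent 0). Feature distribution of an empty set, zero-length regions,
empty queries/universes, and decile sets on < 10 genes are errors.
Scan thresholds use a 1e-9 slack below `f × max_score` so exact-maximum
hits are never lost to floating-point rounding. BH q-values are computed
per collection; σ = 0 genes z-score to 0. Sequence windows shorter than
the matrix return no hits with a warning.

## Problem sizes

The default test suite runs in a few seconds: oracle-equivalence checks
use ~100+ randomized instances of ≤ 200 intervals/positions each, the
annotation oracle labels 1000 random peaks against a toy catalog, and
recovery experiments use 100–200 peaks per set or 200 genes × 20
samples/group × 10 seeds. The acceptance script runs the full default
conditions (2 × 25 Mb genome, 3 × 1000 peaks, 200k tags, two cohorts of
6 × 20 samples, ten signature replicates) in well under a minute.

## Known limitations

* One transcript model per gene; no UTR/TTS subcategories.
* No statistical null for interval overlaps (no permutation testing).
* Motif percentages depend on the synthetic consensus matrices and the
  fraction-of-max threshold; they are not comparable to percentages
  produced by other scanners with empirical matrices.
* The DE rule and the validation criterion (max-FC subtype + FC ≥ 2) are
  deliberately simple, transparent conventions; both are configurable.
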