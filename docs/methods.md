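# Methods

## Model and procedure

`vmrcall` treats a methylome panel as a sites × samples matrix of per-CpG
methylation percentages $m_{c,s} \in [0, 100]$, with each sample assigned
to a cell type and each cell type to a tissue.  The analysis runs in five
stages.

**1. Four-way CpG categorization.**  Seed rules label each CpG from its
cross-sample vector: constitutively unmethylated (U, all values < 30),
constitutively methylated (M, all values > 70), intermediately methylated
(I, at least `i_min_libraries` values in [30, 70]), and variably
methylated (V, third-highest minus third-lowest value ≥ 40).  The rank-3
gap statistic makes the V call robust to up to two outlier samples on
each side while still firing when a full cell type (≥ 3 samples in the
default design) departs from the rest.  Rules are evaluated in the order
U, M, I, V.  U/M are mutually exclusive with everything by construction,
but a vector can satisfy both I and V; I wins by default because it is
the stronger global constraint (50 of 54 samples), and the count of
conflicts is logged.  A `i_precedence=False` switch flips the order for
sensitivity analysis.  With S ≠ 54 samples the intermediate-count cutoff
rescales as ⌈50/54 · S⌉ (overridable).

**2. k-NN refinement.**  CpGs matched by no seed rule are labeled by
k-nearest neighbors with k = 4, Euclidean distance on the full
cross-sample vector — the only feature space available to the method.
Iteration 1 votes among seed-labeled CpGs only; subsequent iterations
(up to 10, early-stopped when no label changes) let newly labeled CpGs
join the reference set, excluding each query's self-match.  A majority
vote decides; on a 2–2 tie the label of the single nearest neighbor
(restricted to the tied labels) wins, which is deterministic and
row-order independent.  Seed labels are frozen by default — refinement
assigns the remainder rather than relabeling the seeds — with a
`relabel_seeds` switch for the alternative reading.  Search is exact
(scikit-learn `NearestNeighbors`); at the panel sizes this package
targets (tens of millions of CpGs would require chunking, which the
brute-force backend supports) approximate search has not been needed.

**3. Region merging and segmentation.**  Same-category CpGs merge into
regions when the number of intervening bases (next start − previous end)
is at most 500 and the open gap crosses no blacklist interval; category
changes always break.  Singleton CpGs become 2-bp regions.  The extended
track tiles each chromosome: adjacent regions whose facing CpGs are
≤ 1000 bp apart meet at the midpoint of the gap (the unique symmetric
choice; odd gaps give the spare base to the left region); larger gaps
become CpG desert (D) starting 50 bp beyond each flanking CpG; chromosome
ends beyond the terminal CpG ± 50 bp are desert, and a terminal gap under
50 bp simply extends the region to the chromosome edge.  Blacklist
intervals carve out B segments from any state last.  The gap is measured
in intervening bases and the desert test compares CpG-to-CpG distance
(next start − previous end); both conventions are config constants.

**4. Hypomethylated VMR calling.**  Per VMR, the mean over member CpGs is
taken per sample, then means are averaged within each cell type (the
two-stage mean — deliberately not a pooled CpG×sample mean, which would
differ under unbalanced designs).  A VMR is hypomethylated in a cell type
when that mean is < 30, and flagged cell-type specific when hypomethylated
in 1–3 cell types; at least one is required — a VMR hypomethylated
nowhere carries no cell-type signal.

**5. Enrichment statistics.**  Background regions match the foreground in
count and exact length multiset, placed uniformly over the non-blacklist
genome by vectorized rejection sampling (chromosomes weighted by
admissible start positions; a `match_chrom` flag adds per-chromosome
matching).  Fold enrichment is (#foreground overlapping ≥ 1 bp)/(#background
overlapping); a zero background count yields a flagged +inf sentinel.
Fisher's exact test is one-sided (greater) by default, matching the
directional claims the statistic supports, with a two-sided option.
Chromatin-state enrichment counts region *centers* ((start+end)//2) in
each state for both foreground and background — the symmetric choice; an
`background_rule="overlap"` flag reproduces the asymmetric alternative.
GWAS variants are 1-bp points (no LD expansion).  Trait enrichment is
hypergeometric: with N catalog associations, K carrying the trait, n in
VMRs and k of those carrying the trait, p = P(X ≥ k), fold =
(k/n)/(K/N), Benjamini–Hochberg within each cell type's trait list.
Tissue specificity of TFBS enrichment uses one-way ANOVA on per-cell-type
folds grouped by tissue (the cell type is the replication unit), with BH
across TFs; zero within-group variance with non-zero between-group
variance is reported as exact separation (F = ∞, p = 0) rather than fed
to the F distribution.

**QC.**  Concordance between two aligned per-CpG vectors is the fraction
with |a−b| strictly below 25 points, restricted to reference CpGs with
coverage ≥ 10.  Saturation draws, for each subset size n, ten random
sample subsets and applies the V gap rule alone — re-running the full
k-NN pipeline hundreds of times would conflate classifier convergence
with the sampling question; a `full_pipeline` flag enables it.  The 1-kb
window matrix (mean methylation per window per sample, with per-window
CpG counts) is emitted for external ordination/clustering; PCA itself is
out of scope.

## Synthetic data generator

`simulate_methylomes` emulates the statistical structure the analysis
assumes, with exact planted truth:

* **Study design** — 54 samples in 18 cell types of 3 samples each,
  grouped 3 cell types per tissue (6 tissues).  Three samples per cell
  type is the minimum that lets a single hypomethylated cell type trigger
  the rank-3 gap rule.
* **Class mixture** — exact largest-remainder allocation of
  (p_M, p_I, p_U, p_V) = (0.70, 0.03, 0.075, 0.195) over 50,000 CpGs on
  two ~3.2-Mb chromosomes.  The proportions echo the empirical pattern in
  multi-tissue panels: ~70% constitutively methylated, ~7.5%
  constitutively unmethylated, a few percent intermediate, ~20% variable.
* **Geometry** — inter-CpG spacing uniform on [2, 238] bp (mean ≈ 120);
  the "clustered" model adds 2% long gaps of 1.2–4 kb to exercise desert
  segmentation.  V CpGs are planted in runs of 3–30 consecutive CpGs with
  intra-run spacing capped at 300 bp, and runs are always separated by at
  least one non-V CpG, so each run merges into exactly one region
  downstream.
* **Values** — base levels per class: M uniform(82, 98), U uniform(2, 18),
  I uniform(40, 60); V CpGs uniform(3, 12) in the region's planted
  hypomethylated cell types (drawn uniformly, 1 to 5 cell types per
  region) and uniform(88, 97) elsewhere.  The ≥ 12-point margins from the
  30/70 cutoffs mean the seed rules recover 100% of labels at zero noise;
  optional Gaussian noise (clipped to [0, 100]) pushes borderline CpGs
  into the k-NN path.  The noise model is a truncated Gaussian on the
  percent scale — real enrichment-based predictors have heteroskedastic,
  coverage-dependent error, which this deliberately does not model.
* **Annotations** — the blacklist (10 × 2 kb) is placed clear of planted
  regions (600 bp margin, larger than the merge gap) and of every CpG
  site, reflecting that blacklisted regions carry no usable signal.
  Peaks and variants: at enrichment factor 1 they are uniform over the
  non-blacklist genome (an exact null against the background sampler);
  at factor f > 1 each lands fully inside a planted region with
  probability min(f·ρ, 1) (ρ = planted genomic density, inside-region
  start chosen uniformly over all admissible starts) and otherwise
  uniformly outside both planted regions and blacklist.  Chromatin
  states tile the genome in random 0.5–5 kb segments over 15 labels.
  All randomness flows from one spawned RNG tree per seed.

`expected_fold_enrichment` gives the closed-form expectation of the fold
statistic under this scheme: the foreground term is exact
(P(region r hit) = 1 − (1 − q·w_r/W)^n with w_r the admissible starts in
r), and the background term uses the uniform-placement approximation
P(two random intervals of lengths ℓ and L on the same chromosome overlap)
≈ (ℓ+L−1)/chrom length, combined over both sides' chromosome-choice
distributions.  Edge effects near blacklist and chromosome boundaries are
ignored; empirically the approximation sits within a few percent of
Monte-Carlo means, well inside the ±15% recovery band the tests assert.

**What passing tests do and do not show.**  The generator's classes are
well separated by construction, so label-recovery results demonstrate
correctness of the implementation (rules, merging, tie-breaks,
bookkeeping), not classifier performance on real methylomes, where class
boundaries blur, missingness and coverage artifacts exist, and
methylation autocorrelates along the genome in ways the iid-per-CpG
value model does not reproduce.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; a CpG is the 2-bp plus-
  strand dinucleotide interval carrying one strand-combined value.
* Missing values are NaN on input; the classifier requires complete rows
  (error by default, `drop_incomplete()` for the drop policy).
* Region centers: (start+end)//2.  TSS distance: region midpoint to the
  nearest TSS (edge distance by flag); the TSS is txStart on +, txEnd on −.
* Exact distance ties in k-NN are resolved by the neighbor-search return
  order; with continuous methylation values exact ties have measure zero.
* Fold with zero background overlaps: +inf sentinel plus `undefined`
  flag, never silently dropped.
* Empty chromosome in the extended track: a single D segment (plus B
  carve-outs).  Empty region sets, zero-variant sets, and empty gene sets
  raise or return defined no-data results as documented per function.
* Concordance uses strict inequality (a difference of exactly 25 is
  discordant).
* One seeded background draw per enrichment by default; averaging over
  draws is the caller's loop.

## Problem sizes

The default study is 50,000 CpGs × 54 samples on a two-chromosome 6.4-Mb
toy genome — large enough that every code path (k-NN refinement, desert
states, blacklist carving, background rejection sampling) is exercised
with hundreds of regions, small enough that the full test suite and the
acceptance script each run in well under a minute of compute per stage.
Null calibration uses 100 annotation/background replicates; signal
recovery uses 20 replicates of 5,000 planted-enrichment intervals.

## Known limitations

* The value model is iid per CpG given its class; no along-genome
  autocorrelation, no CpG-island sequence composition, no read-level
  simulation.
* k-NN search is exact brute force; panels of 10⁷+ CpGs would want a
  chunked or approximate backend.
* Hypomethylation calls assume complete matrices; per-cell-type
  missingness weighting is not implemented.
* GWAS enrichment ignores linkage disequilibrium structure entirely.
* The ANOVA treats per-cell-type folds as independent observations;
  shared background draws induce slight dependence that is not modeled.
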