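# Methods

This note documents the models and procedures `clonetrace` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open.

## Clone calling

### STICR (combinatorial lentiviral barcodes)

A clonal barcode is a triple of fragments, one from each of three
reference pools, followed by a constant per-library *viral index*. Reads
are processed as:

1. **Extraction** at fixed offsets (fragment length 14 nt by default,
   index 6 nt); reads shorter than the layout span are rejected with a
   reason code, flanking sequence is ignored.
2. **Alignment** of each fragment by exhaustive Hamming scan over its pool
   (`max_fragment_mismatch = 2`). The generator guarantees pairwise pool
   distances ≥ 5, so radius-2 balls are disjoint and a ≤2-mismatch hit is
   unique; if two pool entries nevertheless tie at the minimum qualifying
   distance (possible for user-supplied pools) the read is *ambiguous* and
   dropped. The scan is vectorized over unique fragment sequences; pools
   of ≤500 entries need no index structure. The viral index must match a
   known index exactly; it identifies the library, so no mismatch
   tolerance is warranted.
3. **UMI deduplication** per (cell, barcode): directional collapse in
   which UMIs within `umi_collapse_mismatch = 1` of a higher-count UMI
   merge into it. Seeds are visited in (count descending, lexicographic)
   order and clusters absorb neighbours whose count does not exceed the
   member they attach through, which makes the procedure deterministic and
   resolves equal-count ties lexicographically.
4. **Tiered assignment** per cell: barcodes with ≥ `min_umi_candidate = 5`
   surviving UMIs are candidates. Exactly one candidate → tier 1. Two or
   more → tier 2 iff the top candidate has ≥ `dominance_factor = 5` times
   the UMIs of the next most abundant barcode. Any winning call is kept
   only with ≥ `min_umi_final = 9` UMIs. When exactly one candidate passes
   the ≥5 threshold the cell is tier 1 regardless of sub-threshold
   competitors; the dominance comparison is only invoked between
   candidates. This is the laxer of the two defensible readings and is
   easy to tighten via `SticrParams`.
5. **Clone table**: cells sharing a barcode within a dataset form a clone
   (clone id = dataset + barcode, so cross-dataset collisions are
   detectable by construction); any barcode observed in ≥2 datasets is
   blacklisted as a suspected library collision and all its cells dropped.
   Clonal analysis uses tier-1 calls by default (`tier1_and_2` available).

### TrackerSeq (transposon integrations)

Cells carry sets of 37-nt barcodes. Records below 37 nt are discarded and
counted; a cell–UMI–barcode triple needs ≥10 reads; a cell–barcode pair
needs ≥6 distinct UMIs (exact-match UMI dedup — the assay's published
thresholds state no mismatch allowance; a Hamming pre-collapse of barcode
sequencing errors exists but is off by default, since error clustering
belongs to library QC, not clone calling). Surviving pairs form a binary
integration matrix. Clones are flat clusters of average-linkage
agglomeration over Jaccard distances (1 − |A∩B|/|A∪B|) between rows.

**Cut semantics.** The dendrogram is cut at 0.999 *on the distance scale*:
fcluster with criterion `distance`, i.e. cells join a clone only through
merges below 0.999. Cells with disjoint barcode sets are at distance
exactly 1 and can never merge; any shared barcode gives distance < 1. A
normalized-height reading of the cut is conceivable but incoherent with a
Jaccard distance bounded by 1, so the distance-scale reading is adopted
and recorded in output metadata (`cut_scale=jaccard_distance`).

## Lineage coupling

Definitions and the permutation scheme are given in the README. Numerical
choices:

- **Diagonal pairs** {s, s} are excluded and reported NaN; the metric is
  defined for pairs of two distinct states.
- **Shuffling unit** is the individual cell. One global label shuffle per
  iteration serves all pairs, so the null preserves the full per-state
  count vector exactly (a permutation of the observed labels) and the
  pairwise null values are computed on a common shuffle, as a single
  simulation per iteration implies. Clones fragment under this null; that
  is the intended reference distribution.
- **Null sd** is the population standard deviation over the N permutation
  values (n vs n−1 is immaterial at N = 10⁴). Pairs with sd = 0 (e.g. all
  clones singletons) report z = 0 and are flagged in `sd_zero`.
- **Coupling correlations** compare z(s₁, ·) with z(s₂, ·) excluding the
  diagonal and the s₁/s₂ entries themselves, avoiding self-inflation from
  the pair's own (identical) entry. Constant vectors make the correlation
  undefined; such pairs report 0 and require ≥4 states to be meaningful.
- **Clone purity categories** use dominant-class fraction f: "100%" iff
  f = 1, ">80%" iff 0.8 < f < 1, "<80%" iff f ≤ 0.8. Glia = {astrocyte,
  OPC, oligodendrocyte}, neurons = {neuron}; clones containing neither
  (e.g. vascular-only) are set aside as "other" and excluded from the
  glia/neuron fractions.

## Collision model

Labelling n progenitors from a library of D barcodes with abundances pᵢ is
n independent categorical draws; collisions = n − unique. The closed form
E[unique] = Σᵢ(1 − (1 − pᵢ)ⁿ) is exact and serves as the oracle for the
Monte-Carlo curve. Uniform libraries use integer draws; explicit abundance
vectors use per-replicate multinomial occupancy counts, which have exactly
the categorical sampling distribution and vectorize well, falling back to
direct categorical draws when D is too large to materialize count vectors.
The default grid is 10¹…10⁶ cells at 20,000 replicates; a draw budget
(default 2×10⁷ draws per population size) reduces replicates at the
largest sizes (never below 200), reporting the replicate count, standard
error and a `scaled_down` flag per row. The library size itself (e.g. the
~60–70 million distinct barcodes estimated for a real lentiviral library)
is an input, not something the package estimates from saturation curves.

## Cell-type mapping

Model vectors are arithmetic means of log-normalized expression per
postnatal cluster over a user-supplied shared variable-gene list
(variable-feature selection is upstream preprocessing, out of scope).
Cells are assigned by argmax Pearson correlation; ties break to the first
cluster in declared order with a flag, and zero-variance cells are
unassignable and flagged.

**Permutation scheme.** The null permutes each cell's expression values
across genes independently (`within_cell`, the default), leaving the
models unchanged: each cell keeps its value distribution and only the
gene-to-value pairing is broken, which is the natural null for a
correlation against fixed model vectors. Because Pearson correlation is
invariant to per-row standardization, permuting the standardized row
equals standardizing the permuted row, so the permuted correlations reuse
the precomputed standardization. A `within_gene` (across-cell) scheme is
implemented as an option and the scheme used is recorded in output
metadata. p = fraction of the 100 permuted per-cell maxima *strictly*
larger than the observed best correlation — no pseudocount, so p = 0 is
possible at 100 permutations, as a plain counting definition implies.
p-values are Benjamini–Hochberg adjusted and cells map iff FDR < 0.1.

Cluster-level distances are 1 − Spearman ρ between average cluster
expression vectors; constant averages give undefined pairs, reported NaN.

## Synthetic data

The generators emulate the study design the pipeline targets, and their
defaults are the conditions the tests run under:

- **Library**: pools of distinct 14-nt fragments at pairwise Hamming ≥ 5
  (greedy rejection sampling; infeasible requests fail explicitly),
  optional per-fragment lognormal abundance skew, one 6-nt viral index.
- **TrackerSeq barcodes**: a 37-nt template with 16 random positions in 8
  blocks bridged by fixed trinucleotides, giving 4¹⁶ = 16⁸ ≈ 4.3×10⁹
  combinations. The mask is a parameter and is recorded in metadata, so
  smaller effective complexities are producible by masking fewer
  positions.
- **Populations**: clone sizes from constant, truncated-geometric
  (default, p = 0.2–0.35, max 30, matching means of a few cells and
  maxima of tens) or empirical distributions; each cell draws its state
  from its clone's own distribution, so a shared distribution yields
  clone-independent labels (the calibration null), low-concentration
  Dirichlet yields coherent clones, and `gen_coupled_population` plants a
  coupling between one state pair while keeping marginal state counts
  balanced — the planted pair is then the only pair whose sharing exceeds
  the permutation null rather than its marginals.
- **Reads**: per (cell, barcode), a drawn number of distinct UMIs (default
  12, comfortably above the ≥9 final threshold), PCR duplicates per
  triple, 1-substitution UMI error copies at a configurable rate and ≤2
  substitution fragment errors confined to one fragment — exactly the
  error modes the thresholds and mismatch tolerances are designed to
  absorb. UMI length 10 nt and cell-barcode length 16 nt match common
  droplet chemistry.
- **Expression pairs**: matched embryonic/postnatal clusters share
  disjoint marker blocks (default 10 genes of 200) elevated by `effect`
  (default 2.0) over baseline 0.5 with Gaussian noise (sd 0.5), clipped at
  zero — the persistence of marker signatures across development, at
  log-normalized scale, with no library-size, dropout or batch structure.

What passing tests therefore show: the algorithms recover planted clonal
and transcriptional structure under the declared noise models, agree with
closed-form/enumeration oracles, and are calibrated under their own nulls.
What they do not show: robustness to real-data pathologies outside these
models — index hopping, chimeric PCR products, ambient RNA, doublets,
batch effects, or barcode-abundance structure beyond lognormal skew.

## Problem sizes and determinism

Every generator and every randomized statistic is a pure function of its
arguments including an explicit seed; reruns are byte-identical. The test
suite and the acceptance script run the coupling calibration and
planted-signal checks at 50 replicates × 2,000 permutations (the z
estimator's Monte-Carlo error at 2,000 permutations, ≈0.02, is an order of
magnitude below the calibration band being asserted, and the oracle
comparisons that probe the estimator itself use the full N = 10,000),
recovery at ~100 clones / ~300–500 cells with 50-fragment pools, and the
collision check at 2,000 replicates for n ≤ 10⁴ — sizes chosen so the
whole suite completes in well under a minute per check while leaving the
asserted statistics far from their tolerance boundaries.

## Known limitations

- Fragment alignment is exact Hamming scan; indels in reads are not
  modelled or tolerated (consistent with fixed-offset extraction).
- The TrackerSeq barcode generator does not enforce the ≥5-bp pairwise
  separation a designed library carries; random 16-position barcodes make
  collisions negligible at simulated scales but closer pairs are possible.
- Average-linkage ties are resolved by scipy's merge order; partitions at
  the flat cut are tie-order invariant in the tested regimes but exotic
  tie structures could differ between implementations.
- The coupling correlation needs ≥4 states; with exactly 3 the compared
  vectors have length 1 and the correlation is reported as flagged 0.
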