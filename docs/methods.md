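# Methods

This note documents the statistical models implemented in `trailkit`, the
parameter defaults and why they were chosen, the numerical conventions that
make results bit-reproducible, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Differential scoring

Given an expression matrix (genes × samples) and a two-group assignment
(A/B), three scores are provided, each positive when expression is higher
in group A:

- **log2 fold-change**: `log2((mean_A + c) / (mean_B + c))` with
  pseudocount `c` (default 1.0, appropriate for counts; use 0 for data that
  is already strictly positive).  A zero group mean with `c = 0` is an
  error naming the offending gene.
- **Welch t**: `(mean_A − mean_B) / sqrt(s²_A/n_A + s²_B/n_B)` with
  unbiased variances.  Requires ≥ 2 samples per group.  Genes with zero
  variance in both groups are scored 0 (logged as a warning) rather than
  propagating a 0/0.
- **Rank-sum z**: the normal approximation of the two-sample rank-sum
  statistic with the standard tie correction and no continuity correction.
  Fully tied genes score 0.  At very small group sizes the normal
  approximation deviates from the exact permutation distribution; the test
  suite bounds that deviation (|z − z_exact| < 0.15 at n = 4 + 4) rather
  than hiding it.

The absolute-value transform re-sorts descending; all sorts everywhere use
the lexicographic gene token as the final tie-break key, so identical
inputs give byte-identical outputs.

Filter rules: `top_k` (k highest), `upper_lower_percent(q)` with rank-based
cutoffs of `ceil(q/100·n)` genes per tail (not interpolated quantiles), and
`abs_threshold(t)` (|score| ≥ t).

The scoring menu is intentionally small: count-model methods (negative
binomial GLMs and friends) belong to dedicated differential-expression
packages and are out of scope here; this toolkit consumes either raw counts
(for fold-changes and rank tests) or already-normalized values.

## Enrichment statistics

**ORA.**  With universe size N (the reference set), K category members in
the universe, test-set size n and overlap k, the enrichment p-value is the
hypergeometric upper tail P(X ≥ k), the depletion p-value P(X ≤ k), and the
two-sided p-value 2·min(tails) capped at 1 (chosen for monotonicity and
simplicity over more elaborate two-sided definitions).  The record's
statistic is k − nK/N, the deviation from the expected overlap, and its
sign sets the reported direction.  Category sizes are always reported
*after* intersection with the reference: genes annotated to a category but
absent from the data do not exist for the test.

**Running-sum ES.**  Walking down the ranked list, member ranks add
|sᵢ|^p / N_R (N_R = Σ members |s|^p; if the weighted mass is zero the
increment falls back to uniform 1/N_h) and non-member ranks subtract
1/(N − N_h).  ES is the signed maximum deviation from zero, taking the
earliest extremum on exact float ties; `weight_p = 0` reproduces the
unweighted Kolmogorov–Smirnov-like statistic, `weight_p = 1` the familiar
score-weighted variant.  The leading edge is the set of members at or
before the extremum (after it for negative ES).  A category covering the
whole list leaves the statistic undefined and is an error.

**Permutation null.**  Because the input is a single ranked list (not a
sample-by-sample matrix), the null permutes category membership over ranks:
B redraws of N_h distinct ranks, with the rank-attached weights staying in
place.  p = (1 + #{|ES_b| ≥ |ES|}) / (B + 1), two-sided by |ES|; the
add-one estimator never returns zero and is bounded below by 1/(B + 1).
Defaults: B = 1000, seed 42, both recorded in run configs.  Sample-label
permutation GSEA is a non-goal.

The batched null evaluates ES in closed form from sorted member ranks: the
running sum attains local maxima only immediately after members and local
minima immediately before them, so 2·N_h candidates suffice per
permutation.

**Other FCS statistics.**  The rank test compares member positions against
non-member positions with the rank-sum z (positions are distinct, so no tie
correction is needed); the parametric test is a Welch t of member scores
against the rest; the averaging methods report the mean or median member
score with the same membership-permutation null (two-sided: doubled
smaller tail of the null distribution).

**Adjustment.**  Benjamini–Hochberg (step-up with cumulative minimum from
the largest rank, capped at 1), Bonferroni, and Benjamini–Yekutieli, all
delegated to `statsmodels` and cross-checked in the tests against an
independently coded step-up oracle.  Adjustment is computed across tested
categories only; skipped categories (size filter, degenerate variance, no
members in the data) are reported with reasons.

`run_enrichment` filters categories to sizes in [min_size, max_size]
(defaults 3 and 700 — the field's customary guard band against trivially
small and uninformatively large categories; configurable).

## Deregulated-path search

Given a directed gene network and a ranked list, the search returns for
every length ℓ in 2..k_max the node-simple directed path whose gene set
maximizes the unweighted running sum in the enrichment direction (the
maximum of the running sum; always in [0, 1] because the running sum after
the final member is non-negative).  The score depends only on the set of
ranks occupied, so a path is scored in O(ℓ):
after the j-th member at 0-based rank p_j the running sum is
j/N_h − (p_j + 1 − j)/(N − N_h), and the global maximum is attained at one
of these points.

The engine is a depth-first enumeration of node-simple paths with this
closed-form rescoring and lexicographic tie-breaks on the node sequence.
At the graph sizes where length-bounded path analysis is interpretable
(curated pathway maps, a few hundred nodes with modest degree), the
enumerated space is small; correctness is defined by equality with
exhaustive enumeration, which the acceptance suite verifies on 100 random
DAGs.  A dynamic program over (vertex, length) was considered and rejected:
the best length-(ℓ−1) predecessor path is not always extendable (it may
already contain the successor node) and the statistic is not decomposable
over prefixes, so a DP needs either exact rescoring of many candidate
predecessors or a fallback search — at which point plain enumeration is
simpler and exactly right.

Only enrichment-direction paths are searched; to find down-deregulated
paths, pass a negated or absolute-value score list.  Node revisits are
forbidden (a "path" that loops has no biological reading as a cascade).
Significance per length uses B redraws of ℓ distinct ranks (add-one
estimator), BH-adjusted across the returned lengths; the null permutes rank
positions, not network wiring, because the claim under test is about the
rank profile of the path, not about the topology.  Branched-subgraph
(non-path) detection is out of scope.

## Regulator prioritization

Inputs: an RTI table (regulator → target pairs), an expression matrix, and
a score-sorted gene list of interest (for a disease contrast, typically the
most upregulated genes).  For each regulator with at least `min_targets`
targets in the list (default 5):

1. Pearson correlations between the regulator's expression row and each
   in-list target row are computed over the matrix samples (≥ 3 samples
   required; constant rows are skipped and counted).
2. The statistic is a correlation-weighted running sum over the sorted
   list: target hits add |r| (normalized to sum 1; uniform fallback when
   all |r| = 0), misses subtract uniformly — so a regulator scores highly
   when its strongly-correlated targets concentrate at the top of the list.
3. The null redraws the target ranks B times (weights randomly re-paired
   with the redrawn ranks); p is one-sided (enrichment) with the add-one
   estimator, BH-adjusted across tested regulators.
4. The role call is the sign of the mean correlation over in-list targets:
   positive = potential activator, negative = potential repressor, zero or
   incomputable = undetermined.

This statistic is a re-derivation from the published ingredients of
RTI-based regulator prioritization (validated interactions + expression
matrix + sorted gene list + mean-correlation role call); it is validated by
planted-recovery and calibration tests against its own oracles, and no
bit-equality with any other implementation is claimed.  Pearson rather
than Spearman correlation is the default because the workflow's inputs are
already variance-stabilized (log-scale or pseudo-bulk-normalized) values;
binding-motif and open-chromatin methods are out of scope.

## Single-cell workflow

- **QC**: keep cells with detected-gene count in [min_genes, max_genes]
  (defaults 200 and 6000 — conventional bounds for droplet data that drop
  empty/damaged barcodes and doublet-like profiles) and total counts
  ≤ max_total; genes detected in no surviving cell are dropped; removals
  are logged per criterion.
- **Normalization**: counts-per-10k per cell, then log(1 + x).  The
  pre-log column sums equal 10,000 to 1e-6; `scale=1e6` gives CPM.
- **Top-N selection**: each cell's N most highly expressed detected genes
  (default 500), lexicographic tie-break at the boundary; cells with fewer
  detected genes use all of them (logged).
- **Per-cell ORA**: enrichment-tail hypergeometric test of each cell's
  top-N set against every surviving category, with the reference universe
  being all genes of the filtered matrix (the natural background: genes the
  experiment could have detected).  The category size filter is computed
  once and is identical across cells.  Activity = −log10 of the raw
  per-cell p; the raw p-values are retained alongside.
- **Group testing**: per category and group, a two-sided one-vs-rest
  rank-sum test of activity scores (two-sided with a reported direction,
  so "less active" findings surface symmetrically); direction follows the
  sign of the rank statistic; BH across all (category, group) pairs; groups
  with fewer than 3 cells are excluded with a warning.
- **Pseudo-bulk**: gene-wise summation of counts over each sample's cells;
  total counts are conserved exactly (integer equality), making the output
  a valid input for bulk scoring.

Clustering and 2-D embeddings are consumed as optional metadata columns,
never computed: they are upstream concerns of dedicated single-cell
frameworks.

## Time-series workflow

The change score is the aggregated absolute difference over consecutive
time-points, Σ|x_{t+1} − x_t| (absolute rather than signed differences, so
transient responses are not cancelled by their return to baseline).  After
threshold or top-fraction filtering, courses are clustered by seeded
k-medoids under either z-normalized Euclidean distance or 1 − Pearson;
one engine serves both metrics, which is why k-medoids was chosen over
k-means (a mean is not a meaningful centroid under a correlation metric).
Initial medoids are k distinct random genes; assignment ties go to the
lowest medoid index, medoid updates break ties by gene token; the
objective is asserted non-increasing and iteration stops when the medoid
set is fixed (cap 100 iterations).  Constant courses have undefined
correlation; by convention they get zero correlation (distance 1) to
everything and are flagged.  k is user-chosen; no automatic model
selection.  Per-cluster ORA then tests each cluster's members against the
full gene universe, BH within cluster.

## Synthetic fixtures

The generators produce the study conditions the pipelines are tested
under; every generator is fully determined by its spec (including the
seed) and returns a truth record naming the planted structure.

- **Bulk**: log-normal intensities (baseline log2-mean 6, SD 1.5,
  biological noise SD 1 in log2) for 1,000 genes × (10 + 10) samples; 25
  planted genes shifted by 2 log2 units in group A.  Effect 2 at n = 10+10
  puts planted genes at |t| ≈ 4–5, strong but not degenerate.
- **Gene sets**: 50 uniform decoy sets (sizes 10–50) plus one planted set
  = the planted genes with 5 random padding genes.
- **Network**: an Erdős–Rényi DAG over a topological order (30 nodes,
  edge probability 0.12) with a simple path injected through the top
  planted genes, consistent with the topological order so the graph stays
  acyclic.
- **Single cell**: negative-binomial counts (variance μ + 0.5μ², mean
  depth 2,000, log-normal depth variation) for 800 genes × three groups of
  100 cells labelled ARDS / NonVent / Healthy — the severity-contrast
  shape of a COVID-19 monocyte data set — with a 50-gene program up-shifted
  4-fold in the ARDS cells, plus 3 near-empty and 3 doublet-like cells that
  deliberately fail QC.
- **RTI**: 20 regulators; the causal one targets the planted genes and its
  expression row is built to correlate (generating correlation 0.8) with
  their standardized mean profile; 19 decoys draw 80 targets uniformly
  (large target sets, as is typical for transcription factors, so decoys
  actually pass the min-target filter and compete) and express independent
  noise.
- **Time courses**: three planted shape families (monotone up, monotone
  down, transient peak; amplitude 2) plus flat noise genes, Gaussian noise
  SD 0.3.  For flat genes the expected change score is closed-form
  (per step E|Δ| = 2σ/√π), which the tests verify.

What the fixtures do **not** emulate: batch effects, ambient RNA,
doublet structure beyond inflated totals, gene–gene correlation beyond the
planted program, dropout beyond what the negative binomial produces, and
realistic pathway overlap between categories.  Passing the recovery tests
therefore demonstrates that the statistics find the structure they are
designed to find under clean conditions with realistic noise magnitudes —
not that they are robust to every artefact of real data.

## Problem sizes and determinism

The acceptance checks run 100 seeded simulations per pipeline at the sizes
above, 500 randomized running-sum cases, a complete ORA enumeration sweep
for universes up to N = 12, 1,000-case randomized sweeps for the
hypergeometric identity and Benjamini–Hochberg, and a 200-repeat
calibration of the permutation null at B = 1000 — sizes at which the
binomial noise on a ≥ 95/100 recovery criterion and the Monte-Carlo error
on a mean-p window of ±0.03 are both well controlled.  All randomness
flows through explicit seeds (`numpy.random.default_rng`); run outputs,
logs and run-config JSONs contain no timestamps, so any command re-run
with identical inputs and seeds reproduces its outputs byte for byte.

## Known limitations

- The rank-sum z is a normal approximation; exact small-sample tests are
  not provided.
- ORA treats genes as exchangeable; no correction for gene length, GC, or
  expression-level selection bias.
- The GSEA null permutes membership, not sample labels, and therefore
  tests rank concentration, not inter-gene correlation structure.
- The path search's worst case is exponential in k_max on dense graphs;
  it is intended for sparse curated networks and modest path lengths.
- Regulator prioritization depends on the completeness of the RTI table;
  regulators with few catalogued targets in the list are excluded, not
  scored.
- Identifier handling is a case-insensitive token match; no cross-species
  or cross-database identifier mapping.
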