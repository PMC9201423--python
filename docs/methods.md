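# Methods

`scnkit` implements group-level structural covariance network (SCN) analysis
of regional gray-matter volumes: two groups of subjects, one volume per atlas
region per subject, are turned into one binary graph per group per edge
density, graph metrics are computed and normalized against random nulls, and
group differences are tested by full-pipeline permutation. This note records
the model, the conventions that change numbers, and the design choices made
where the design was genuinely open.

## From volumes to graphs

**Nuisance regression.** Regional volumes correlate with head size, which
would inflate every inter-regional correlation. Within each group, each
region's volumes are regressed on total intracranial volume (TIV; ordinary
least squares with intercept) and replaced by the residuals. Residualization
is recomputed inside every permutation, on the permuted group, so the null
pipeline is structurally identical to the observed one.

**Association.** The group's association matrix is the region×region Pearson
correlation of the residual vectors. The diagonal is stored as 0 and is
never edge-eligible.

**Thresholding.** At density `d`, the graph keeps exactly
`round(d·N(N−1)/2)` edges (round half away from zero): the pairs with the
largest *signed* correlation, ties broken by ascending (row, column) index.
Signed ranking (most positive first, negatives effectively last) is the
convention of the covariance-network toolboxes this pipeline follows; an
absolute-value mode exists behind `threshold_mode="absolute"` but is off by
default. Rank selection with a fixed tie-break makes edge sets nested across
densities and every graph bit-reproducible.

**Density grid and Dmin.** Metrics are computed across densities 0.27–0.50
in steps of 0.01 (24 points). The lower bound follows the Dmin rule: the
grid must start at a density where both groups' graphs form a single
connected component, and 0.50 is the ceiling beyond which covariance graphs
are regarded as non-biological. `find_dmin` returns the smallest grid
density that connects both groups; on the synthetic cohorts below this is
0.27 for most seeds and occasionally 0.28–0.36, because a subject-level
noise outlier can depress one region's correlations collectively — the same
phenomenon that makes the Dmin rule necessary on real data. Tests and the
acceptance script therefore start the grid at `max(0.27, Dmin)` per cohort.

## Graph metrics

All graphs are simple and undirected; distances are BFS hop counts.
Conventions, which matter for comparison with other software:

- **Clustering (Cp)** — mean over nodes of the fraction of neighbor pairs
  that are themselves linked; degree-<2 nodes contribute 0 to the mean.
- **Characteristic path length (Lp)** — mean shortest-path length over all
  node pairs; defined only for connected graphs (the Dmin rule guarantees
  this on the grid).
- **Global efficiency** — mean of 1/distance over pairs; unreachable pairs
  contribute 0, so disconnection is allowed.
- **Local efficiency** — mean over nodes of the global efficiency of the
  subgraph induced by the node's neighbors; degree-<2 nodes contribute 0.
- **Transitivity** — 3 × triangles / connected triples.
- **Assortativity** — Newman's degree correlation over edge ends; undefined
  (NaN, flagged downstream) when edge-end degrees have no variance, e.g. on
  regular graphs.
- **Modularity (Q)** — Newman–Girvan modularity of a deterministically
  optimized partition. For graphs of ≤8 nodes the optimizer enumerates all
  partitions (restricted growth strings; Bell(8)=4140) and is exact; above
  that it alternates index-order local node moves (including splitting a
  node into a fresh singleton) with greedy pair merges until neither phase
  improves. The algorithm draws no random numbers; the `seed` argument
  exists only for interface stability. Exactness on tiny graphs was chosen
  because a pilot showed pure greedy agglomeration + refinement misses the
  optimum on ~1% of small random graphs, and determinism beats marginal
  optimality at scale.
- **Betweenness (BC)** — exact Brandes betweenness, endpoints excluded,
  each unordered pair counted once. The normalized variant divides by the
  network-mean BC with zero-BC nodes included, so it averages to 1 whenever
  any shortest path has an interior node; on graphs where no shortest path
  has one (complete graphs) the normalized BC is defined as all-zero and
  flagged.

**Null normalization.** γ = Cp/Cp_rand and λ = Lp/Lp_rand, with the
reference means taken over 20 random null networks (configurable). The null
model preserves the degree sequence by double-edge swaps — 10 × edge-count
swaps per realization — and preserves connectivity with a growing/shrinking
check window (a block of swaps that disconnects the graph is undone and the
window halves). A density-matched Erdős–Rényi mode (`null_model="er"`,
connected realizations only) exists behind a flag. σ = γ/λ; a network with
γ > 1 and λ ≈ 1 or σ > 1 is considered small-world. Null Lp is computed
only on connected realizations — guaranteed by construction in both modes.

## Inference

**Permutation test.** Group labels are randomly reassigned (group sizes
preserved) and the entire per-group pipeline is re-run: residualize →
correlate → threshold across the grid → all requested metrics, including
γ/λ/σ with fresh null-ensemble seeds per evaluation. Two-tailed p-values
use the add-one rule p = (1 + #{|Δperm| ≥ |Δobs|})/(n_perm + 1), which is
exactly valid for finite permutation counts and bounds p below by
1/(n_perm+1). Differences are oriented second-group-minus-first in sorted
label order; subjects keep their table order, so for equal group sizes the
p-values are exactly invariant to swapping the labels. A permuted split
whose graph disconnects at the grid minimum is redrawn (bounded retries,
count reported) rather than skipped, keeping null and observed pipelines
structurally identical. Defaults: 1,000 permutations, α = 0.05.

**Summary statistics.** Metrics are compared per density (uncorrected) and
via the trapezoidal area under the metric–density curve (AUC), which is
robust to the choice of any single threshold. The 90 regional BC tests use
the between-group difference of normalized BC averaged across the grid
(AUC-equivalent up to a constant) and are corrected with Benjamini–Hochberg
FDR (statsmodels); per-density global tests are reported uncorrected, FDR
is applied only to the regional family.

**Resilience.** Targeted attack removes nodes in descending order of BC
ranked once on the intact graph (static ordering, ties by index; a
recompute-after-removal mode is not the default because the static variant
is the literal reading of "descending order of BC"). Random failure
averages 50 uniformly random removal orders. After each removal the
relative size of the largest remaining component is recorded with the
*original* node count as denominator, so curves run from 1 (connected
graph) to 0 (all nodes removed) and are comparable across steps. Group
comparison runs at one reference density (default: the grid minimum)
through the same permutation engine, on the curve pointwise and on its AUC.
Within an evaluation both groups share the same random removal orders
(common random numbers): identical groups then give exactly p = 1 and the
comparison variance shrinks. Note that under the generator's default group
effect the degree hierarchy of group B flattens along with its modular
covariance, so resilience curves *can* genuinely differ between synthetic
groups; a covariance effect that spares the hub structure leaves them
indistinguishable. The tests pin down the comparison's calibration
(duplicated groups give p = 1; null cohorts reject at the nominal rate),
not any particular direction.

**Demographics.** Group matching is tested with Student's t (continuous:
age, TIV), Pearson's chi-square without continuity correction
(categorical: sex) and the Wilcoxon rank-sum (ordinal: education).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
per-subject regional volumes drawn from a group-specific multivariate
normal around 7.0 mL with SD 0.9 mL, a block correlation target (within a
module `r_within`, across modules `r_between`, repaired to positive
semi-definiteness by eigenvalue clipping when block patterns are marginally
indefinite), a TIV confound (TIV ~ N(1480, 125²) mL, matching the magnitude
of adult cohorts; every region gains `tiv_beta`=0.005 mL per mL of TIV),
and an optional demographics block generated to be *exactly* matched across
groups. Volumes are clamped at 1% of the mean rather than redrawn so sample
sizes stay exact and generation is deterministic; the clamp sits ~6 SD
below the mean and is effectively never active. The group effect multiplies
group B's within-module correlations by `effect_within_b`.

Defaults define the test conditions and were chosen for statistical power
of the test suite, not anatomical realism: 49+49 subjects, 90 regions, four
covariance modules of 32/24/18/16 regions, `r_within`=0.60,
`r_between`=0.36, `effect_within_b`=1 (null). Two deliberate choices:

- *Heterogeneous module sizes.* With equal-size modules every node has the
  same expected degree, degree variance carries no group information, and
  assortativity differences are undetectable in principle. Skewed community
  sizes create a degree gradient (large modules → high-degree nodes), which
  is also closer to real parcellation communities.
- *`r_between` = 0.6 × `r_within`.* Under the canonical effect size 0.6,
  group B's within-module correlation drops exactly to the between-module
  level: the modular excess covariance dissolves completely, the cleanest
  form of "more randomized" network organization, and the strongest
  detectable contrast for clustering-family and degree-structure metrics.

What the generator does **not** emulate: spatial structure (no voxels, no
smoothing, no distance-dependent covariance), disease topography, lesions,
non-Gaussian volume distributions, site or scanner effects. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*
under its own statistical assumptions, not the reproduction of any
particular clinical finding.

## Numerical and performance choices

The permutation engine evaluates the full metric battery across 24
densities × 2 groups × (n_perm + 1) relabelings; a study-scale comparison
is ~100,000 graph-metric computations, and calibration studies multiply
that by hundreds of replicates. The graph kernels are therefore numba-
compiled and allocation-light: distances come from level-synchronous
reachability propagation through 64-bit masks rather than per-source BFS
queues, local efficiency rebuilds each neighborhood subgraph in local index
space (usually one machine word per row), and the double-edge-swap loop
uses an inline xorshift64* generator. Compiled kernels are cached on disk
after first use. networkx implements the same standard metrics and serves
as an independent cross-check in the test suite (together with hand-written
brute-force enumerations on tiny graphs), never as the computational path.

Tolerances: metric agreement with brute-force oracles is asserted to
1e-12; the PSD repair floor is 1e-10 with failure below −1e-8; modularity
gains below 1e-12 are treated as ties. Degenerate inputs are errors
(constant TIV, zero-variance regions, <3 subjects per group, edgeless
graphs for Q) or flagged values (NaN assortativity, all-zero normalized
BC), never silent.

Test-suite problem sizes: the type-I calibration of the seven directly
computed global metrics runs at full study scale (200 null cohorts,
n_perm=99); the γ/λ/σ calibration runs the identical engine on 20-region
cohorts over an 8-density grid (150 replicates, n_perm=49), since the
embedded null-network randomization makes the 90-region version several
orders of magnitude more expensive while adding nothing statistically —
permutation exactness does not depend on network size, and the specific
risk being tested (a statistic that is itself randomized) is present at
any size. The power study uses 20 effect cohorts at full scale, and the
determinism check runs the complete pipeline twice at n_perm=100.

## Known limitations

- Group-level networks only: no subject-level covariance graphs.
- Binary, undirected graphs; no weighted metric variants, rich-club,
  k-core or participation coefficients.
- Correlation significance is never used for thresholding (density only).
- The λ reference uses connected null realizations only; on graphs where
  connectivity-preserving swaps are impossible (trees) the null ensemble
  fails loudly.
- NIfTI support is read-only, 3-D, and limited to summing a (modulated)
  gray-matter image over integer atlas labels; segmentation, normalization
  and smoothing are upstream of this package.
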