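# scnkit

Structural covariance network (SCN) analysis of regional brain volumes.

In morphometric studies, regions whose gray-matter volumes rise and fall
together across subjects are considered structurally connected: correlating
the volumes of N atlas regions across the subjects of a group yields an
N×N association matrix, and thresholding it at a fixed edge density gives a
binary brain graph per group. `scnkit` implements this pipeline end to end
for case-control designs — typically two groups of ~50 subjects on the
90-region AAL parcellation — and answers the questions such studies ask:

- **Network construction.** Total intracranial volume is regressed out of
  every region (per group), regions are correlated (Pearson), and graphs
  are built across a density grid *d* = 0.27…0.50 (step 0.01), starting at
  the smallest density at which both groups' networks are fully connected
  (the Dmin rule). Exactly round(d·N(N−1)/2) edges are kept at each density.
- **Graph metrics.** Clustering coefficient Cp, characteristic path length
  Lp, global and local efficiency, transitivity, degree assortativity,
  modularity Q, and nodal betweenness centrality normalized by the network
  mean. Cp and Lp are referenced to 20 degree-preserving random null
  networks (connected double-edge swaps): γ = Cp/Cp_rand, λ = Lp/Lp_rand,
  and the small-world index σ = γ/λ; γ > 1 with λ ≈ 1 or σ > 1 marks a
  small-world network.
- **Inference.** Non-parametric permutation tests (default 1,000
  relabelings) re-run the *entire* pipeline per permutation; metrics are
  compared per density and via the area under the metric–density curve
  (AUC), with two-tailed add-one p-values; the 90 regional betweenness
  tests are corrected with Benjamini–Hochberg FDR. Demographic matching is
  checked with chi-square / t / rank-sum tests.
- **Resilience.** Targeted attack (nodes removed in descending betweenness
  order) and random failure curves of the relative largest-component size,
  compared between groups with the same permutation engine.
- **Synthetic cohorts.** A generator draws two-group cohorts with known
  block-modular covariance, a group effect on covariance strength, a TIV
  confound and exactly matched demographics, so the whole pipeline is
  testable without patient data.

The permutation engine executes ~10⁵ graph-metric evaluations per
comparison; the graph kernels are numba-compiled (bitset BFS, compiled
double-edge swaps) so a full study-scale comparison takes seconds to
minutes, not hours.

## Worked example

`examples/group_comparison.py` generates a 49+49 × 90 cohort in which group
B's within-module covariance is weakened to 60% and compares the groups:

```
groups: ('A', 'B'), 199 permutations
metric       AUC A     AUC B  diff(B-A)       p
cp          0.1336    0.1220    -0.0116   0.035
lp          0.3430    0.3408    -0.0022   0.335
eglob       0.1455    0.1458    +0.0003   0.345
eloc        0.1703    0.1644    -0.0059   0.030
assort      0.0024   -0.0118    -0.0143   0.090
trans       0.1278    0.1170    -0.0108   0.020
q           0.0619    0.0238    -0.0381   0.005

regional betweenness: 0 of 90 regions significant after FDR
```

Each row is one global metric's area under its curve over densities
0.29–0.50 (0.29 is this cohort's Dmin) for each group, the B−A difference,
and the two-tailed permutation p-value: the weakened group shows
significantly lower clustering, local efficiency, transitivity and
modularity — the segregation metrics that live on within-module edges —
while path length and global efficiency (integration metrics) are
unaffected. `examples/small_world.py` prints the full metric battery for
one graph (γ = 1.72, σ = 1.66: clearly small-world), and
`examples/resilience.py` shows that the same covariance effect leaves
network resilience indistinguishable (targeted-attack AUC difference
−0.003, p = 0.92).

The other examples cover cohort simulation with matched demographics
(`simulate_cohort.py`) and network construction plus the Dmin rule
(`build_network.py`). For shell use, the same stages are exposed as a thin
CLI: `scnkit simulate | build | metrics | compare | resilience | run |
report` (exit codes: 0 ok, 2 config error, 3 data error), with `scnkit run
--config cfg.yaml` executing everything from a YAML config and writing
CSV result tables plus a run manifest. Identical config and seed reproduce
every output byte for byte.

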