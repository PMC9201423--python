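"""Network resilience: targeted attack vs random failure.

Removes nodes from a group-A network either in descending betweenness
order (targeted attack) or uniformly at random (failure, averaged over 50
orders) and tracks the relative size of the largest connected component.
Then compares the two groups' targeted-attack curves by permutation: a
covariance effect that spares the hub structure should leave resilience
indistinguishable (p > 0.05).
"""

from scnkit import (
    CohortSpec,
    DensityGrid,
    PermutationConfig,
    build_association,
    find_dmin,
    generate_cohort,
    random_failure_curve,
    residualize_tiv,
    resilience_comparison,
    targeted_attack_curve,
    threshold_by_density,
)

cohort = generate_cohort(CohortSpec(seed=1, effect_within_b=0.6))
assoc_a = build_association(residualize_tiv(cohort, "A"))
assoc_b = build_association(residualize_tiv(cohort, "B"))
dmin = find_dmin(assoc_a, assoc_b)
graph = threshold_by_density(assoc_a, dmin)

targeted = targeted_attack_curve(graph)
random_ = random_failure_curve(graph, n_iter=50, seed=3)
print(f"targeted-attack AUC: {targeted.auc():.4f}")
print(f"random-failure AUC:  {random_.auc():.4f}")
print("(attack <= failure: removing hubs first dismantles the network faster)")

cfg = PermutationConfig(
    n_perm=199, seed=4, densities=DensityGrid(max(0.27, dmin), 0.50, 0.01),
    global_metrics=("cp",), include_nodal=False,
)
res = resilience_comparison(cohort, cfg, mode="targeted")
print(
    f"\ntargeted attack, group comparison at density {res.reference_density}: "
    f"AUC diff (B-A) = {res.auc_diff:+.4f}, p = {res.auc_p:.3f}"
)
print("p > 0.05: the weakened-covariance group is as robust as the control group.")
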