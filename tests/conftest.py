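import numpy as np
import pytest

from scnkit import (
    CohortSpec,
    DensityGrid,
    build_association,
    find_dmin,
    generate_cohort,
    residualize_tiv,
)


def feasible_grid(cohort, step=0.02, span=0.10, d_max=0.5):
    """A short density grid that both groups' networks can support.

    Small noisy test cohorts often disconnect at low densities; following the
    Dmin rule, the grid starts one step above the smallest density that
    connects both groups (the margin absorbs permuted splits).
    """
    ga, gb = cohort.groups
    assoc_a = build_association(residualize_tiv(cohort, ga))
    assoc_b = build_association(residualize_tiv(cohort, gb))
    dmin = find_dmin(assoc_a, assoc_b, grid_step=step, d_max=d_max)
    d0 = round(min(dmin + step, d_max - step), 10)
    return DensityGrid(d0, round(min(d0 + span, d_max), 10), step)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 20-region cohort used by engine-level tests."""
    return generate_cohort(CohortSpec(n_group_a=20, n_group_b=20, n_regions=20, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default 49+49 x 90 study scale."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
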