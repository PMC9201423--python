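"""Permutation inference: AUC, FDR, p-value guarantees, demographics."""

import numpy as np
import pandas as pd
import pytest

from bruteforce import bf_bh

from scnkit import (
    CohortTable,
    ConfigError,
    DataError,
    DensityGrid,
    PermutationConfig,
    auc,
    bh_fdr,
    demographic_matching,
    permutation_test,
)

from conftest import feasible_grid

FAST_METRICS = ("cp", "lp", "eglob")


def _fast_cfg(cohort, **kw):
    base = dict(
        n_perm=30,
        seed=5,
        n_null=2,
        densities=feasible_grid(cohort),
        global_metrics=FAST_METRICS,
        include_nodal=True,
    )
    base.update(kw)
    return PermutationConfig(**base)


class TestAuc:
    def test_constant_curve_rectangle(self):
        grid = DensityGrid()
        assert auc(np.full(24, 2.0), grid) == pytest.approx(0.46)

    def test_linear_curve_triangle(self):
        grid = DensityGrid()
        assert auc(np.linspace(0, 1, 24), grid) == pytest.approx(0.115)

    def test_matches_fine_riemann_sum(self, rng):
        grid = DensityGrid()
        y = rng.random(24)
        # oracle: dense linear interpolation + left Riemann sum
        xs = grid.points
        fine = np.linspace(xs[0], xs[-1], 200_001)
        approx = np.interp(fine, xs, y)[:-1].sum() * (xs[-1] - xs[0]) / 200_000
        assert auc(y, grid) == pytest.approx(approx, abs=1e-6)

    def test_missing_point_rejected(self):
        with pytest.raises(DataError):
            auc(np.full(10, 1.0), DensityGrid())
        curve = np.full(24, 1.0)
        curve[3] = np.nan
        with pytest.raises(DataError, match="missing"):
            auc(curve, DensityGrid())


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        out = bh_fdr([0.005, 0.03, 0.04])
        assert np.allclose(out, [0.015, 0.04, 0.04])

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([])
        with pytest.raises(DataError):
            bh_fdr([0.0, 0.5])

    def test_matches_textbook_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bf_bh(p), atol=1e-12)
            assert (bh_fdr(p) >= p - 1e-12).all()


class TestPermutationTest:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            PermutationConfig(n_perm=0)
        with pytest.raises(ConfigError):
            PermutationConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            PermutationConfig(global_metrics=("cp", "bogus"))

    def test_duplicated_group_gives_p_one(self, small_cohort):
        """If group B is a copy of group A, every observed difference is 0
        and the add-one two-tailed rule returns exactly p = 1."""
        da = small_cohort.subjects_in("A").copy()
        db = da.copy()
        db["group"] = "B"
        db["subject_id"] = [f"B{i:03d}" for i in range(len(db))]
        twin = CohortTable(
            data=pd.concat([da, db], ignore_index=True), atlas=small_cohort.atlas
        )
        res = permutation_test(twin, _fast_cfg(twin))
        assert np.allclose(res.auc_diff, 0.0)
        assert (res.auc_p == 1.0).all()
        assert (res.per_density_p == 1.0).all()
        assert (res.nodal_p_raw == 1.0).all()

    def test_label_swap_symmetry(self, small_cohort):
        """Renaming the groups flips difference signs but not p-values."""
        res1 = permutation_test(small_cohort, _fast_cfg(small_cohort))
        flipped = small_cohort.data.copy()
        flipped["group"] = flipped["group"].map({"A": "Z", "B": "B"})
        cohort2 = CohortTable(data=flipped, atlas=small_cohort.atlas)
        res2 = permutation_test(cohort2, _fast_cfg(cohort2))
        assert np.allclose(res1.auc_diff, -res2.auc_diff)
        assert np.allclose(res1.auc_p, res2.auc_p)

    def test_add_one_lower_bound(self, small_cohort):
        res = permutation_test(small_cohort, _fast_cfg(small_cohort, n_perm=19))
        assert (res.auc_p >= 1 / 20 - 1e-12).all()
        assert (res.per_density_p > 0).all()

    def test_result_shapes_and_fdr_monotone(self, small_cohort):
        cfg = _fast_cfg(small_cohort)
        res = permutation_test(small_cohort, cfg)
        n_d = len(cfg.densities)
        assert res.curve_a.shape == (3, n_d)
        assert res.per_density_p.shape == (3, n_d)
        assert res.nodal_p_fdr.shape == (20,)
        assert (res.nodal_p_fdr >= res.nodal_p_raw - 1e-12).all()

    def test_deterministic_under_seed(self, small_cohort):
        r1 = permutation_test(small_cohort, _fast_cfg(small_cohort, seed=77))
        r2 = permutation_test(small_cohort, _fast_cfg(small_cohort, seed=77))
        assert np.array_equal(r1.auc_p, r2.auc_p)
        assert np.array_equal(r1.nodal_p_raw, r2.nodal_p_raw)


class TestDemographics:
    def test_matched_cohort_all_p_one(self, default_cohort):
        table = demographic_matching(default_cohort)
        by_var = table.set_index("variable")
        assert by_var.loc["sex", "statistic"] == 0.0
        assert by_var.loc["sex", "p"] == pytest.approx(1.0)
        assert by_var.loc["age", "statistic"] == pytest.approx(0.0)
        assert by_var.loc["age", "p"] == pytest.approx(1.0)
        assert by_var.loc["education", "p"] == pytest.approx(1.0)

    def test_chi_square_textbook_2x2(self, small_cohort):
        """Construct unbalanced sex counts and compare with the hand formula
        chi2 = sum (O-E)^2 / E on the 2x2 table."""
        df = small_cohort.data.copy()
        df["age"] = 40.0
        df["education"] = 2
        sex = np.array(["F"] * len(df), dtype=object)
        sex[(df["group"] == "A").to_numpy().nonzero()[0][:14]] = "M"
        sex[(df["group"] == "B").to_numpy().nonzero()[0][:6]] = "M"
        df["sex"] = sex
        cohort = CohortTable(data=df, atlas=small_cohort.atlas)
        table = demographic_matching(cohort).set_index("variable")
        obs = np.array([[14, 6], [6, 14]], dtype=float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert table.loc["sex", "statistic"] == pytest.approx(chi2_hand, abs=1e-10)

    def test_missing_column_named(self, small_cohort):
        df = small_cohort.data.drop(columns=["education"])
        cohort = CohortTable(data=df, atlas=small_cohort.atlas)
        with pytest.raises(DataError, match="education"):
            demographic_matching(cohort)
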