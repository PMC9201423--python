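"""Synthetic cohort generator: target covariance, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

from scnkit import (
    CohortSpec,
    CohortTable,
    ConfigError,
    DataError,
    build_target_covariance,
    generate_cohort,
    residualize_tiv,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r_within=0.2, r_between=0.5),  # r_between > r_within
            dict(r_within=1.0),
            dict(effect_within_b=0.0),
            dict(effect_within_b=2.0, r_within=0.6),  # product >= 1
            dict(n_group_a=2),
            dict(volume_sd=-1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CohortSpec(**kwargs)

    def test_module_assignment_length_checked(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_regions=10, module_assignment=np.zeros(9, dtype=int))


class TestTargetCovariance:
    def test_independence_case_is_diagonal(self):
        spec = CohortSpec(n_regions=6, r_within=0.0, r_between=0.0, volume_sd=1.3)
        cov = build_target_covariance(spec)
        assert np.allclose(cov, np.eye(6) * 1.3**2)

    def test_single_module_uniform_block(self):
        spec = CohortSpec(
            n_regions=3,
            module_assignment=np.zeros(3, dtype=int),
            r_within=0.7,
            r_between=0.0,
            volume_sd=2.0,
        )
        cov = build_target_covariance(spec)
        off = cov[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.7 * 4.0)
        assert np.allclose(np.diag(cov), 4.0)

    def test_two_block_pattern_is_psd(self):
        spec = CohortSpec(
            n_regions=6,
            module_assignment=np.repeat([0, 1], 3),
            r_within=0.6,
            r_between=0.1,
        )
        for group in ("A", "B"):
            cov = build_target_covariance(spec, group)
            w = np.linalg.eigvalsh(cov)
            assert w.min() >= -1e-8
            assert np.allclose(cov, cov.T)

    def test_group_b_scaling(self):
        spec = CohortSpec(
            n_regions=4,
            module_assignment=np.zeros(4, dtype=int),
            r_within=0.5,
            effect_within_b=0.6,
        )
        ca = build_target_covariance(spec, "A")
        cb = build_target_covariance(spec, "B")
        assert np.allclose(cb[0, 1] / ca[0, 1], 0.6)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=6))
        assert not a.data[a.atlas.labels[0]].equals(b.data[b.atlas.labels[0]])

    def test_volumes_positive_and_shapes(self, default_cohort):
        assert default_cohort.volumes().shape == (98, 90)
        assert (default_cohort.volumes() > 0).all()
        assert default_cohort.groups == ("A", "B")

    def test_demographics_exactly_matched(self, default_cohort):
        da = default_cohort.subjects_in("A")
        db = default_cohort.subjects_in("B")
        assert (da["age"].to_numpy() == db["age"].to_numpy()).all()
        assert (da["sex"].to_numpy() == db["sex"].to_numpy()).all()
        assert (da["education"].to_numpy() == db["education"].to_numpy()).all()

    def test_tiv_decoupled_when_beta_zero(self):
        spec = CohortSpec(
            n_group_a=20_000, n_group_b=3, n_regions=10, tiv_beta=0.0,
            include_demographics=False, seed=3,
        )
        cohort = generate_cohort(spec)
        vols = cohort.volumes("A")
        tiv = cohort.tiv("A")
        r = [np.corrcoef(vols[:, k], tiv)[0, 1] for k in range(10)]
        assert max(abs(np.asarray(r))) < 0.05

    def test_single_module_correlation_recovered(self):
        spec = CohortSpec(
            n_group_a=2000, n_group_b=3, n_regions=8,
            module_assignment=np.zeros(8, dtype=int), r_within=0.7,
            tiv_beta=0.0, include_demographics=False, seed=4,
        )
        vols = generate_cohort(spec).volumes("A")
        corr = np.corrcoef(vols.T)
        off = corr[~np.eye(8, dtype=bool)]
        assert abs(off.mean() - 0.7) < 0.03

    def test_parameter_recovery_after_residualization(self):
        """The TIV confound inflates raw correlations; regression removes it."""
        spec = CohortSpec(
            n_group_a=8000, n_group_b=3, n_regions=20,
            module_assignment=np.repeat([0, 1], 10),
            r_within=0.6, r_between=0.2, include_demographics=False, seed=9,
        )
        cohort = generate_cohort(spec)
        resid = residualize_tiv(cohort.volumes("A"), tiv=cohort.tiv("A"))
        corr = np.corrcoef(resid)
        target = np.where(
            np.repeat([0, 1], 10)[:, None] == np.repeat([0, 1], 10)[None, :], 0.6, 0.2
        )
        np.fill_diagonal(target, 1.0)
        np.fill_diagonal(corr, 1.0)
        assert np.abs(corr - target).max() < 0.05

    def test_cohort_table_validation(self, small_cohort):
        bad = small_cohort.data.copy()
        bad.loc[0, small_cohort.atlas.labels[0]] = -1.0
        with pytest.raises(DataError, match="positive"):
            CohortTable(data=bad, atlas=small_cohort.atlas)
        bad2 = small_cohort.data.copy()
        bad2.loc[0, "subject_id"] = bad2.loc[1, "subject_id"]
        with pytest.raises(DataError, match="duplicate"):
            CohortTable(data=bad2, atlas=small_cohort.atlas)
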