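"""TIV residualization, association matrices, density thresholding, Dmin."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scnkit import (
    AssociationMatrix,
    ConfigError,
    DataError,
    DensityGrid,
    build_association,
    edge_count_for_density,
    find_dmin,
    residualize_tiv,
    threshold_by_density,
)
from scnkit.network import rank_edges


def _assoc(values):
    return AssociationMatrix(values=np.asarray(values, dtype=float), n_subjects=10)


class TestDensityGrid:
    def test_default_grid_has_24_points(self):
        grid = DensityGrid()
        pts = grid.points
        assert len(pts) == 24
        assert pts[0] == 0.27 and pts[-1] == 0.50
        assert np.allclose(np.diff(pts), 0.01)

    def test_invalid_grid(self):
        with pytest.raises(ConfigError):
            DensityGrid(d_min=0.6, d_max=0.5)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        tiv = rng.normal(1500, 100, size=30)
        vols = np.outer(tiv, np.full(5, 2.0))  # every region exactly 2*TIV
        resid = residualize_tiv(vols, tiv=tiv)
        assert np.abs(resid).max() < 1e-9

    def test_residuals_uncorrelated_with_tiv(self, rng):
        tiv = rng.normal(1500, 100, size=2000)
        vols = rng.normal(7, 1, size=(2000, 4)) + 0.004 * tiv[:, None]
        resid = residualize_tiv(vols, tiv=tiv)
        assert np.abs(resid.mean(axis=1)).max() < 1e-9
        for k in range(4):
            assert abs(np.corrcoef(resid[k], tiv)[0, 1]) < 1e-9

    def test_constant_tiv_rejected(self, rng):
        with pytest.raises(DataError, match="constant"):
            residualize_tiv(rng.random((10, 3)), tiv=np.full(10, 1500.0))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(DataError, match="3 subjects"):
            residualize_tiv(rng.random((2, 3)), tiv=np.array([1.0, 2.0]))

    def test_tiv_unit_invariance(self, rng):
        """Association is unchanged by affine rescaling of TIV units."""
        tiv = rng.normal(1500, 100, size=40)
        vols = rng.normal(7, 1, size=(40, 6)) + 0.004 * tiv[:, None]
        a1 = build_association(residualize_tiv(vols, tiv=tiv)).values
        a2 = build_association(residualize_tiv(vols, tiv=tiv / 1000.0 + 3.0)).values
        assert np.allclose(a1, a2, atol=1e-12)


class TestAssociation:
    def test_duplicate_and_negated_regions(self, rng):
        base = rng.normal(size=20)
        resid = np.vstack([base, base.copy(), -base, rng.normal(size=20)])
        assoc = build_association(resid)
        assert assoc.values[0, 1] == pytest.approx(1.0)
        assert assoc.values[0, 2] == pytest.approx(-1.0)
        assert (np.diag(assoc.values) == 0).all()

    def test_hand_computed_pearson(self):
        # two centered 4-subject residual vectors, textbook formula
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([0.5, 0.5, 1.0, -2.0])
        y = y - y.mean()
        expected = (x @ y) / np.sqrt((x @ x) * (y @ y))
        assoc = build_association(np.vstack([x, y]))
        assert assoc.values[0, 1] == pytest.approx(expected, abs=1e-14)

    def test_zero_variance_region_named(self):
        resid = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DataError, match="zero-variance"):
            build_association(resid, labels=("flat", "ok"))


class TestThreshold:
    def test_edge_count_rule(self):
        assert edge_count_for_density(10, 0.27) == 12  # round(12.15)
        assert edge_count_for_density(90, 0.27) == 1081  # round(1081.35)
        assert edge_count_for_density(4, 0.25) == 2  # round-half-away: 1.5 -> 2

    def test_exact_count_and_saturation(self, rng):
        vals = rng.normal(size=(10, 10))
        vals = np.clip((vals + vals.T) / 2, -0.99, 0.99)
        np.fill_diagonal(vals, 0)
        g = threshold_by_density(_assoc(vals), 0.27)
        assert g.n_edges == 12
        full = threshold_by_density(_assoc(vals), 1.0)
        assert full.n_edges == 45

    def test_density_bounds(self, rng):
        vals = np.zeros((30, 30))
        with pytest.raises(ConfigError):
            threshold_by_density(_assoc(vals), 1.5)
        with pytest.raises(DataError, match="no edges"):
            threshold_by_density(_assoc(vals), 1e-4)

    def test_signed_vs_absolute_ranking(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = -0.95
        vals[2, 3] = vals[3, 2] = 0.5
        vals[0, 2] = vals[2, 0] = 0.1
        signed = threshold_by_density(_assoc(vals), 1 / 6 + 1e-9)
        assert signed.adjacency[2, 3] == 1 and signed.adjacency[0, 1] == 0
        absolute = threshold_by_density(_assoc(vals), 1 / 6 + 1e-9, mode="absolute")
        assert absolute.adjacency[0, 1] == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nested_edge_sets(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(12, 12))
        vals = np.clip((vals + vals.T) / 2, -0.99, 0.99)
        np.fill_diagonal(vals, 0)
        prev = None
        for d in (0.2, 0.35, 0.5, 0.8):
            g = threshold_by_density(_assoc(np.clip(vals, -1, 1)), d)
            if prev is not None:
                assert ((prev == 1) <= (g.adjacency == 1)).all()
            prev = g.adjacency


class TestDmin:
    def test_fully_tied_matrix_connects_via_tiebreak(self):
        """All-equal correlations: ties resolve by index, giving a star-like
        edge set; the first density with >= n-1 edges must connect."""
        n = 12
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 0)
        a = _assoc(vals)
        d = find_dmin(a, a, grid_step=0.01, d_max=0.5)
        # oracle: scan densities, check connectivity via scipy
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        expected = None
        for k in range(1, 51):
            dd = round(k * 0.01, 10)
            n_edges = edge_count_for_density(n, dd)
            if n_edges < 1:
                continue
            g = threshold_by_density(a, dd)
            ncomp, _ = connected_components(sp.csr_matrix(g.adjacency))
            if ncomp == 1:
                expected = dd
                break
        assert d == expected

    def test_two_block_instance(self):
        """Two 5-node blocks (r=0.9) with one 0.5 bridge: Dmin is the first
        grid density whose edge budget reaches the bridge's rank (21st)."""
        n = 10
        vals = np.full((n, n), 0.1)
        for blk in (range(5), range(5, 10)):
            for i in blk:
                for j in blk:
                    vals[i, j] = 0.9
        vals[0, 5] = vals[5, 0] = 0.5
        np.fill_diagonal(vals, 0)
        a = _assoc(vals)
        d = find_dmin(a, a, grid_step=0.01, d_max=0.5)
        assert edge_count_for_density(n, d) >= 21
        assert edge_count_for_density(n, round(d - 0.01, 10)) < 21

    def test_unreachable_dmax_raises(self):
        n = 8
        vals = np.full((n, n), 0.1)
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    vals[i, j] = 0.9
        np.fill_diagonal(vals, 0)
        a = _assoc(vals)  # two cliques, no bridge above 0.1 until late
        with pytest.raises(DataError, match="best density"):
            find_dmin(a, a, grid_step=0.01, d_max=0.25)


def test_rank_edges_deterministic_tie_break():
    vals = np.full((5, 5), 0.3)
    np.fill_diagonal(vals, 0)
    eu, ev = rank_edges(vals)
    assert (eu[0], ev[0]) == (0, 1)
    assert (eu[1], ev[1]) == (0, 2)
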