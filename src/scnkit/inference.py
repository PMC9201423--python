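"""Permutation inference for group differences in network metrics.

Group labels are randomly reassigned (group sizes preserved) and the entire
per-group pipeline — TIV residualization within group, Pearson association,
density thresholding across the grid, metric computation including the
null-normalized γ/λ/σ — is re-run for every permutation. Two-tailed p-values
use the add-one rule p = (1 + #{|Δperm| ≥ |Δobs|}) / (n_perm + 1), which is
exactly valid for finite permutation counts and guarantees p ≥ 1/(n_perm+1).
Differences are oriented as (second group − first group) in sorted label
order. Per-density tests are reported uncorrected; the 90 regional
betweenness tests are corrected with Benjamini–Hochberg FDR. AUC over the
density grid (trapezoidal) summarizes each metric robustly to threshold
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .errors import ConfigError, DataError
from .network import DensityGrid, edge_count_for_density, rank_edges, _residualize_arrays
from .synthetic import CohortTable

__all__ = [
    "GLOBAL_METRIC_NAMES",
    "PermutationConfig",
    "GroupComparisonResult",
    "auc",
    "bh_fdr",
    "permutation_test",
    "demographic_matching",
]

GLOBAL_METRIC_NAMES = (
    "cp",
    "lp",
    "eglob",
    "eloc",
    "assort",
    "trans",
    "q",
    "gamma",
    "lam",
    "sigma",
)

# kernel output columns (see _kernels.GLOBAL_COLS)
_COL = {name: i for i, name in enumerate(_kernels.GLOBAL_COLS)}


@dataclass
class PermutationConfig:
    """Settings shared by all permutation comparisons."""

    n_perm: int = 1000
    seed: int = 0
    densities: DensityGrid = field(default_factory=DensityGrid)
    n_null: int = 20
    alpha: float = 0.05
    threshold_mode: str = "signed"
    null_model: str = "degree_preserving"
    global_metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
    include_nodal: bool = True
    swap_multiplier: int = 10
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_null < 1:
            raise ConfigError("n_null must be >= 1")
        if self.threshold_mode not in ("signed", "absolute"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.null_model not in ("degree_preserving", "er"):
            raise ConfigError(f"unknown null_model {self.null_model!r}")
        unknown = set(self.global_metrics) - set(GLOBAL_METRIC_NAMES)
        if unknown:
            raise ConfigError(f"unknown global metrics: {sorted(unknown)}")
        self.global_metrics = tuple(self.global_metrics)


@dataclass
class GroupComparisonResult:
    """Observed curves, AUCs and permutation p-values for a two-group test."""

    groups: tuple[str, str]
    metric_names: tuple[str, ...]
    densities: np.ndarray
    curve_a: np.ndarray  # (n_metrics, n_densities)
    curve_b: np.ndarray
    per_density_p: np.ndarray
    auc_a: np.ndarray
    auc_b: np.ndarray
    auc_diff: np.ndarray  # B - A
    auc_p: np.ndarray
    region_labels: Optional[tuple[str, ...]] = None
    nodal_bc_a: Optional[np.ndarray] = None  # mean bc_norm over densities
    nodal_bc_b: Optional[np.ndarray] = None
    nodal_bc_diff: Optional[np.ndarray] = None
    nodal_p_raw: Optional[np.ndarray] = None
    nodal_p_fdr: Optional[np.ndarray] = None
    n_perm: int = 0
    seed: int = 0
    n_resampled: int = 0


def auc(curve: np.ndarray, densities: Union[DensityGrid, np.ndarray]) -> float:
    """Trapezoidal area under a metric curve over the density grid."""
    x = densities.points if isinstance(densities, DensityGrid) else np.asarray(densities)
    y = np.asarray(curve, dtype=np.float64)
    if y.shape[-1] != x.shape[0]:
        raise DataError(
            f"curve has {y.shape[-1]} points but the grid has {x.shape[0]}"
        )
    if np.isnan(y).any():
        raise DataError("curve has missing points")
    return float(np.trapezoid(y, x))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise DataError("bh_fdr needs at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation engine


def _group_curves(
    vols: np.ndarray,
    tiv: np.ndarray,
    cfg: PermutationConfig,
    null_seed: int,
    want_nodal: bool,
) -> tuple[np.ndarray, Optional[np.ndarray], bool]:
    """Metric curves for one (possibly permuted) group.

    Returns (global curves (n_sel, D), nodal mean bc_norm (n_regions,) or
    None, ok). ok is False when the graph is disconnected at the smallest
    density or a null ensemble fails.
    """
    resid = _residualize_arrays(vols, tiv)
    sd = resid.std(axis=1)
    if (sd <= 0).any():
        raise DataError(f"zero-variance regions: {np.flatnonzero(sd <= 0).tolist()}")
    corr = np.corrcoef(resid)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)

    n = corr.shape[0]
    eu, ev = rank_edges(corr, cfg.threshold_mode)
    points = cfg.densities.points
    edge_counts = np.array(
        [edge_count_for_density(n, d) for d in points], dtype=np.int64
    )
    sel = cfg.global_metrics
    need_nulls = bool({"gamma", "lam", "sigma"} & set(sel))
    want = np.zeros(8, dtype=np.uint8)
    want[_COL["cp"]] = ("cp" in sel) or ("gamma" in sel) or ("sigma" in sel)
    want[_COL["lp"]] = 1
    want[_COL["eglob"]] = "eglob" in sel
    want[_COL["eloc"]] = "eloc" in sel
    want[_COL["assort"]] = "assort" in sel
    want[_COL["trans"]] = "trans" in sel
    want[_COL["q"]] = "q" in sel
    want[7] = 1 if need_nulls else 0

    out, connected, status = _kernels.grid_global(
        eu.astype(np.int64),
        ev.astype(np.int64),
        n,
        edge_counts,
        want,
        cfg.n_null,
        cfg.swap_multiplier,
        int(null_seed),
    )
    out = np.asarray(out)
    if not connected[0] or status == 0.0:
        return np.empty(0), None, False

    curves = np.empty((len(sel), len(points)))
    for mi, name in enumerate(sel):
        if name == "gamma":
            curves[mi] = out[:, _COL["cp"]] / out[:, _COL["cprand"]]
        elif name == "lam":
            curves[mi] = out[:, _COL["lp"]] / out[:, _COL["lprand"]]
        elif name == "sigma":
            curves[mi] = (out[:, _COL["cp"]] / out[:, _COL["cprand"]]) / (
                out[:, _COL["lp"]] / out[:, _COL["lprand"]]
            )
        else:
            curves[mi] = out[:, _COL[name]]

    nodal = None
    if want_nodal:
        bc = np.asarray(
            _kernels.grid_betweenness(eu.astype(np.int64), ev.astype(np.int64), n, edge_counts)
        )
        means = bc.mean(axis=1, keepdims=True)
        norm = np.divide(bc, means, out=np.zeros_like(bc), where=means > 0)
        nodal = norm.mean(axis=0)
    return curves, nodal, True


EvalFn = Callable[[np.ndarray, np.ndarray, int, int], tuple[np.ndarray, bool, object]]


def _run_permutations(
    n_total: int,
    idx_a0: np.ndarray,
    idx_b0: np.ndarray,
    cfg: PermutationConfig,
    evaluate: EvalFn,
) -> tuple[np.ndarray, object, np.ndarray, int]:
    """Shared label-permutation loop with connectivity resampling.

    ``evaluate(idx_a, idx_b, seed_a, seed_b)`` returns (flat difference
    statistics, ok, extras); extras are kept from the observed call only.
    Subjects keep their table order, so for equal group sizes the two-tailed
    p-values are exactly invariant to swapping the group labels.
    Returns (observed stats, extras, add-one p-values, resample count).
    """
    n_a = len(idx_a0)
    rng = np.random.default_rng(cfg.seed)

    def draw_seeds() -> tuple[int, int]:
        s = rng.integers(0, 2**31 - 1, size=2)
        return int(s[0]), int(s[1])

    sa, sb = draw_seeds()
    obs, ok, extras = evaluate(idx_a0, idx_b0, sa, sb)
    if not ok:
        raise DataError(
            "observed groups are disconnected at the smallest density "
            "(or a null ensemble failed); raise d_min or check the data"
        )
    counts = np.zeros_like(obs)
    abs_obs = np.abs(obs)
    n_resampled = 0
    for _p in range(cfg.n_perm):
        for _attempt in range(cfg.max_resample):
            perm = rng.permutation(n_total)
            sa, sb = draw_seeds()
            stat, ok, _ = evaluate(perm[:n_a], perm[n_a:], sa, sb)
            if ok:
                break
            n_resampled += 1
        else:
            raise DataError(
                f"no connected permutation split found in {cfg.max_resample} tries"
            )
        a = np.abs(stat)
        counts += (a >= abs_obs) | np.isnan(a)
    p = (1.0 + counts) / (cfg.n_perm + 1.0)
    p[np.isnan(obs)] = np.nan
    return obs, extras, p, n_resampled


def permutation_test(cohort: CohortTable, config: PermutationConfig) -> GroupComparisonResult:
    """Full-pipeline permutation comparison of two groups.

    For the observed labels and each of ``n_perm`` random relabelings, both
    groups are re-residualized, re-correlated, re-thresholded across the
    density grid and re-measured; permuted splits that disconnect a graph at
    the smallest density are redrawn (bounded retries, count reported).
    """
    cfg = config
    ga, gb = cohort.groups
    grp = cohort.data["group"].astype(str).to_numpy()
    vols = cohort.volumes()
    tiv = cohort.tiv()
    idx_a0 = np.flatnonzero(grp == ga)
    idx_b0 = np.flatnonzero(grp == gb)
    if len(idx_a0) < 3 or len(idx_b0) < 3:
        raise DataError("each group needs at least 3 subjects")

    sel = cfg.global_metrics
    n_m = len(sel)
    points = cfg.densities.points
    n_d = len(points)
    n_regions = vols.shape[1]
    want_nodal = cfg.include_nodal

    def evaluate(idx_a, idx_b, seed_a, seed_b):
        ca, na, ok_a = _group_curves(vols[idx_a], tiv[idx_a], cfg, seed_a, want_nodal)
        if not ok_a:
            return np.empty(0), False, None
        cb, nb, ok_b = _group_curves(vols[idx_b], tiv[idx_b], cfg, seed_b, want_nodal)
        if not ok_b:
            return np.empty(0), False, None
        diff_curve = (cb - ca).ravel()
        auc_a_ = np.trapezoid(ca, points, axis=1)
        auc_b_ = np.trapezoid(cb, points, axis=1)
        parts = [diff_curve, auc_b_ - auc_a_]
        if want_nodal:
            parts.append(nb - na)
        extras = (ca, cb, auc_a_, auc_b_, na, nb)
        return np.concatenate(parts), True, extras

    obs, extras, p, n_resampled = _run_permutations(
        len(grp), idx_a0, idx_b0, cfg, evaluate
    )
    ca, cb, auc_a_, auc_b_, na, nb = extras

    pd_p = p[: n_m * n_d].reshape(n_m, n_d)
    auc_p_ = p[n_m * n_d : n_m * n_d + n_m]
    result = GroupComparisonResult(
        groups=(ga, gb),
        metric_names=sel,
        densities=points,
        curve_a=ca,
        curve_b=cb,
        per_density_p=pd_p,
        auc_a=auc_a_,
        auc_b=auc_b_,
        auc_diff=auc_b_ - auc_a_,
        auc_p=auc_p_,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        n_resampled=n_resampled,
    )
    if want_nodal:
        nodal_p = p[n_m * n_d + n_m :]
        result.region_labels = cohort.atlas.labels
        result.nodal_bc_a = na
        result.nodal_bc_b = nb
        result.nodal_bc_diff = nb - na
        result.nodal_p_raw = nodal_p
        result.nodal_p_fdr = bh_fdr(nodal_p) if not np.isnan(nodal_p).any() else nodal_p
    return result


# ---------------------------------------------------------------------------
# demographics


def demographic_matching(cohort: CohortTable) -> pd.DataFrame:
    """Between-group tests on demographics and TIV.

    Continuous variables (age, TIV) use Student's t-test, categorical (sex)
    the chi-square test, ordinal (education) the Wilcoxon rank-sum test.
    Returns a table with variable, test, statistic, df and p-value.
    """
    needed = ["age", "sex", "education"]
    missing = [c for c in needed if c not in cohort.data.columns]
    if missing:
        raise DataError(f"missing demographic columns: {missing}")
    ga, gb = cohort.groups
    da = cohort.subjects_in(ga)
    db = cohort.subjects_in(gb)
    rows = []

    for var in ("age", "tiv"):
        t, p = sps.ttest_ind(da[var], db[var])
        df = len(da) + len(db) - 2
        rows.append((var, "t", float(t), float(df), float(p)))

    table = pd.crosstab(cohort.data["group"], cohort.data["sex"])
    if table.shape[1] < 2:
        chi2, p, df = 0.0, 1.0, 0.0
    else:
        chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    rows.append(("sex", "chi2", float(chi2), float(df), float(p)))

    stat, p = sps.ranksums(da["education"], db["education"])
    rows.append(("education", "rank-sum", float(stat), float("nan"), float(p)))

    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "df", "p"])
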