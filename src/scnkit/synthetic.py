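"""Synthetic two-group morphometric cohorts with known covariance structure.

Real structural covariance studies correlate regional gray-matter volumes
across subjects within each group. This module emulates that data-generating
process: regional volumes are drawn from a group-specific multivariate normal
with a block-modular correlation structure (regions within a module covary at
``r_within``, across modules at ``r_between``), a multiplicative group effect
(``effect_within_b``) weakens or strengthens group B's within-module
covariance, and a shared total-intracranial-volume (TIV) confound couples all
regions to a per-subject TIV draw. Every downstream stage of the pipeline is
therefore testable against known ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, aal90, generic_atlas
from .errors import ConfigError, DataError

__all__ = ["CohortSpec", "CohortTable", "build_target_covariance", "generate_cohort"]

# Minimum eigenvalue used when repairing marginally non-PSD block-correlation
# targets, and the tolerance below which the repair is considered failed.
_EIG_FLOOR = 1e-10
_EIG_TOL = -1e-8


# Default community-size profile (fractions of the region count). Real
# parcellations have heterogeneous community sizes, and degree-based metrics
# (assortativity above all) carry no group signal when every module is the
# same size, so the default is deliberately skewed: [32, 24, 18, 16] regions
# at the 90-region default.
_MODULE_FRACTIONS = np.array([32, 24, 18, 16], dtype=np.float64) / 90.0


def _default_modules(n_regions: int) -> np.ndarray:
    """Contiguous modules following the default heterogeneous size profile."""
    sizes = np.floor(_MODULE_FRACTIONS * n_regions).astype(np.int64)
    sizes = np.maximum(sizes, 1)
    while sizes.sum() < n_regions:
        sizes[np.argmax(_MODULE_FRACTIONS * n_regions - sizes)] += 1
    while sizes.sum() > n_regions:  # pragma: no cover - tiny n_regions only
        sizes[np.argmax(sizes)] -= 1
    return np.repeat(np.arange(len(sizes)), sizes)


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror the scale of a 49-vs-49 subject, 90-region study, with
    four covariance modules of heterogeneous size (32/24/18/16 regions).
    r_between = r_within * 0.6, so the default group effect (0.6) erases
    group B's within-module excess covariance entirely - the cleanest form
    of "more randomized" network organization.
    TIV distribution parameters are in mL and follow the magnitude reported
    for adult cohorts (≈1480 ± 125 mL); ``tiv_beta`` is the per-region slope
    (mL regional volume per mL TIV) of the shared confound that TIV
    residualization must remove.
    """

    n_group_a: int = 49
    n_group_b: int = 49
    n_regions: int = 90
    module_assignment: Optional[np.ndarray] = None
    r_within: float = 0.60
    r_between: float = 0.36
    effect_within_b: float = 1.0
    volume_mean: float = 7.0
    volume_sd: float = 0.9
    tiv_mean: float = 1480.0
    tiv_sd: float = 125.0
    tiv_beta: float = 0.005
    include_demographics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 3 or self.n_group_b < 3:
            raise ConfigError("each group needs at least 3 subjects")
        if self.n_regions < 2:
            raise ConfigError("need at least 2 regions")
        if not (0.0 <= self.r_between <= self.r_within < 1.0):
            raise ConfigError(
                f"require 0 <= r_between <= r_within < 1, got "
                f"r_between={self.r_between}, r_within={self.r_within}"
            )
        if self.effect_within_b <= 0.0:
            raise ConfigError("effect_within_b must be positive")
        if self.effect_within_b * self.r_within >= 1.0:
            raise ConfigError(
                f"effect_within_b * r_within = "
                f"{self.effect_within_b * self.r_within:.3f} must be < 1"
            )
        if self.volume_mean <= 0 or self.volume_sd <= 0:
            raise ConfigError("volume_mean and volume_sd must be positive")
        if self.tiv_sd <= 0:
            raise ConfigError("tiv_sd must be positive")
        if self.module_assignment is None:
            self.module_assignment = _default_modules(self.n_regions)
        else:
            self.module_assignment = np.asarray(self.module_assignment, dtype=np.int64)
        if self.module_assignment.shape != (self.n_regions,):
            raise ConfigError(
                "module_assignment must assign every region to exactly one module "
                f"(expected length {self.n_regions}, got {self.module_assignment.shape})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_assignment"] = [int(m) for m in self.module_assignment]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("module_assignment") is not None:
            d["module_assignment"] = np.asarray(d["module_assignment"], dtype=np.int64)
        return cls(**d)


@dataclass
class CohortTable:
    """Per-subject regional volumes plus TIV, group label and demographics.

    ``data`` holds one row per subject with columns ``subject_id``, ``group``,
    ``tiv``, optional demographics (``age``, ``sex``, ``education``) and then
    one column per region in atlas order.
    """

    data: pd.DataFrame
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "tiv"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"cohort table missing columns: {sorted(missing)}")
        missing_regions = [l for l in self.atlas.labels if l not in self.data.columns]
        if missing_regions:
            raise DataError(f"cohort table missing region columns: {missing_regions}")
        if self.data["subject_id"].duplicated().any():
            dupes = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise DataError(f"duplicate subject ids: {sorted(set(dupes))}")
        levels = sorted(self.data["group"].astype(str).unique())
        if len(levels) != 2:
            raise DataError(
                f"group column must have exactly two levels, got {levels}"
            )
        vols = self.data[list(self.atlas.labels)].to_numpy()
        if not np.issubdtype(vols.dtype, np.number):
            raise DataError("region volume columns must be numeric")
        if not (vols > 0).all():
            bad = np.argwhere(~(vols > 0))[0]
            raise DataError(
                f"volumes must be strictly positive; first offender at subject row "
                f"{bad[0]}, region {self.atlas.labels[bad[1]]}"
            )

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(sorted(self.data["group"].astype(str).unique()))  # type: ignore[return-value]

    @property
    def n_regions(self) -> int:
        return self.atlas.size

    def subjects_in(self, group: str) -> pd.DataFrame:
        return self.data.loc[self.data["group"].astype(str) == str(group)]

    def volumes(self, group: Optional[str] = None) -> np.ndarray:
        """(n_subjects, n_regions) volume matrix, atlas column order."""
        df = self.data if group is None else self.subjects_in(group)
        return df[list(self.atlas.labels)].to_numpy(dtype=np.float64)

    def tiv(self, group: Optional[str] = None) -> np.ndarray:
        df = self.data if group is None else self.subjects_in(group)
        return df["tiv"].to_numpy(dtype=np.float64)

    @property
    def has_demographics(self) -> bool:
        return {"age", "sex", "education"}.issubset(self.data.columns)


def _target_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    modules = spec.module_assignment
    same = modules[:, None] == modules[None, :]
    r_w = spec.r_within * (spec.effect_within_b if group == "B" else 1.0)
    corr = np.where(same, r_w, spec.r_between)
    np.fill_diagonal(corr, 1.0)
    return corr


def _repair_psd(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w[0] >= 0.0:
        return corr
    w = np.clip(w, _EIG_FLOOR, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    w2 = np.linalg.eigvalsh(fixed)
    if w2[0] < _EIG_TOL:
        raise DataError(
            f"correlation target not positive semi-definite after repair "
            f"(minimum eigenvalue {w2[0]:.3e})"
        )
    return fixed


def build_target_covariance(spec: CohortSpec, group: str = "A") -> np.ndarray:
    """Region×region covariance implied by the block-correlation target.

    Within-module correlations are ``r_within`` (× ``effect_within_b`` for
    group B), between-module correlations ``r_between``; the diagonal is
    ``volume_sd**2``. Marginally non-PSD block patterns are repaired by
    eigenvalue clipping.
    """
    if group not in ("A", "B"):
        raise ConfigError(f"group must be 'A' or 'B', got {group!r}")
    corr = _repair_psd(_target_correlation(spec, group))
    return corr * spec.volume_sd**2


def _matched_demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics for one group; both groups receive identical copies.

    Marginals echo a typical adult cohort: age ≈ N(44.7, 11.1) truncated at
    18, ~45% male, four ordinal education levels.
    """
    age = np.clip(rng.normal(44.67, 11.06, size=n), 18.0, None).round(1)
    n_male = int(round(n * 22 / 49))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    edu_counts = np.floor(n * np.array([3, 15, 15, 16]) / 49).astype(int)
    while edu_counts.sum() < n:
        edu_counts[np.argmax([3, 15, 15, 16])] += 1
        if edu_counts.sum() > n:  # pragma: no cover - defensive
            edu_counts[np.argmax(edu_counts)] -= 1
    education = np.repeat(np.arange(1, 5), edu_counts)[:n]
    return pd.DataFrame({"age": age, "sex": sex, "education": education})


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a deterministic two-group cohort from the spec.

    TIV ~ N(tiv_mean, tiv_sd²) per subject; regional volumes are multivariate
    normal around ``volume_mean`` with the group's target covariance, plus
    ``tiv_beta × (tiv − tiv_mean)`` added to every region. Volumes are clamped
    at 1% of ``volume_mean`` so sample sizes stay exact. The same seed always
    yields a bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = aal90() if spec.n_regions == 90 else generic_atlas(spec.n_regions)

    frames = []
    demo: Optional[pd.DataFrame] = None
    if spec.include_demographics:
        if spec.n_group_a != spec.n_group_b:
            raise ConfigError(
                "exactly matched demographics require equal group sizes; "
                "set include_demographics=False for unequal groups"
            )
        demo = _matched_demographics(spec.n_group_a, rng)

    for group, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        cov = build_target_covariance(spec, group)
        w, v = np.linalg.eigh(cov)
        factor = v * np.sqrt(np.clip(w, 0.0, None))
        tiv = rng.normal(spec.tiv_mean, spec.tiv_sd, size=n)
        z = rng.standard_normal((n, spec.n_regions))
        vols = spec.volume_mean + z @ factor.T
        vols = vols + spec.tiv_beta * (tiv - spec.tiv_mean)[:, None]
        vols = np.maximum(vols, 0.01 * spec.volume_mean)
        frame = pd.DataFrame(vols, columns=list(atlas.labels))
        frame.insert(0, "tiv", tiv)
        frame.insert(0, "group", group)
        frame.insert(0, "subject_id", [f"{group}{i + 1:03d}" for i in range(n)])
        if demo is not None:
            for col in ("education", "sex", "age"):
                frame.insert(3, col, demo[col].to_numpy())
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data=data, atlas=atlas)
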