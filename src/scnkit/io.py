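"""On-disk artifacts: volume tables, NIfTI ROI extraction, result tables.

All tables are comma-separated UTF-8 with a mandatory header and "." decimal
point. Region columns always follow the atlas order, whatever their order on
disk. NIfTI support is read-only and limited to 3-D images: regional volume
is the sum of the (modulated) gray-matter image over the voxels carrying the
region's integer label, times the voxel volume, in mL.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .errors import DataError
from .inference import GroupComparisonResult
from .network import AssociationMatrix, BinaryGraph
from .resilience import ResilienceComparisonResult
from .synthetic import CohortTable

__all__ = [
    "read_volume_table",
    "write_volume_table",
    "extract_roi_volumes",
    "write_results",
    "RESULT_FILES",
]

_META_COLS = ("subject_id", "group", "tiv", "age", "sex", "education")

RESULT_FILES = (
    "manifest.json",
    "global_curves_a.csv",
    "global_curves_b.csv",
    "global_per_density_p.csv",
    "global_auc.csv",
    "nodal_bc.csv",
    "resilience_targeted.csv",
    "resilience_random.csv",
    "resilience_auc.csv",
)


def write_volume_table(cohort: CohortTable, path: Union[str, Path]) -> None:
    """Write a cohort as CSV: subject_id, group, tiv, [demographics], regions."""
    cols = [c for c in _META_COLS if c in cohort.data.columns]
    cols += list(cohort.atlas.labels)
    cohort.data[cols].to_csv(path, index=False)


def read_volume_table(path: Union[str, Path], atlas: RegionAtlas) -> CohortTable:
    """Read a volume table, matching region columns to the atlas by label.

    Columns may appear in any order on disk; they are reordered to the atlas
    order. Raises on missing region columns, non-numeric volumes, duplicate
    subject ids or a group column without exactly two levels.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume table not found: {path}")
    df = pd.read_csv(path)
    missing = [l for l in atlas.labels if l not in df.columns]
    if missing:
        raise DataError(f"volume table missing region columns: {missing}")
    for lab in atlas.labels:
        if not np.issubdtype(df[lab].dtype, np.number):
            bad = df[pd.to_numeric(df[lab], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else -1
            raise DataError(f"non-numeric volume in column {lab!r}, row {row}")
    cols = [c for c in _META_COLS if c in df.columns] + list(atlas.labels)
    return CohortTable(data=df[cols].copy(), atlas=atlas)


def extract_roi_volumes(
    gm_image: Union[str, Path],
    atlas_image: Union[str, Path],
    atlas: RegionAtlas,
) -> np.ndarray:
    """Regional volumes (mL) from a gray-matter image and an integer label image.

    Region k (1-based, following atlas order) gets the sum of the gray-matter
    image over voxels labeled k, times the voxel volume. Label 0 is
    background; labels beyond the atlas size are an error.
    """
    import nibabel as nib

    gm = nib.load(str(gm_image))
    lab = nib.load(str(atlas_image))
    gm_data = np.asarray(gm.dataobj, dtype=np.float64)
    lab_data = np.asarray(lab.dataobj)
    if gm_data.ndim != 3 or lab_data.ndim != 3:
        raise DataError(
            f"only 3-D images are supported, got shapes {gm_data.shape} and {lab_data.shape}"
        )
    if gm_data.shape != lab_data.shape:
        raise DataError(
            f"image grids differ: gray-matter {gm_data.shape} vs atlas {lab_data.shape}"
        )
    labels_int = np.rint(lab_data).astype(np.int64)
    max_label = int(labels_int.max()) if labels_int.size else 0
    if max_label > atlas.size or labels_int.min() < 0:
        raise DataError(
            f"atlas image labels run to {max_label} but the atlas has {atlas.size} regions"
        )
    voxel_ml = float(abs(np.linalg.det(gm.affine[:3, :3]))) / 1000.0
    sums = np.bincount(
        labels_int.ravel(), weights=gm_data.ravel(), minlength=atlas.size + 1
    )
    return sums[1 : atlas.size + 1] * voxel_ml


# ---------------------------------------------------------------------------
# results


def _curves_frame(result: GroupComparisonResult, which: str) -> pd.DataFrame:
    curves = result.curve_a if which == "a" else result.curve_b
    df = pd.DataFrame({"density": result.densities})
    for mi, name in enumerate(result.metric_names):
        df[name] = curves[mi]
    return df


def write_adjacency(
    graph: BinaryGraph, atlas: RegionAtlas, path: Union[str, Path]
) -> None:
    df = pd.DataFrame(graph.adjacency, index=atlas.labels, columns=atlas.labels)
    df.to_csv(path, index_label="region")


def write_association(
    assoc: AssociationMatrix, atlas: RegionAtlas, path: Union[str, Path]
) -> None:
    df = pd.DataFrame(assoc.values, index=atlas.labels, columns=atlas.labels)
    df.to_csv(path, index_label="region")


def write_results(
    comparison: GroupComparisonResult,
    resilience: Mapping[str, ResilienceComparisonResult],
    atlas: RegionAtlas,
    out_dir: Union[str, Path],
    manifest: Optional[dict] = None,
    adjacencies: Optional[Mapping[str, BinaryGraph]] = None,
    associations: Optional[Mapping[str, AssociationMatrix]] = None,
) -> Path:
    """Write the full result bundle as CSV/JSON files; returns the directory.

    Files: per-density global metric curves per group, per-density p-values,
    the AUC table with p-values, the nodal betweenness table with raw and
    FDR-adjusted p-values, resilience curves with per-fraction p-values and
    their AUC table, optional Dmin adjacency/association matrices, and a run
    manifest.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"cannot write to results directory {out}: {exc}") from exc

    ga, gb = comparison.groups
    _curves_frame(comparison, "a").to_csv(out / "global_curves_a.csv", index=False)
    _curves_frame(comparison, "b").to_csv(out / "global_curves_b.csv", index=False)

    pdf = pd.DataFrame({"density": comparison.densities})
    for mi, name in enumerate(comparison.metric_names):
        pdf[name] = comparison.per_density_p[mi]
    pdf.to_csv(out / "global_per_density_p.csv", index=False)

    pd.DataFrame(
        {
            "metric": comparison.metric_names,
            f"auc_{ga}": comparison.auc_a,
            f"auc_{gb}": comparison.auc_b,
            "auc_diff": comparison.auc_diff,
            "p": comparison.auc_p,
        }
    ).to_csv(out / "global_auc.csv", index=False)

    if comparison.nodal_bc_a is not None:
        nodal = pd.DataFrame(
            {
                "region": comparison.region_labels,
                f"bc_norm_{ga}": comparison.nodal_bc_a,
                f"bc_norm_{gb}": comparison.nodal_bc_b,
                "diff": comparison.nodal_bc_diff,
                "p_raw": comparison.nodal_p_raw,
                "p_fdr": comparison.nodal_p_fdr,
            }
        )
    else:
        nodal = pd.DataFrame(
            columns=["region", f"bc_norm_{ga}", f"bc_norm_{gb}", "diff", "p_raw", "p_fdr"]
        )
    nodal.to_csv(out / "nodal_bc.csv", index=False)

    auc_rows = []
    for mode in ("targeted", "random"):
        res = resilience.get(mode)
        if res is None:
            pd.DataFrame(
                columns=["fraction_removed", f"rel_lcc_{ga}", f"rel_lcc_{gb}", "p"]
            ).to_csv(out / f"resilience_{mode}.csv", index=False)
            continue
        pd.DataFrame(
            {
                "fraction_removed": res.fraction_removed,
                f"rel_lcc_{ga}": res.curve_a,
                f"rel_lcc_{gb}": res.curve_b,
                "p": res.per_fraction_p,
            }
        ).to_csv(out / f"resilience_{mode}.csv", index=False)
        auc_rows.append(
            (mode, res.reference_density, res.auc_a, res.auc_b, res.auc_diff, res.auc_p)
        )
    pd.DataFrame(
        auc_rows,
        columns=["mode", "reference_density", f"auc_{ga}", f"auc_{gb}", "auc_diff", "p"],
    ).to_csv(out / "resilience_auc.csv", index=False)

    for name, graph in (adjacencies or {}).items():
        write_adjacency(graph, atlas, out / f"adjacency_{name}.csv")
    for name, assoc in (associations or {}).items():
        write_association(assoc, atlas, out / f"association_{name}.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)
    return out
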