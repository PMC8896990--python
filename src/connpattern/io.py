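"""Cohort TSV reading and writing.

The on-disk dialect is deliberately plain: one TSV per subject-session
(columns = the 10 storage ROI names, rows = volumes), a cohort manifest
TSV naming each file with its metadata, and in voxel mode one TSV per
ROI referenced from the manifest via a filename pattern.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityPattern
from .rois import STORAGE_ROIS, SUBSET_MASKS
from .timeseries import ROITimeSeriesSet

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "lesion_side",
    "week",
    "tr_seconds",
    "path",
    "voxel_path_pattern",
)


def write_cohort(cohort: Iterable[ROITimeSeriesSet], out_dir: str | Path) -> Path:
    """Write session TSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        stem = f"{ts.subject_id}_{ts.week}"
        rel = f"{stem}_bold.tsv"
        frame = pd.DataFrame(ts.data, columns=list(ts.roi_names))
        frame.to_csv(out_dir / rel, sep="\t", index=False, float_format="%.10g")
        voxel_pattern = ""
        if ts.voxel_data is not None:
            voxel_pattern = f"{stem}_voxels_{{roi}}.tsv"
            for roi, matrix in ts.voxel_data.items():
                cols = [f"v{j:03d}" for j in range(matrix.shape[1])]
                pd.DataFrame(matrix, columns=cols).to_csv(
                    out_dir / voxel_pattern.format(roi=roi),
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
        rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "lesion_side": ts.lesion_side,
                "week": ts.week,
                "tr_seconds": ts.tr_seconds,
                "path": rel,
                "voxel_path_pattern": voxel_pattern,
            }
        )
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def read_manifest(
    manifest_path: str | Path, load_voxels: bool = False
) -> list[ROITimeSeriesSet]:
    """Load every subject-session referenced by a cohort manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, sep="\t", dtype={"voxel_path_pattern": str})
    missing_cols = set(MANIFEST_COLUMNS[:6]) - set(table.columns)
    if missing_cols:
        raise ValueError(f"manifest is missing column(s): {sorted(missing_cols)}")
    cohort = []
    for row in table.itertuples(index=False):
        path = base / row.path
        if not path.exists():
            raise FileNotFoundError(
                f"missing session file for {row.subject_id} {row.week}: {path}"
            )
        frame = pd.read_csv(path, sep="\t")
        if list(frame.columns) != list(STORAGE_ROIS):
            raise ValueError(
                f"{path}: expected ROI columns {list(STORAGE_ROIS)}, "
                f"got {list(frame.columns)}"
            )
        voxel_data = None
        pattern = getattr(row, "voxel_path_pattern", "") or ""
        if load_voxels and isinstance(pattern, str) and pattern:
            voxel_data = {}
            for roi in STORAGE_ROIS:
                vpath = base / pattern.format(roi=roi)
                if not vpath.exists():
                    raise FileNotFoundError(
                        f"missing voxel file for {row.subject_id} {row.week}: {vpath}"
                    )
                voxel_data[roi] = pd.read_csv(vpath, sep="\t").to_numpy(dtype=float)
        cohort.append(
            ROITimeSeriesSet(
                subject_id=str(row.subject_id),
                group=str(row.group),
                lesion_side=str(row.lesion_side),
                week=str(row.week),
                tr_seconds=float(row.tr_seconds),
                data=frame.to_numpy(dtype=float),
                voxel_data=voxel_data,
            )
        )
    return cohort


def weights_long_table(patterns: Sequence[ConnectivityPattern]) -> pd.DataFrame:
    """Long-format weight table (one row per subject-session-pair)."""
    subset_of = np.full(45, "", dtype=object)
    for name, mask in SUBSET_MASKS.items():
        if name == "full":
            continue
        subset_of[mask] = name
    rows = []
    for p in patterns:
        for k, (roi_a, roi_b) in enumerate(p.pair_labels):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": p.group,
                    "week": p.week,
                    "roiA": roi_a,
                    "roiB": roi_b,
                    "subset": subset_of[k],
                    "z": p.weights[k],
                }
            )
    return pd.DataFrame(rows)
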