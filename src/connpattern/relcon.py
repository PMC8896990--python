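"""Voxelwise relative interhemispheric connectivity (RelCon) of SM1.

The numerator is the mean Pearson correlation over all cross-hemisphere
voxel pairs of sensorimotor cortex (SM1 = union of S1 and M1 voxels);
the denominator is the mean over all distinct within-ipsilesional voxel
pairs (self-correlations excluded). RelCon is their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import fisher_z
from .timeseries import ROITimeSeriesSet

#: Denominators smaller than this are considered unstable.
MIN_WITHIN_MEAN = 1e-6


@dataclass(frozen=True)
class RelConResult:
    subject_id: str
    week: str
    inter_mean: float
    within_mean: float
    relcon: float


def relcon(
    voxels_ipsi: np.ndarray,
    voxels_contra: np.ndarray,
    subject_id: str = "",
    week: str = "",
    fisher_average: bool = False,
) -> RelConResult:
    """RelCon from two T x V voxel time-series matrices.

    With ``fisher_average`` the voxel-pair correlations are averaged in
    Fisher-Z space and back-transformed (an option; the default averages
    raw correlations).
    """
    a = np.asarray(voxels_ipsi, dtype=float)
    b = np.asarray(voxels_contra, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("voxel matrices must be 2D (volumes x voxels)")
    if a.shape[0] != b.shape[0]:
        raise ValueError("hemisphere voxel matrices disagree on scan length")
    t, v1 = a.shape
    v2 = b.shape[1]
    if t < 3:
        raise ValueError("need at least 3 volumes")
    if v1 < 2:
        raise ValueError("need >= 2 ipsilesional voxels (within-mean undefined)")
    if v2 < 1:
        raise ValueError("need >= 1 contralesional voxel")
    if np.any(a.var(axis=0) == 0.0) or np.any(b.var(axis=0) == 0.0):
        raise ValueError("zero-variance voxel series")

    corr = np.corrcoef(np.hstack([a, b]), rowvar=False)
    cross = corr[:v1, v1:]
    iu = np.triu_indices(v1, k=1)
    within = corr[:v1, :v1][iu]
    if fisher_average:
        inter_mean = float(np.tanh(np.mean(fisher_z(cross))))
        within_mean = float(np.tanh(np.mean(fisher_z(within))))
    else:
        inter_mean = float(cross.mean())
        within_mean = float(within.mean())
    if abs(within_mean) < MIN_WITHIN_MEAN:
        raise ValueError(
            f"within-hemisphere mean correlation {within_mean:.2e} too close "
            "to zero for a stable RelCon ratio"
        )
    return RelConResult(
        subject_id=subject_id,
        week=week,
        inter_mean=inter_mean,
        within_mean=within_mean,
        relcon=inter_mean / within_mean,
    )


def sm1_voxels(ts: ROITimeSeriesSet, hemisphere: str) -> np.ndarray:
    """Stack S1 and M1 voxel series of one anatomical hemisphere (L/R)."""
    if ts.voxel_data is None:
        raise ValueError(f"{ts.subject_id} {ts.week}: no voxel-level data")
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    return np.hstack([ts.voxel_data[f"S1_{hemisphere}"], ts.voxel_data[f"M1_{hemisphere}"]])


def relcon_from_timeseries(ts: ROITimeSeriesSet, fisher_average: bool = False) -> RelConResult:
    """RelCon of SM1 for one subject-session, ipsilesional denominator.

    Controls (no lesion) use the left hemisphere as the reference
    'ipsilesional' block, mirroring the pattern-vectorization convention.
    """
    ipsi = "R" if ts.lesion_side == "right" else "L"
    contra = "L" if ipsi == "R" else "R"
    return relcon(
        sm1_voxels(ts, ipsi),
        sm1_voxels(ts, contra),
        subject_id=ts.subject_id,
        week=ts.week,
        fisher_average=fisher_average,
    )
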