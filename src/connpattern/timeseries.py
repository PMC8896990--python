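"""ROI-level BOLD time-series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rois import STORAGE_ROIS


@dataclass
class ROITimeSeriesSet:
    """One subject-session's T x 10 matrix of ROI-averaged BOLD samples.

    ``data`` columns follow ``roi_names`` (anatomical left/right storage
    order by default); hemisphere alignment to the ipsilesional block is
    performed downstream when the connectivity pattern is computed.
    ``voxel_data`` optionally maps an ROI name to its T x V voxel matrix.
    """

    subject_id: str
    group: str  # "patient" | "control"
    lesion_side: str  # "left" | "right" | "none"
    week: str
    tr_seconds: float
    data: np.ndarray
    roi_names: tuple[str, ...] = STORAGE_ROIS
    voxel_data: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"data must be T x {len(self.roi_names)}, got {self.data.shape}"
            )
        if len(self.roi_names) != 10:
            raise ValueError("exactly 10 ROI columns are required")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 volumes per scan")
        variances = self.data.var(axis=0)
        dead = [n for n, v in zip(self.roi_names, variances) if v == 0.0]
        if dead:
            raise ValueError(f"zero-variance ROI column(s): {', '.join(dead)}")
        if self.group == "patient" and self.lesion_side not in ("left", "right"):
            raise ValueError("patients must have lesion_side 'left' or 'right'")
        if self.group == "control" and self.lesion_side != "none":
            raise ValueError("controls must have lesion_side 'none'")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]
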