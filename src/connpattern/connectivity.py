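"""Fisher-Z ROI-pair connectivity patterns.

Pairwise Pearson correlations between the 10 ROI time courses are
Fisher-Z transformed and vectorized as the upper triangle of the
10 x 10 connectivity matrix, giving 45 weights per subject-session:
10 intrahemispheric pairs per hemisphere plus 25 interhemispheric
pairs. Hemisphere blocks are aligned so block 1 is ipsilesional for
patients and the fixed reference (left) hemisphere for controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import rois
from .rois import (
    HETEROLOGOUS_MASK,
    N_PAIRS,
    PAIR_INDICES,
    PAIR_LABELS,
    SUBSET_MASKS,
    pair_index,
    storage_to_canonical_order,
)
from .timeseries import ROITimeSeriesSet

#: Clamp threshold for degenerate (near ±1) correlations.
CLAMP_EPS = 1e-7

SUBSETS = ("full", "intra_ipsilesional", "intra_contralesional", "interhemispheric")


@dataclass
class ConnectivityPattern:
    """Vectorized Fisher-Z connectivity pattern for one subject-session."""

    weights: np.ndarray
    subject_id: str = ""
    group: str = ""
    week: str = ""
    pair_labels: tuple[tuple[str, str], ...] = PAIR_LABELS
    subset_masks: Mapping[str, np.ndarray] = field(default_factory=lambda: SUBSET_MASKS)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_PAIRS,):
            raise ValueError(f"expected {N_PAIRS} weights, got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectivity weights must be finite")

    def subset(self, name: str) -> np.ndarray:
        """Weights restricted to a named subset (copy)."""
        try:
            mask = self.subset_masks[name]
        except KeyError as exc:
            raise KeyError(
                f"unknown subset {name!r}; expected one of {SUBSETS}"
            ) from exc
        return self.weights[mask]


def fisher_z(r):
    """Fisher-Z transform (arctanh) of a correlation coefficient.

    Values with ``|r| >= 1 - 1e-7`` are clamped with a warning rather than
    raising, so degenerate near-duplicate series degrade gracefully.
    """
    r = np.asarray(r, dtype=float)
    limit = 1.0 - CLAMP_EPS
    if np.any(np.abs(r) > limit):
        warnings.warn(
            "correlation(s) at or beyond +/-1 clamped before Fisher-Z",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -limit, limit)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compute_pattern(ts: ROITimeSeriesSet) -> ConnectivityPattern:
    """Fisher-Z connectivity pattern of one subject-session.

    Columns are permuted so hemisphere block 1 is ipsilesional before the
    upper triangle is vectorized in canonical pair order.
    """
    variances = ts.data.var(axis=0)
    dead = [n for n, v in zip(ts.roi_names, variances) if v == 0.0]
    if dead:
        raise ValueError(f"zero-variance ROI column(s): {', '.join(dead)}")
    perm = storage_to_canonical_order(ts.lesion_side)
    aligned = ts.data[:, perm]
    corr = np.corrcoef(aligned, rowvar=False)
    rows, cols = zip(*PAIR_INDICES)
    weights = fisher_z(corr[rows, cols])
    return ConnectivityPattern(
        weights=np.atleast_1d(weights),
        subject_id=ts.subject_id,
        group=ts.group,
        week=ts.week,
    )


def _hemisphere_average(weights: np.ndarray) -> np.ndarray:
    """Average weights over the two hemisphere orientations.

    Intrahemispheric weights are replaced by the mean of the two
    homologous within-hemisphere entries; heterologous interhemispheric
    weights by the mean of their two orientations. Homologous
    interhemispheric weights are orientation-free and untouched.
    """
    out = weights.copy()
    for k, (i, j) in enumerate(PAIR_INDICES):
        if (i < 5) == (j < 5):  # intrahemispheric: partner in other block
            pi, pj = (i + 5) % 10, (j + 5) % 10
            partner = PAIR_INDICES.index((min(pi, pj), max(pi, pj)))
            out[k] = (weights[k] + weights[partner]) / 2.0
        elif HETEROLOGOUS_MASK[k]:  # mirror orientation (B_h1, A_h2)
            pi, pj = j - 5, i + 5
            partner = PAIR_INDICES.index((min(pi, pj), max(pi, pj)))
            out[k] = (weights[k] + weights[partner]) / 2.0
    return out


def average_pattern(
    patterns: Sequence[ConnectivityPattern],
    control_hemisphere_average: bool = False,
    allow_mixed_groups: bool = False,
) -> ConnectivityPattern:
    """Entrywise mean of label-compatible patterns.

    With ``control_hemisphere_average`` set (the control-group
    convention), each orientation-dependent weight of the averaged
    pattern is replaced by the mean over both hemisphere orientations.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("cannot average an empty pattern collection")
    labels = patterns[0].pair_labels
    if any(p.pair_labels != labels for p in patterns):
        raise ValueError("patterns have incompatible pair labels")
    groups = {p.group for p in patterns}
    if len(groups) > 1 and not allow_mixed_groups:
        raise ValueError(
            f"refusing to average mixed groups {sorted(groups)}; "
            "pass allow_mixed_groups=True to override"
        )
    mean = np.mean([p.weights for p in patterns], axis=0)
    if control_hemisphere_average:
        mean = _hemisphere_average(mean)
    return ConnectivityPattern(
        weights=mean,
        subject_id="+".join(sorted({p.subject_id for p in patterns if p.subject_id})),
        group=groups.pop() if len(groups) == 1 else "mixed",
        week="+".join(sorted({p.week for p in patterns if p.week})),
    )


def extract_weight(pattern: ConnectivityPattern, roi_a: str, roi_b: str) -> float:
    """Single named Fisher-Z weight (order-insensitive lookup)."""
    return float(pattern.weights[pair_index(roi_a, roi_b)])


def extract_roi_means(
    image: np.ndarray,
    mask: np.ndarray,
    label_map: Mapping[int, str],
    *,
    subject_id: str = "",
    group: str = "control",
    lesion_side: str = "none",
    week: str = "",
    tr_seconds: float = 2.0,
) -> ROITimeSeriesSet:
    """Across-voxel mean time series per labelled ROI.

    ``image`` is an X x Y x Z x T volume (or a nibabel image),
    ``mask`` an integer label volume on the same grid, and ``label_map``
    maps mask labels to the 10 storage ROI names.
    """
    image = np.asarray(getattr(image, "dataobj", image), dtype=float)
    mask = np.asarray(getattr(mask, "dataobj", mask))
    if image.ndim != 4:
        raise ValueError(f"image must be 4D, got {image.ndim}D")
    if mask.shape != image.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match image grid {image.shape[:3]}"
        )
    wanted = {name: label for label, name in label_map.items()}
    missing = [name for name in rois.STORAGE_ROIS if name not in wanted]
    if missing:
        raise ValueError(f"label_map is missing ROI(s): {', '.join(missing)}")
    n_volumes = image.shape[3]
    data = np.empty((n_volumes, 10))
    for col, name in enumerate(rois.STORAGE_ROIS):
        voxels = mask == wanted[name]
        if not voxels.any():
            raise ValueError(f"ROI {name!r} (label {wanted[name]}) is empty in mask")
        data[:, col] = image[voxels, :].mean(axis=0)
    return ROITimeSeriesSet(
        subject_id=subject_id,
        group=group,
        lesion_side=lesion_side,
        week=week,
        tr_seconds=tr_seconds,
        data=data,
    )


def patterns_to_matrix(
    patterns: Iterable[ConnectivityPattern], subset: str = "full"
) -> np.ndarray:
    """Stack patterns into an n_subjects x n_weights matrix for a subset."""
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns supplied")
    mask = SUBSET_MASKS[subset]
    return np.vstack([p.weights[mask] for p in patterns])
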