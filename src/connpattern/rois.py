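"""Canonical ROI ordering, pair labels and subset masks.

Five sensorimotor areas per hemisphere are analysed. The canonical
vectorization puts the ipsilesional hemisphere (block 1) first; for
controls, who have no lesion, the left hemisphere plays the role of the
fixed reference block. All connectivity patterns in this package share
the pair ordering defined here, so Euclidean distances between patterns
are comparable across subjects and sessions.
"""

from __future__ import annotations

import itertools

import numpy as np

#: Base sensorimotor area names, in canonical within-hemisphere order.
BASE_ROIS: tuple[str, ...] = ("S1", "M1", "PMd", "PMv", "SMA")

#: Hemisphere block suffixes in canonical order (block 1 = ipsilesional).
HEMI_SUFFIXES: tuple[str, str] = ("ipsi", "contra")

#: The 10 canonical ROI labels (block 1 then block 2).
CANONICAL_ROIS: tuple[str, ...] = tuple(
    f"{r}_{h}" for h in HEMI_SUFFIXES for r in BASE_ROIS
)

#: Storage-side labels, hemisphere given anatomically (left then right).
STORAGE_ROIS: tuple[str, ...] = tuple(
    f"{r}_{h}" for h in ("L", "R") for r in BASE_ROIS
)

N_ROIS = 10
N_PAIRS = 45

#: Upper-triangle (i < j) index pairs over the 10 canonical ROIs.
PAIR_INDICES: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(N_ROIS), 2)
)

#: The 45 canonical (roiA, roiB) pair labels.
PAIR_LABELS: tuple[tuple[str, str], ...] = tuple(
    (CANONICAL_ROIS[i], CANONICAL_ROIS[j]) for i, j in PAIR_INDICES
)


def split_label(label: str) -> tuple[str, str]:
    """Split ``"M1_ipsi"`` into ``("M1", "ipsi")``."""
    base, _, hemi = label.rpartition("_")
    if base not in BASE_ROIS:
        raise KeyError(f"unknown ROI label: {label!r}")
    return base, hemi


def _mask(predicate) -> np.ndarray:
    out = np.zeros(N_PAIRS, dtype=bool)
    for k, (i, j) in enumerate(PAIR_INDICES):
        out[k] = predicate(i, j)
    return out


#: 10 pairs within hemisphere block 1 (ipsilesional).
INTRA_IPSI_MASK = _mask(lambda i, j: i < 5 and j < 5)
#: 10 pairs within hemisphere block 2 (contralesional).
INTRA_CONTRA_MASK = _mask(lambda i, j: i >= 5 and j >= 5)
#: 25 pairs spanning the two hemispheres.
INTER_MASK = _mask(lambda i, j: i < 5 <= j)

SUBSET_MASKS: dict[str, np.ndarray] = {
    "full": np.ones(N_PAIRS, dtype=bool),
    "intra_ipsilesional": INTRA_IPSI_MASK,
    "intra_contralesional": INTRA_CONTRA_MASK,
    "interhemispheric": INTER_MASK,
}

#: Homologous interhemispheric pairs (same area, opposite hemispheres).
HOMOLOGOUS_MASK = _mask(lambda i, j: i < 5 <= j and j - i == 5)
#: Heterologous interhemispheric pairs.
HETEROLOGOUS_MASK = INTER_MASK & ~HOMOLOGOUS_MASK


def pair_index(roi_a: str, roi_b: str) -> int:
    """Index of the unordered canonical pair (order-insensitive)."""
    try:
        i, j = CANONICAL_ROIS.index(roi_a), CANONICAL_ROIS.index(roi_b)
    except ValueError as exc:
        raise KeyError(f"unknown ROI label in pair ({roi_a!r}, {roi_b!r})") from exc
    if i == j:
        raise KeyError(f"self-pair ({roi_a!r}, {roi_b!r}) has no weight")
    if i > j:
        i, j = j, i
    return PAIR_INDICES.index((i, j))


def storage_to_canonical_order(lesion_side: str) -> list[int]:
    """Column permutation taking L/R storage order to ipsi-first order.

    ``lesion_side`` of ``"left"`` maps the left hemisphere to block 1;
    ``"right"`` flips the blocks; ``"none"`` (controls) uses the left
    hemisphere as the fixed reference block.
    """
    if lesion_side in ("left", "none"):
        return list(range(10))
    if lesion_side == "right":
        return list(range(5, 10)) + list(range(5))
    raise ValueError(f"invalid lesion_side: {lesion_side!r}")
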