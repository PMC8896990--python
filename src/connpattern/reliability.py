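"""Split-half intrasession reliability of connectivity patterns."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .connectivity import SUBSETS, compute_pattern
from .timeseries import ROITimeSeriesSet

DEFAULT_HALF_LENGTH = 100


@dataclass(frozen=True)
class ReliabilityRecord:
    subject_id: str
    group: str
    week: str
    subset: str
    r_split: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_split <= 1.0:
            raise ValueError(f"r_split out of [-1, 1]: {self.r_split}")


def split_half(
    ts: ROITimeSeriesSet, half_length: int = DEFAULT_HALF_LENGTH
) -> list[ReliabilityRecord]:
    """Correlate half-scan connectivity patterns, one record per subset.

    The pattern is computed independently on volumes
    ``[0, half_length)`` and ``[half_length, 2 * half_length)``; any
    volumes beyond ``2 * half_length`` are ignored. ``r_split`` is the
    Pearson correlation across the subset's weights between the two
    half-patterns.
    """
    if half_length < 2:
        raise ValueError("half_length must be >= 2")
    if ts.n_volumes < 2 * half_length:
        raise ValueError(
            f"need at least {2 * half_length} volumes for half_length="
            f"{half_length}, got {ts.n_volumes}"
        )
    first = replace(ts, data=ts.data[:half_length], voxel_data=None)
    second = replace(ts, data=ts.data[half_length : 2 * half_length], voxel_data=None)
    p1, p2 = compute_pattern(first), compute_pattern(second)
    records = []
    for subset in SUBSETS:
        a, b = p1.subset(subset), p2.subset(subset)
        r = float(np.corrcoef(a, b)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))  # guard fp overshoot
        records.append(
            ReliabilityRecord(
                subject_id=ts.subject_id,
                group=ts.group,
                week=ts.week,
                subset=subset,
                r_split=r,
            )
        )
    return records


def summarize_reliability(
    records: Iterable[ReliabilityRecord],
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int | None = None,
) -> dict:
    """Mean r_split with a percentile bootstrap CI over records."""
    values = np.array([r.r_split for r in records], dtype=float)
    if values.size == 0:
        raise ValueError("no reliability records to summarize")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.quantile(boot_means, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {
        "mean": float(values.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": int(values.size),
        "n_boot": int(n_boot),
    }
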