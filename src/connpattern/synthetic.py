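"""Synthetic longitudinal cohort generator.

Emits multi-subject, multi-session ROI-level (and optionally
voxel-level) BOLD time series whose stationary correlation structure is
controlled in Fisher-Z space: every subject receives the cohort
ground-truth pattern plus idiosyncratic Gaussian perturbations, patients
optionally receive a fixed group-difference pattern of configurable
Euclidean norm, and each session adds its own perturbation. Sampling is
a zero-mean multivariate AR(1) process whose stationary correlation
matrix is the (positive-definite-repaired) back-transform of the
session's Fisher-Z pattern.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.signal import lfilter

from .rois import (
    BASE_ROIS,
    N_PAIRS,
    PAIR_INDICES,
    storage_to_canonical_order,
)
from .timeseries import ROITimeSeriesSet

DEFAULT_SESSIONS: tuple[str, ...] = ("W1", "W4", "W12", "W24", "W52")


class GenerationError(RuntimeError):
    """Raised when a session's correlation matrix cannot be repaired."""


# ---------------------------------------------------------------------------
# Ground-truth pattern
# ---------------------------------------------------------------------------

# Fixed Fisher-Z tables anchored at published control-group values:
# within-hemisphere S1-M1 = 0.91 (strongest) and M1-PMv = 0.58 (weakest);
# interhemispheric homologous S1-S1 = 0.90 and heterologous M1-PMv = 0.59.
# Off-anchor entries interpolate between the anchors; every homologous
# interhemispheric weight strictly exceeds every heterologous one. The
# implied 10 x 10 correlation matrix is positive definite as written.
_INTRA_Z: dict[frozenset, float] = {
    frozenset(p): z
    for p, z in {
        ("S1", "M1"): 0.91,
        ("S1", "PMd"): 0.76,
        ("S1", "PMv"): 0.68,
        ("S1", "SMA"): 0.72,
        ("M1", "PMd"): 0.80,
        ("M1", "PMv"): 0.58,
        ("M1", "SMA"): 0.75,
        ("PMd", "PMv"): 0.70,
        ("PMd", "SMA"): 0.74,
        ("PMv", "SMA"): 0.65,
    }.items()
}

_HOMOLOGOUS_Z: dict[str, float] = {
    "S1": 0.90,
    "M1": 0.85,
    "PMd": 0.80,
    "PMv": 0.78,
    "SMA": 0.82,
}

_HETEROLOGOUS_Z: dict[frozenset, float] = {
    frozenset(p): z
    for p, z in {
        ("S1", "M1"): 0.55,
        ("S1", "PMd"): 0.50,
        ("S1", "PMv"): 0.45,
        ("S1", "SMA"): 0.47,
        ("M1", "PMd"): 0.52,
        ("M1", "PMv"): 0.59,
        ("M1", "SMA"): 0.50,
        ("PMd", "PMv"): 0.48,
        ("PMd", "SMA"): 0.49,
        ("PMv", "SMA"): 0.44,
    }.items()
}


def default_ground_truth() -> np.ndarray:
    """Fixed 45-vector of Fisher-Z population weights in canonical order."""
    out = np.empty(N_PAIRS)
    for k, (i, j) in enumerate(PAIR_INDICES):
        a, b = BASE_ROIS[i % 5], BASE_ROIS[j % 5]
        if (i < 5) == (j < 5):  # same hemisphere block
            out[k] = _INTRA_Z[frozenset((a, b))]
        elif a == b:
            out[k] = _HOMOLOGOUS_Z[a]
        else:
            out[k] = _HETEROLOGOUS_Z[frozenset((a, b))]
    return out


def inject_direction(dim: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Standard-normal draw of length ``dim`` scaled to unit Euclidean norm."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # pragma: no cover - probability zero
        v = rng.standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


# ---------------------------------------------------------------------------
# Positive-definite repair
# ---------------------------------------------------------------------------

def nearest_pd_correlation(
    matrix: np.ndarray, floor: float = 1e-6, max_iter: int = 20
) -> np.ndarray:
    """Project a symmetric matrix to a nearby positive-definite correlation.

    Eigenvalues are clipped at ``floor`` and the diagonal re-normalized to
    one; the two steps are alternated until both constraints hold.
    """
    a = np.asarray(matrix, dtype=float)
    a = (a + a.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(a)
        if vals.min() >= floor * 0.5 and np.allclose(np.diag(a), 1.0, atol=1e-12):
            return a
        vals = np.clip(vals, floor, None)
        a = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    vals = np.linalg.eigvalsh(a)
    if vals.min() < floor * 0.5:
        raise GenerationError(
            f"correlation matrix not repairable (min eigenvalue {vals.min():.3g})"
        )
    return a


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class SyntheticCohortConfig(BaseModel):
    """Parameters of a synthetic longitudinal cohort."""

    n_patients: int = Field(default=19, ge=0)
    n_controls: int = Field(default=11, ge=0)
    sessions: tuple[str, ...] = DEFAULT_SESSIONS
    n_volumes: int = Field(default=210, ge=2)
    tr_seconds: float = Field(default=2.0, gt=0)
    ground_truth_z: tuple[float, ...] = Field(
        default_factory=lambda: tuple(default_ground_truth())
    )
    subject_sd_patient: float = Field(default=0.30, ge=0)
    subject_sd_control: float = Field(default=0.25, ge=0)
    session_sd: float = Field(default=0.10, ge=0)
    roi_noise_sd: float = Field(default=0.0, ge=0)
    ar1_phi: float = Field(default=0.3, ge=0, lt=1)
    injected_difference_norm: float = Field(default=0.0, ge=0)
    missing_rate: float = Field(default=0.11, ge=0, lt=1)
    voxels_per_roi: int = Field(default=0, ge=0)
    voxel_signal_fraction: float = Field(default=0.6, gt=0, le=1)
    seed: int = 0

    @field_validator("ground_truth_z")
    @classmethod
    def _check_ground_truth(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) != N_PAIRS:
            raise ValueError(f"ground_truth_z must have {N_PAIRS} entries, got {len(v)}")
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("ground_truth_z entries must be finite")
        return v

    @model_validator(mode="after")
    def _check_sessions(self) -> "SyntheticCohortConfig":
        if not self.sessions:
            raise ValueError("at least one session is required")
        if len(set(self.sessions)) != len(self.sessions):
            raise ValueError("session labels must be unique")
        return self


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _simulate_ar1(
    rng: np.random.Generator, corr: np.ndarray, n_volumes: int, phi: float
) -> np.ndarray:
    """T samples of a zero-mean AR(1) process with stationary correlation."""
    chol = np.linalg.cholesky(corr)
    eps = rng.standard_normal((n_volumes, corr.shape[0]))
    if phi == 0.0:
        return eps @ chol.T
    innov = (eps @ chol.T) * np.sqrt(1.0 - phi * phi)
    x0 = rng.standard_normal(corr.shape[0]) @ chol.T
    out, _ = lfilter([1.0], [1.0, -phi], innov, axis=0, zi=(phi * x0)[None, :])
    return out


def _session_correlation(z_canonical: np.ndarray, lesion_side: str) -> np.ndarray:
    """Back-transform a canonical Fisher-Z 45-vector to a storage-order
    positive-definite correlation matrix."""
    zmat = np.zeros((10, 10))
    rows, cols = zip(*PAIR_INDICES)
    zmat[rows, cols] = z_canonical
    zmat = zmat + zmat.T
    corr = np.tanh(zmat)
    np.fill_diagonal(corr, 1.0)
    corr = nearest_pd_correlation(corr)
    perm = storage_to_canonical_order(lesion_side)
    inverse = np.argsort(perm)
    return corr[np.ix_(inverse, inverse)]


def generate_cohort(config: SyntheticCohortConfig) -> list[ROITimeSeriesSet]:
    """Generate all subject-sessions of a synthetic cohort.

    Deterministic given ``config.seed``. Sessions after the first are
    dropped independently with probability ``missing_rate``; the first
    session is always present.
    """
    rng = np.random.default_rng(config.seed)
    ground_truth = np.asarray(config.ground_truth_z, dtype=float)

    # One fixed difference direction per cohort (drawn even when the norm
    # is zero, so the stream layout is stable across configs).
    direction = inject_direction(N_PAIRS, rng)
    offset = config.injected_difference_norm * direction

    subjects: list[tuple[str, str, str, float]] = []
    for i in range(config.n_patients):
        side = "left" if i % 2 == 0 else "right"
        subjects.append((f"P{i + 1:02d}", "patient", side, config.subject_sd_patient))
    for i in range(config.n_controls):
        subjects.append((f"C{i + 1:02d}", "control", "none", config.subject_sd_control))

    cohort: list[ROITimeSeriesSet] = []
    for subject_id, group, lesion_side, subject_sd in subjects:
        z_subject = ground_truth + rng.normal(0.0, subject_sd, N_PAIRS)
        if group == "patient":
            z_subject = z_subject + offset
        for s, week in enumerate(config.sessions):
            if s > 0 and rng.random() < config.missing_rate:
                continue
            z_session = z_subject + rng.normal(0.0, config.session_sd, N_PAIRS)
            try:
                corr = _session_correlation(z_session, lesion_side)
            except GenerationError as exc:
                raise GenerationError(
                    f"subject {subject_id} week {week}: {exc}"
                ) from exc
            data = _simulate_ar1(rng, corr, config.n_volumes, config.ar1_phi)
            if config.roi_noise_sd > 0:
                data = data + rng.normal(
                    0.0, config.roi_noise_sd, data.shape
                )
            voxel_data = None
            if config.voxels_per_roi > 0:
                voxel_data = _voxelize(rng, data, config)
            cohort.append(
                ROITimeSeriesSet(
                    subject_id=subject_id,
                    group=group,
                    lesion_side=lesion_side,
                    week=week,
                    tr_seconds=config.tr_seconds,
                    data=data,
                    voxel_data=voxel_data,
                )
            )
    return cohort


def _voxelize(
    rng: np.random.Generator, data: np.ndarray, config: SyntheticCohortConfig
) -> dict[str, np.ndarray]:
    """Per-ROI voxel series = shared ROI signal + independent voxel noise."""
    from .rois import STORAGE_ROIS

    f = config.voxel_signal_fraction
    n_volumes = data.shape[0]
    out: dict[str, np.ndarray] = {}
    for col, roi in enumerate(STORAGE_ROIS):
        noise = rng.standard_normal((n_volumes, config.voxels_per_roi))
        out[roi] = (
            np.sqrt(f) * data[:, [col]] + np.sqrt(1.0 - f) * noise
        )
    return out
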