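"""Pipeline orchestration and publication-style result tables.

``run_pipeline`` executes connectivity -> reliability -> permutation
statistics -> RelCon over a cohort manifest and writes tidy TSV tables:
group comparisons per week and subset (with equivalence bounds),
longitudinal week distances, variability tests, the week-variability
ANOVA, a per-subject M1-M1 / RelCon longitudinal table, reliability
records, serialized null distributions, and a run log carrying the seed
and parameters. Results are reported unadjusted for multiplicity across
subsets and weeks.
"""

from __future__ import annotations

import json
import logging
import platform
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .connectivity import (
    ConnectivityPattern,
    SUBSETS,
    average_pattern,
    compute_pattern,
    extract_weight,
)
from .io import read_manifest, weights_long_table
from .permstats import (
    delta_pattern_test,
    equivalence_test,
    longitudinal_deltas,
    variability_test,
    week_distance_table,
    week_variability_anova,
)
from .reliability import split_half
from .relcon import relcon_from_timeseries
from .timeseries import ROITimeSeriesSet

logger = logging.getLogger(__name__)

ALL_COMPARISONS = ("group", "week", "variability", "equivalence")


class RunConfig(BaseModel):
    """Configuration of a full pipeline run."""

    manifest: Path
    out_dir: Path = Path("results")
    subsets: tuple[str, ...] = SUBSETS
    comparisons: tuple[str, ...] = ALL_COMPARISONS
    n_shuffles: int = Field(default=10_000, ge=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    delta_grid_start: float = Field(default=0.05, gt=0)
    delta_grid_stop: float = Field(default=3.0, gt=0)
    delta_grid_step: float = Field(default=0.05, gt=0)
    reference_week: str = "W1"
    half_length: int = Field(default=100, ge=2)
    seed: int = 0
    verbosity: str = "INFO"

    def delta_grid(self) -> np.ndarray:
        return np.round(
            np.arange(
                self.delta_grid_start,
                self.delta_grid_stop + 1e-9,
                self.delta_grid_step,
            ),
            10,
        )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def session_patterns(cohort: Sequence[ROITimeSeriesSet]) -> list[ConnectivityPattern]:
    return [compute_pattern(ts) for ts in cohort]


def control_subject_patterns(
    patterns: Sequence[ConnectivityPattern],
) -> list[ConnectivityPattern]:
    """One pattern per control: sessions averaged, hemispheres averaged.

    Controls' patterns are averaged over time-points (their patterns are
    stable across sessions) and orientation-averaged across hemispheres,
    the control-group estimation convention.
    """
    by_subject: dict[str, list[ConnectivityPattern]] = defaultdict(list)
    for p in patterns:
        if p.group == "control":
            by_subject[p.subject_id].append(p)
    return [
        average_pattern(ps, control_hemisphere_average=True)
        for _, ps in sorted(by_subject.items())
    ]


def patient_patterns_by_week(
    patterns: Sequence[ConnectivityPattern],
) -> dict[str, list[ConnectivityPattern]]:
    out: dict[str, list[ConnectivityPattern]] = defaultdict(list)
    for p in patterns:
        if p.group == "patient":
            out[p.week].append(p)
    return dict(out)


def _save_null(nulls_dir: Path, label: str, null: np.ndarray) -> str:
    nulls_dir.mkdir(parents=True, exist_ok=True)
    name = label.replace("/", "-") + ".tsv"
    pd.DataFrame({"null_delta": null}).to_csv(
        nulls_dir / name, sep="\t", index=False, float_format="%.10g"
    )
    return name


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis; returns the result tables by name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    incomplete_marker = out_dir / "INCOMPLETE"
    incomplete_marker.write_text("run in progress\n")
    nulls_dir = out_dir / "nulls"
    rng = np.random.default_rng(config.seed)
    tables: dict[str, pd.DataFrame] = {}

    stage = "load"
    try:
        cohort = read_manifest(config.manifest, load_voxels=True)
        stage = "connectivity"
        patterns = session_patterns(cohort)
        tables["weights"] = weights_long_table(patterns)
        controls = control_subject_patterns(patterns)
        patients_by_week = patient_patterns_by_week(patterns)
        weeks = sorted(
            patients_by_week, key=lambda w: (w != config.reference_week, w)
        )

        stage = "reliability"
        records = []
        for ts in cohort:
            if ts.n_volumes >= 2 * config.half_length:
                records.extend(split_half(ts, config.half_length))
        tables["reliability"] = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "week": r.week,
                    "subset": r.subset,
                    "r_split": r.r_split,
                }
                for r in records
            ]
        )

        stage = "permstats"
        tables.update(
            _run_permstats(
                config, rng, nulls_dir, controls, patients_by_week, weeks
            )
        )

        stage = "alternative-metrics"
        tables["m1m1_relcon"] = _m1m1_relcon_table(cohort, patterns)

        stage = "write"
        for name, table in tables.items():
            table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        _write_run_log(config, out_dir)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    incomplete_marker.unlink()
    return tables


def _run_permstats(
    config: RunConfig,
    rng: np.random.Generator,
    nulls_dir: Path,
    controls: list[ConnectivityPattern],
    patients_by_week: dict[str, list[ConnectivityPattern]],
    weeks: list[str],
) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    grid = config.delta_grid()
    group_rows, week_rows, var_rows, anova_rows = [], [], [], []

    for subset in config.subsets:
        if "group" in config.comparisons or "equivalence" in config.comparisons:
            for week in weeks:
                label = f"patients-vs-controls_{week}_{subset}"
                res = delta_pattern_test(
                    patients_by_week[week],
                    controls,
                    n_shuffles=config.n_shuffles,
                    seed=rng,
                    subset=subset,
                    comparison_label=label,
                )
                row = {
                    "comparison": label,
                    "week": week,
                    "subset": subset,
                    "delta": res.observed_delta,
                    "p": res.p_value,
                    "n_shuffles": res.n_shuffles,
                    "null_file": _save_null(nulls_dir, label, res.null_distribution),
                    "delta_star": np.nan,
                    "d": np.nan,
                }
                if "equivalence" in config.comparisons and res.p_value >= config.alpha:
                    eq = equivalence_test(
                        patients_by_week[week],
                        controls,
                        observed_delta=res.observed_delta,
                        n_shuffles=config.n_shuffles,
                        alpha=config.alpha,
                        delta_grid=grid,
                        seed=rng,
                        subset=subset,
                    )
                    if eq.determinable:
                        row["delta_star"] = eq.delta_star_rejectable
                        row["d"] = eq.cohens_d_equivalent
                group_rows.append(row)

        if "week" in config.comparisons and config.reference_week in patients_by_week:
            for res in longitudinal_deltas(
                patients_by_week,
                config.reference_week,
                n_shuffles=config.n_shuffles,
                seed=rng,
                subset=subset,
            ):
                label = f"patients_{res.comparison_label}_{subset}"
                week_rows.append(
                    {
                        "comparison": label,
                        "subset": subset,
                        "delta": res.observed_delta,
                        "p": res.p_value,
                        "n_shuffles": res.n_shuffles,
                        "null_file": _save_null(
                            nulls_dir, label, res.null_distribution
                        ),
                    }
                )
            if len(patients_by_week) > 1:
                table = week_distance_table(
                    patients_by_week, config.reference_week, subset=subset
                )
                if table.shape[0] >= 2 and table.shape[1] >= 2:
                    anova = week_variability_anova(table)
                    anova_rows.append(
                        {
                            "subset": subset,
                            "F": anova.f_stat,
                            "p": anova.p_value,
                            "df_between": anova.df_between,
                            "df_within": anova.df_within,
                            "n_subjects": table.shape[0],
                        }
                    )

        if "variability" in config.comparisons:
            for week in weeks:
                if len(patients_by_week[week]) < 2 or len(controls) < 2:
                    continue
                label = f"variability_{week}_{subset}"
                res = variability_test(
                    patients_by_week[week],
                    controls,
                    n_shuffles=config.n_shuffles,
                    seed=rng,
                    subset=subset,
                    comparison_label=label,
                )
                var_rows.append(
                    {
                        "comparison": label,
                        "week": week,
                        "subset": subset,
                        "patient_variability": res.group_variability_a,
                        "control_variability": res.group_variability_b,
                        "delta_variability": res.delta_variability,
                        "p": res.p_value,
                        "direction": res.direction,
                        "n_shuffles": res.n_shuffles,
                        "null_file": _save_null(
                            nulls_dir, label, res.null_distribution
                        ),
                    }
                )

    if group_rows:
        tables["group_tests"] = pd.DataFrame(group_rows)
    if week_rows:
        tables["week_tests"] = pd.DataFrame(week_rows)
    if var_rows:
        tables["variability_tests"] = pd.DataFrame(var_rows)
    if anova_rows:
        tables["week_variability_anova"] = pd.DataFrame(anova_rows)
    return tables


def _m1m1_relcon_table(
    cohort: Sequence[ROITimeSeriesSet], patterns: Sequence[ConnectivityPattern]
) -> pd.DataFrame:
    rows = []
    for ts, pattern in zip(cohort, patterns):
        row = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "week": ts.week,
            "m1_m1_z": extract_weight(pattern, "M1_ipsi", "M1_contra"),
            "relcon": np.nan,
            "relcon_inter_mean": np.nan,
            "relcon_within_mean": np.nan,
        }
        if ts.voxel_data is not None:
            res = relcon_from_timeseries(ts)
            row["relcon"] = res.relcon
            row["relcon_inter_mean"] = res.inter_mean
            row["relcon_within_mean"] = res.within_mean
        rows.append(row)
    return pd.DataFrame(rows)


def _write_run_log(config: RunConfig, out_dir: Path) -> None:
    log = {
        "seed": config.seed,
        "n_shuffles": config.n_shuffles,
        "alpha": config.alpha,
        "subsets": list(config.subsets),
        "comparisons": list(config.comparisons),
        "reference_week": config.reference_week,
        "connpattern_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "note": "p-values are reported unadjusted for multiplicity "
        "across subsets and weeks",
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
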