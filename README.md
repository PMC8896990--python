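# connpattern

Longitudinal resting-state ROI connectivity-pattern analysis with
permutation statistics, built around a synthetic-cohort generator so the
whole pipeline can be exercised end to end without any real imaging
data.

The package covers:

- **Synthetic cohorts** (`connpattern.synthetic`): multi-subject,
  multi-session ROI-level (and optional voxel-level) BOLD time series.
  Each subject's Fisher-Z connectivity pattern is the cohort ground
  truth plus Gaussian perturbations (larger for patients if configured);
  patients can receive a fixed group-difference pattern of chosen
  Euclidean norm; sampling is a multivariate AR(1) process whose
  stationary correlation is the (positive-definite-repaired)
  back-transform of the session pattern. Missing follow-up sessions,
  alternating lesion sides, and measurement noise are configurable.
- **Connectivity patterns** (`connpattern.connectivity`): Pearson
  correlations between the 10 sensorimotor ROI time courses
  ({S1, M1, PMd, PMv, SMA} × both hemispheres), Fisher-Z transformed
  and vectorized as the 45-weight upper triangle, with hemisphere
  blocks aligned so block 1 is ipsilesional. Subset masks split the
  pattern into 10 + 10 intrahemispheric and 25 interhemispheric
  weights. ROI-mean extraction from 4D images + integer label masks
  (NIfTI via nibabel) is included.
- **Reliability** (`connpattern.reliability`): split-half intrasession
  reliability (pattern on volumes 1–100 vs 101–200, correlated per
  subset) with a bootstrap CI summary.
- **Permutation statistics** (`connpattern.permstats`): the
  Euclidean-distance permutation test between group mean patterns, a
  permutation equivalence test that injects random difference patterns
  of candidate norm Δ\* and reports the smallest rejectable norm plus
  its average univariate Cohen's d, within-group variability tests,
  paired longitudinal week comparisons, and the week-variability ANOVA.
- **RelCon** (`connpattern.relcon`): voxelwise relative interhemispheric
  connectivity of sensorimotor cortex (mean cross-hemisphere voxel-pair
  correlation divided by mean within-ipsilesional pair correlation).
- **Pipeline & CLI** (`connpattern.report`, `connpattern.cli`):
  manifest-driven orchestration producing tidy TSV result tables,
  serialized null distributions, and a seeded run log.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (structural
targets, permutation-oracle equivalence, type-I calibration, power
monotonicity, equivalence coverage, parameter recovery, closed forms,
degenerate contracts, ANOVA surface). The full suite runs in a few
minutes on one CPU.

## CLI

One entry point with subcommands:

```bash
# generate a synthetic cohort (TSV per subject-session + manifest)
connpattern synth --out data/cohort --seed 1 --patients 19 --controls 11

# split-half reliability per subject-session and subset
connpattern reliability --manifest data/cohort/manifest.tsv --half 100

# one-off group / variability / equivalence test at a week
connpattern analyze --manifest data/cohort/manifest.tsv \
    --comparison group --subset full --week W1 -B 10000 --seed 0

# RelCon (requires a voxel-mode cohort: synth --voxels-per-roi N)
connpattern relcon --manifest data/voxcohort/manifest.tsv

# full pipeline from a YAML config
connpattern run --config run.yaml
```

Example `run.yaml`:

```yaml
manifest: data/cohort/manifest.tsv
out_dir: results/run1
n_shuffles: 10000
alpha: 0.05
seed: 7
subsets: [full, interhemispheric, intra_ipsilesional, intra_contralesional]
comparisons: [group, week, variability, equivalence]
```

Outputs: `group_tests.tsv` (distance, p, Δ\*, d per week and subset),
`week_tests.tsv` (paired distances from the reference week),
`variability_tests.tsv`, `week_variability_anova.tsv`,
`reliability.tsv`, `m1m1_relcon.tsv`, `weights.tsv` (long format),
`nulls/` (serialized null distributions), and `run_log.json`.

## Notes

- All randomness flows through seeded `numpy.random.Generator`s; equal
  seeds reproduce results bit for bit.
- p-values are plain null-tail proportions with ties counted as extreme
  (degenerate data give p = 1) and are reported unadjusted for
  multiplicity across subsets and weeks.
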