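"""Permutation statistics on connectivity patterns.

Implements the Euclidean-distance permutation test between groups, the
permutation-based equivalence test with injected difference patterns,
its Cohen's d conversion, within-group variability testing, paired
longitudinal week comparisons, and the week-variability ANOVA.

All tests are deterministic given a seed, and every p-value is the
plain proportion of null draws at least as extreme as the observed
statistic (ties count as extreme, so degenerate data yield p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .connectivity import ConnectivityPattern, patterns_to_matrix

#: Absolute tolerance when comparing null draws against the observed
#: statistic; keeps exact ties (degenerate data) counted as extreme.
_TIE_TOL = 1e-12

DEFAULT_N_SHUFFLES = 10_000
DEFAULT_DELTA_GRID = np.round(np.arange(0.05, 3.0 + 1e-9, 0.05), 2)


def _as_matrix(group, subset: str = "full") -> np.ndarray:
    """Accept a 2D array or a sequence of ConnectivityPattern."""
    if isinstance(group, np.ndarray):
        out = np.atleast_2d(np.asarray(group, dtype=float))
    elif len(group) > 0 and isinstance(group[0], ConnectivityPattern):
        out = patterns_to_matrix(group, subset)
    else:
        out = np.atleast_2d(np.asarray(group, dtype=float))
    if out.size == 0:
        raise ValueError("empty group")
    return out


def _subject_ids(group) -> list[str] | None:
    if len(group) > 0 and isinstance(group[0], ConnectivityPattern):
        return [p.subject_id for p in group]
    return None


def _check_disjoint(group_a, group_b) -> None:
    ids_a, ids_b = _subject_ids(group_a), _subject_ids(group_b)
    if ids_a is None or ids_b is None:
        return
    overlap = set(filter(None, ids_a)) & set(filter(None, ids_b))
    if overlap:
        raise ValueError(f"subject(s) in both groups: {sorted(overlap)}")


def _group_assignment_shuffles(
    rng: np.random.Generator, n_total: int, n_a: int, n_shuffles: int
) -> np.ndarray:
    """(B, n) 0/1 matrix; each row selects a pseudo-group A of size n_a."""
    keys = rng.random((n_shuffles, n_total))
    order = np.argsort(keys, axis=1, kind="stable")
    select = np.zeros((n_shuffles, n_total))
    np.put_along_axis(select, order[:, :n_a], 1.0, axis=1)
    return select


@dataclass
class PermutationResult:
    observed_delta: float
    null_distribution: np.ndarray
    p_value: float
    n_shuffles: int
    subset: str = "full"
    comparison_label: str = ""

    def __post_init__(self) -> None:
        self.null_distribution = np.asarray(self.null_distribution, dtype=float)
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class EquivalenceResult:
    delta_star_rejectable: float
    alpha: float
    cohens_d_equivalent: float
    delta_grid: np.ndarray
    rejected: np.ndarray
    observed_delta: float
    n_shuffles: int
    determinable: bool
    subset: str = "full"


@dataclass
class VariabilityResult:
    group_variability_a: float
    group_variability_b: float
    delta_variability: float
    p_value: float
    null_distribution: np.ndarray
    n_shuffles: int
    direction: str = ""
    subset: str = "full"
    comparison_label: str = ""


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int


def euclidean_delta(mean_a, mean_b) -> float:
    """L2 norm of the difference between two pattern vectors."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def delta_pattern_test(
    group_a,
    group_b,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    subset: str = "full",
    comparison_label: str = "",
) -> PermutationResult:
    """Euclidean-distance permutation test between two groups' means.

    Group labels are reshuffled ``n_shuffles`` times preserving the
    original group sizes; the p-value is the proportion of null
    distances at least as large as the observed distance.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    _check_disjoint(group_a, group_b)
    xa = _as_matrix(group_a, subset)
    xb = _as_matrix(group_b, subset)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups have different pattern lengths")
    observed = euclidean_delta(xa.mean(axis=0), xb.mean(axis=0))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.vstack([xa, xb])
    n_a, n_b = xa.shape[0], xb.shape[0]
    null = np.empty(n_shuffles)
    chunk = 5_000
    for start in range(0, n_shuffles, chunk):
        size = min(chunk, n_shuffles - start)
        select = _group_assignment_shuffles(rng, n_a + n_b, n_a, size)
        mean_a = (select @ x) / n_a
        mean_b = ((1.0 - select) @ x) / n_b
        null[start : start + size] = np.linalg.norm(mean_a - mean_b, axis=1)
    p = float(np.mean(null >= observed - _TIE_TOL))
    return PermutationResult(
        observed_delta=observed,
        null_distribution=null,
        p_value=p,
        n_shuffles=n_shuffles,
        subset=subset,
        comparison_label=comparison_label,
    )


def exhaustive_delta_pattern_test(group_a, group_b, subset: str = "full") -> PermutationResult:
    """Exact version of :func:`delta_pattern_test` over all label assignments.

    Intended for small groups (oracle/validation use)."""
    from itertools import combinations

    xa = _as_matrix(group_a, subset)
    xb = _as_matrix(group_b, subset)
    x = np.vstack([xa, xb])
    n_a, n = xa.shape[0], xa.shape[0] + xb.shape[0]
    observed = euclidean_delta(xa.mean(axis=0), xb.mean(axis=0))
    null = []
    for combo in combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        null.append(euclidean_delta(x[sel].mean(axis=0), x[~sel].mean(axis=0)))
    null = np.asarray(null)
    p = float(np.mean(null >= observed - _TIE_TOL))
    return PermutationResult(
        observed_delta=observed,
        null_distribution=null,
        p_value=p,
        n_shuffles=len(null),
        subset=subset,
        comparison_label="exhaustive",
    )


def equivalence_test(
    group_a,
    group_b,
    observed_delta: float | None = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    alpha: float = 0.05,
    delta_grid: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    subset: str = "full",
    redraw_direction: bool = True,
    d_method: str = "expected",
) -> EquivalenceResult:
    """Smallest injected group-difference norm rejectable at level alpha.

    For each candidate norm on ``delta_grid`` and each of ``n_shuffles``
    simulations, within-group deviations are reshuffled into
    pseudo-groups and a random Gaussian pattern scaled to the candidate
    norm is added to every pseudo-member of group A; the candidate is
    rejected when the observed distance falls at or below the alpha
    quantile of the simulated distances. Shuffles (and injected
    directions) are shared across grid points, and the reported
    ``delta_star_rejectable`` is the smallest grid value from which the
    rejection region is contiguous up to the grid maximum.
    """
    if delta_grid is None:
        delta_grid = DEFAULT_DELTA_GRID
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.ndim != 1 or delta_grid.size == 0:
        raise ValueError("delta_grid must be a non-empty 1D array")
    if np.any(np.diff(delta_grid) <= 0) or np.any(delta_grid < 0):
        raise ValueError("delta_grid must be strictly increasing and >= 0")
    _check_disjoint(group_a, group_b)
    xa = _as_matrix(group_a, subset)
    xb = _as_matrix(group_b, subset)
    if observed_delta is None:
        observed_delta = euclidean_delta(xa.mean(axis=0), xb.mean(axis=0))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dev = np.vstack([xa - xa.mean(axis=0), xb - xb.mean(axis=0)])
    n_a, n_b = xa.shape[0], xb.shape[0]
    n, k = dev.shape

    # Per simulation: pseudo-group mean-deviation difference d0 and unit
    # injection direction u. The simulated distance for candidate norm D
    # is then ||d0 + D u|| = sqrt(||d0||^2 + 2 D (d0 . u) + D^2), so the
    # whole grid is evaluated from two dot products per simulation.
    sq_norms = np.empty(n_shuffles)
    cross = np.empty(n_shuffles)
    directions = rng.standard_normal((n_shuffles, k))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    if not redraw_direction:
        directions[:] = directions[0]
    chunk = 5_000
    for start in range(0, n_shuffles, chunk):
        size = min(chunk, n_shuffles - start)
        select = _group_assignment_shuffles(rng, n, n_a, size)
        d0 = (select @ dev) / n_a - ((1.0 - select) @ dev) / n_b
        sq_norms[start : start + size] = np.einsum("ij,ij->i", d0, d0)
        cross[start : start + size] = np.einsum(
            "ij,ij->i", d0, directions[start : start + size]
        )

    rejected = np.zeros(delta_grid.size, dtype=bool)
    for g, cand in enumerate(delta_grid):
        dist = np.sqrt(np.maximum(sq_norms + 2.0 * cand * cross + cand * cand, 0.0))
        rejected[g] = observed_delta <= np.quantile(dist, alpha) + _TIE_TOL

    # Smallest grid value from which rejection is contiguous upward.
    delta_star = np.nan
    determinable = False
    if rejected[-1]:
        g = delta_grid.size - 1
        while g > 0 and rejected[g - 1]:
            g -= 1
        delta_star = float(delta_grid[g])
        determinable = True

    d_equiv = np.nan
    if determinable:
        try:
            d_equiv = cohens_d_from_delta(delta_star, xa, xb, seed=rng, method=d_method)
        except ValueError:
            pass  # zero pooled SD (degenerate groups): d undefined, keep nan
    return EquivalenceResult(
        delta_star_rejectable=delta_star,
        alpha=alpha,
        cohens_d_equivalent=float(d_equiv),
        delta_grid=delta_grid,
        rejected=rejected,
        observed_delta=float(observed_delta),
        n_shuffles=n_shuffles,
        determinable=determinable,
        subset=subset,
    )


def cohens_d_from_delta(
    delta_star: float,
    group_a,
    group_b,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
    subset: str = "full",
    method: str = "expected",
) -> float:
    """Average univariate Cohen's d implied by an injected norm.

    For a random unit direction u scaled to ``delta_star``, connection i
    receives offset ``delta_star * u_i``; its univariate effect size is
    ``|delta_star * u_i| / s_i`` with ``s_i`` the pooled across-group SD
    of connection i. ``method="expected"`` averages over ``n_draws``
    random directions, ``"single"`` uses one draw, and ``"sqrt_k"`` uses
    the deterministic ``delta_star / sqrt(K)`` per-connection heuristic.
    """
    if delta_star < 0:
        raise ValueError("delta_star must be >= 0")
    xa = _as_matrix(group_a, subset)
    xb = _as_matrix(group_b, subset)
    n_a, n_b = xa.shape[0], xb.shape[0]
    pooled_var = (
        (n_a - 1) * xa.var(axis=0, ddof=1) + (n_b - 1) * xb.var(axis=0, ddof=1)
    ) / (n_a + n_b - 2)
    s = np.sqrt(pooled_var)
    zero = np.flatnonzero(s == 0.0)
    if zero.size:
        raise ValueError(f"zero pooled SD for connection index(es) {zero.tolist()}")
    k = s.size
    if method == "sqrt_k":
        return float(np.mean((delta_star / np.sqrt(k)) / s))
    if method not in ("expected", "single"):
        raise ValueError(f"unknown method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = 1 if method == "single" else n_draws
    u = rng.standard_normal((draws, k))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    per_draw = np.mean(np.abs(delta_star * u) / s, axis=1)
    return float(per_draw.mean())


def _group_variability(x: np.ndarray) -> float:
    """Mean Euclidean distance of members to their own group mean."""
    return float(np.linalg.norm(x - x.mean(axis=0), axis=1).mean())


def variability_test(
    group_a,
    group_b,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    subset: str = "full",
    two_sided: bool = False,
    comparison_label: str = "",
) -> VariabilityResult:
    """Permutation test on the difference in within-group variability.

    ``delta_variability`` is group A's mean member-to-mean distance
    minus group B's. The null shuffles labels preserving group sizes;
    because unequal sizes make the null asymmetric, the default p-value
    is one-sided in the observed direction (``two_sided=True`` doubles
    the smaller tail).
    """
    _check_disjoint(group_a, group_b)
    xa = _as_matrix(group_a, subset)
    xb = _as_matrix(group_b, subset)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("each group needs >= 2 members for a variability estimate")
    var_a, var_b = _group_variability(xa), _group_variability(xb)
    delta = var_a - var_b
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.vstack([xa, xb])
    n, n_a = x.shape[0], xa.shape[0]
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        perm = rng.permutation(n)
        null[b] = _group_variability(x[perm[:n_a]]) - _group_variability(x[perm[n_a:]])
    upper = float(np.mean(null >= delta - _TIE_TOL))
    lower = float(np.mean(null <= delta + _TIE_TOL))
    if two_sided:
        p = min(1.0, 2.0 * min(upper, lower))
        direction = "two-sided"
    elif delta >= 0:
        p, direction = upper, "greater"
    else:
        p, direction = lower, "less"
    return VariabilityResult(
        group_variability_a=var_a,
        group_variability_b=var_b,
        delta_variability=delta,
        p_value=p,
        null_distribution=null,
        n_shuffles=n_shuffles,
        direction=direction,
        subset=subset,
        comparison_label=comparison_label,
    )


def longitudinal_deltas(
    patterns_by_week: Mapping[str, Sequence[ConnectivityPattern]],
    reference_week: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    subset: str = "full",
) -> list[PermutationResult]:
    """Distance from the reference week to each later week, paired design.

    Each comparison is restricted to subjects observed at both weeks;
    the null permutes the two week labels within each subject pair
    (independent fair swaps), respecting the repeated-measures design.
    """
    if reference_week not in patterns_by_week:
        raise ValueError(f"reference week {reference_week!r} not present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref_by_subject = {
        p.subject_id: p for p in patterns_by_week[reference_week] if p.subject_id
    }
    results = []
    for week, patterns in patterns_by_week.items():
        if week == reference_week:
            continue
        pairs = [
            (ref_by_subject[p.subject_id], p)
            for p in patterns
            if p.subject_id in ref_by_subject
        ]
        if not pairs:
            raise ValueError(
                f"no subjects observed at both {reference_week!r} and {week!r}"
            )
        ref = patterns_to_matrix([a for a, _ in pairs], subset)
        cur = patterns_to_matrix([b for _, b in pairs], subset)
        n = ref.shape[0]
        base = ref.mean(axis=0) - cur.mean(axis=0)
        observed = float(np.linalg.norm(base))
        diff = cur - ref
        swaps = rng.random((n_shuffles, n)) < 0.5
        null = np.linalg.norm(base + 2.0 * (swaps @ diff) / n, axis=1)
        p = float(np.mean(null >= observed - _TIE_TOL))
        results.append(
            PermutationResult(
                observed_delta=observed,
                null_distribution=null,
                p_value=p,
                n_shuffles=n_shuffles,
                subset=subset,
                comparison_label=f"{reference_week}_vs_{week}",
            )
        )
    return results


def week_distance_table(
    patterns_by_week: Mapping[str, Sequence[ConnectivityPattern]],
    reference_week: str,
    subset: str = "full",
):
    """Complete-case table of per-subject distances to the reference week.

    Rows are subjects observed at every week, columns the non-reference
    weeks; entry (s, w) is the Euclidean distance between subject s's
    week-w pattern and their own reference-week pattern.
    """
    import pandas as pd

    if reference_week not in patterns_by_week:
        raise ValueError(f"reference week {reference_week!r} not present")
    weeks = [w for w in patterns_by_week if w != reference_week]
    by_week = {
        w: {p.subject_id: p for p in patterns_by_week[w] if p.subject_id}
        for w in patterns_by_week
    }
    complete = sorted(
        set(by_week[reference_week]).intersection(*(set(by_week[w]) for w in weeks))
    )
    rows = {}
    for sid in complete:
        ref = patterns_to_matrix([by_week[reference_week][sid]], subset)[0]
        rows[sid] = [
            euclidean_delta(patterns_to_matrix([by_week[w][sid]], subset)[0], ref)
            for w in weeks
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=weeks)


def week_variability_anova(per_subject_distances) -> AnovaResult:
    """One-way ANOVA over the week factor on per-subject distances.

    Expects a complete subjects x weeks table (array or DataFrame); a
    table with k weeks and n subjects is tested with (k - 1, n*k - k)
    degrees of freedom, matching the published layout (e.g. 10 subjects
    by 4 weeks -> F(3, 36)).
    """
    table = np.asarray(per_subject_distances, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2D table with >= 2 subjects and >= 2 weeks")
    if np.isnan(table).any():
        raise ValueError(
            "table has missing cells; filter to complete cases upstream "
            "(subjects observed at all weeks)"
        )
    n, k = table.shape
    f_stat, p = stats.f_oneway(*(table[:, j] for j in range(k)))
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p),
        df_between=k - 1,
        df_within=n * k - k,
    )
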