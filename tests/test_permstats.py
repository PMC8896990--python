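import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from connpattern.connectivity import ConnectivityPattern
from connpattern.permstats import (
    cohens_d_from_delta,
    delta_pattern_test,
    equivalence_test,
    euclidean_delta,
    exhaustive_delta_pattern_test,
    longitudinal_deltas,
    variability_test,
    week_distance_table,
    week_variability_anova,
)


def patterns_from(matrix, group="patient", prefix="S"):
    return [
        ConnectivityPattern(
            weights=row, subject_id=f"{prefix}{i:02d}", group=group, week="W1"
        )
        for i, row in enumerate(np.asarray(matrix, dtype=float))
    ]


class TestEuclideanDelta:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(45)
        assert euclidean_delta(v, v) == 0.0

    def test_three_four_five(self):
        a = np.zeros(45)
        b = np.zeros(45)
        b[0], b[1] = 3.0, 4.0
        assert euclidean_delta(a, b) == 5.0

    @given(st.floats(min_value=-20, max_value=20))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert euclidean_delta(c * a, c * b) == pytest.approx(
            abs(c) * euclidean_delta(a, b), rel=1e-9, abs=1e-12
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            euclidean_delta(np.zeros(3), np.zeros(4))


class TestDeltaPatternTest:
    def test_degenerate_identical_patterns(self):
        x = np.tile(np.linspace(0, 1, 45), (6, 1))
        res = delta_pattern_test(x[:4], x[4:], n_shuffles=200, seed=0)
        assert res.observed_delta == 0.0
        assert np.all(res.null_distribution == 0.0)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        xa = rng.standard_normal((3, 45))
        xb = rng.standard_normal((2, 45)) + 0.4
        exact = exhaustive_delta_pattern_test(xa, xb)
        assert exact.n_shuffles == 10  # C(5, 3)
        n_shuffles = 20_000
        mc = delta_pattern_test(xa, xb, n_shuffles=n_shuffles, seed=1)
        tol = 3 * np.sqrt(exact.p_value * (1 - exact.p_value) / n_shuffles) + 1e-9
        assert abs(mc.p_value - exact.p_value) <= tol

    def test_subject_in_both_groups_errors(self, rng):
        pats = patterns_from(rng.standard_normal((3, 45)), prefix="X")
        with pytest.raises(ValueError, match="both groups"):
            delta_pattern_test(pats, pats[:1])

    def test_seeded_determinism(self, rng):
        xa, xb = rng.standard_normal((5, 45)), rng.standard_normal((4, 45))
        r1 = delta_pattern_test(xa, xb, n_shuffles=500, seed=7)
        r2 = delta_pattern_test(xa, xb, n_shuffles=500, seed=7)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_distribution, r2.null_distribution)

    def test_null_delta_estimate_bias_decreases_with_n(self, rng):
        # the observed distance is positively biased; more subjects, less bias
        def mean_observed(n_per_group, reps=40):
            vals = []
            for _ in range(reps):
                xa = rng.standard_normal((n_per_group, 45))
                xb = rng.standard_normal((n_per_group, 45))
                vals.append(euclidean_delta(xa.mean(axis=0), xb.mean(axis=0)))
            return np.mean(vals)

        small, large = mean_observed(5), mean_observed(40)
        assert small > large > 0

    def test_p_value_on_grid(self, rng):
        res = delta_pattern_test(
            rng.standard_normal((4, 45)),
            rng.standard_normal((3, 45)),
            n_shuffles=100,
            seed=2,
        )
        assert res.p_value in {i / 100 for i in range(101)}

    def test_subset_restriction(self, rng):
        pats_a = patterns_from(rng.standard_normal((4, 45)), prefix="A")
        pats_b = patterns_from(rng.standard_normal((3, 45)), group="control", prefix="B")
        res = delta_pattern_test(pats_a, pats_b, n_shuffles=50, seed=0,
                                 subset="interhemispheric")
        assert res.subset == "interhemispheric"


class TestEquivalenceTest:
    def test_degenerate_zero_variance(self):
        # no within-group spread and observed 0: the simulated distance is
        # exactly the injected norm, so every positive candidate is rejected
        xa = np.tile(np.ones(45), (4, 1))
        xb = np.tile(np.ones(45), (3, 1))
        grid = np.array([0.1, 0.2, 0.5, 1.0])
        res = equivalence_test(
            xa, xb, observed_delta=0.0, n_shuffles=100, delta_grid=grid, seed=0
        )
        assert res.determinable
        assert res.delta_star_rejectable == pytest.approx(0.1)
        assert res.rejected.all()

    def test_not_determinable_flagged(self, rng):
        xa = rng.standard_normal((4, 45))
        xb = rng.standard_normal((3, 45))
        res = equivalence_test(
            xa, xb, observed_delta=100.0, n_shuffles=100,
            delta_grid=np.array([0.5, 1.0]), seed=0,
        )
        assert not res.determinable
        assert np.isnan(res.delta_star_rejectable)

    def test_smaller_noise_shrinks_delta_star(self):
        grid = np.round(np.arange(0.1, 4.01, 0.1), 2)
        stars_wide, stars_tight = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            base_a = rng.standard_normal((12, 45))
            base_b = rng.standard_normal((10, 45))
            for scale, bucket in ((1.0, stars_wide), (0.25, stars_tight)):
                res = equivalence_test(
                    scale * base_a,
                    scale * base_b,
                    n_shuffles=400,
                    delta_grid=grid,
                    seed=seed + 100,
                )
                assert res.determinable
                bucket.append(res.delta_star_rejectable)
        assert np.mean(stars_tight) < np.mean(stars_wide)

    def test_invalid_grid_errors(self, rng):
        xa, xb = rng.standard_normal((3, 45)), rng.standard_normal((3, 45))
        with pytest.raises(ValueError):
            equivalence_test(xa, xb, delta_grid=np.array([0.5, 0.4]), n_shuffles=10)
        with pytest.raises(ValueError):
            equivalence_test(xa, xb, delta_grid=np.array([]), n_shuffles=10)

    def test_fixed_direction_mode_runs(self, rng):
        xa, xb = rng.standard_normal((5, 45)), rng.standard_normal((4, 45))
        res = equivalence_test(
            xa, xb, n_shuffles=200, seed=0, redraw_direction=False
        )
        assert res.n_shuffles == 200


class TestCohensD:
    def _unit_sd_groups(self):
        # two observations per group at distance sqrt(2): pooled SD is
        # exactly 1 for every connection
        xa = np.vstack([np.zeros(45), np.full(45, np.sqrt(2.0))])
        xb = np.vstack([np.zeros(45), np.full(45, np.sqrt(2.0))])
        return xa, xb

    def test_zero_delta_gives_zero(self, rng):
        xa, xb = rng.standard_normal((4, 45)), rng.standard_normal((3, 45))
        assert cohens_d_from_delta(0.0, xa, xb, n_draws=10, seed=0) == 0.0

    def test_unit_sd_closed_form(self):
        # oracle: for a uniform unit direction u in R^K,
        # E|u_i| = Gamma(K/2) / (sqrt(pi) Gamma((K+1)/2))
        xa, xb = self._unit_sd_groups()
        k = 45
        expected_abs = np.exp(gammaln(k / 2) - gammaln((k + 1) / 2)) / np.sqrt(np.pi)
        delta = 1.3
        n_draws = 100_000
        d = cohens_d_from_delta(delta, xa, xb, n_draws=n_draws, seed=0)
        assert d == pytest.approx(delta * expected_abs, rel=0.02)
        # and the asymptotic sqrt(2/pi)/sqrt(K) form is close at K = 45
        assert d == pytest.approx(delta * np.sqrt(2 / np.pi) / np.sqrt(k), rel=0.03)

    def test_linearity_in_delta(self):
        xa, xb = self._unit_sd_groups()
        d1 = cohens_d_from_delta(0.7, xa, xb, n_draws=2000, seed=5)
        d2 = cohens_d_from_delta(1.4, xa, xb, n_draws=2000, seed=5)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_zero_pooled_sd_errors(self):
        xa = np.tile(np.ones(45), (3, 1))
        xb = np.tile(np.ones(45), (3, 1))
        with pytest.raises(ValueError, match="zero pooled SD"):
            cohens_d_from_delta(1.0, xa, xb, n_draws=10, seed=0)

    def test_sqrt_k_heuristic(self):
        xa, xb = self._unit_sd_groups()
        d = cohens_d_from_delta(1.0, xa, xb, method="sqrt_k")
        assert d == pytest.approx(1.0 / np.sqrt(45))

    def test_negative_delta_errors(self):
        xa, xb = self._unit_sd_groups()
        with pytest.raises(ValueError):
            cohens_d_from_delta(-1.0, xa, xb)


class TestVariabilityTest:
    def test_identical_members_zero_variability(self, rng):
        xa = np.tile(rng.standard_normal(45), (4, 1))
        xb = rng.standard_normal((4, 45))
        res = variability_test(xa, xb, n_shuffles=100, seed=0)
        assert res.group_variability_a == 0.0
        assert res.delta_variability == -res.group_variability_b

    def test_swapping_groups_negates_delta(self, rng):
        xa, xb = rng.standard_normal((5, 45)), rng.standard_normal((6, 45))
        r1 = variability_test(xa, xb, n_shuffles=50, seed=0)
        r2 = variability_test(xb, xa, n_shuffles=50, seed=0)
        assert r1.delta_variability == pytest.approx(-r2.delta_variability)

    def test_group_of_one_errors(self, rng):
        with pytest.raises(ValueError):
            variability_test(rng.standard_normal((1, 45)), rng.standard_normal((3, 45)))

    def test_doubled_spread_detected(self):
        positive = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            xa = 2.0 * rng.standard_normal((12, 45))
            xb = rng.standard_normal((10, 45))
            res = variability_test(xa, xb, n_shuffles=100, seed=seed)
            positive += res.delta_variability > 0
        assert positive == 10

    def test_two_sided_option(self, rng):
        xa, xb = rng.standard_normal((5, 45)), rng.standard_normal((4, 45))
        res = variability_test(xa, xb, n_shuffles=200, seed=1, two_sided=True)
        assert res.direction == "two-sided"
        assert 0.0 <= res.p_value <= 1.0


class TestLongitudinalDeltas:
    def _by_week(self, rng, n=8, weeks=("W1", "W4", "W12"), step_week=None, step=0.0):
        base = rng.standard_normal((n, 45))
        out = {}
        for w in weeks:
            noise = 0.2 * rng.standard_normal((n, 45))
            shift = step if w == step_week else 0.0
            out[w] = patterns_from(base + noise + shift, prefix="P")
        return out

    def test_identical_weeks_give_p_one(self, rng):
        base = rng.standard_normal((6, 45))
        by_week = {
            "W1": patterns_from(base, prefix="P"),
            "W4": patterns_from(base, prefix="P"),
        }
        (res,) = longitudinal_deltas(by_week, "W1", n_shuffles=100, seed=0)
        assert res.observed_delta == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_step_change_week_has_minimal_p(self, rng):
        by_week = self._by_week(rng, step_week="W12", step=1.0)
        results = longitudinal_deltas(by_week, "W1", n_shuffles=1000, seed=3)
        by_label = {r.comparison_label: r for r in results}
        assert by_label["W1_vs_W12"].p_value == min(r.p_value for r in results)
        # sign-flip null with n subjects bottoms out near 2 / 2^n (the
        # all-flip configuration reproduces the observed distance)
        assert by_label["W1_vs_W12"].p_value <= 0.02

    def test_missing_reference_errors(self, rng):
        with pytest.raises(ValueError, match="reference"):
            longitudinal_deltas({"W4": []}, "W1")

    def test_no_overlap_errors(self, rng):
        by_week = {
            "W1": patterns_from(rng.standard_normal((3, 45)), prefix="A"),
            "W4": patterns_from(rng.standard_normal((3, 45)), prefix="B"),
        }
        with pytest.raises(ValueError, match="both"):
            longitudinal_deltas(by_week, "W1", n_shuffles=10)

    def test_restricted_to_common_subjects(self, rng):
        w1 = patterns_from(rng.standard_normal((5, 45)), prefix="P")
        w4 = patterns_from(rng.standard_normal((3, 45)), prefix="P")
        (res,) = longitudinal_deltas({"W1": w1, "W4": w4}, "W1", n_shuffles=50, seed=0)
        expected = euclidean_delta(
            np.mean([p.weights for p in w1[:3]], axis=0),
            np.mean([p.weights for p in w4], axis=0),
        )
        assert res.observed_delta == pytest.approx(expected)

    def test_controls_null_rarely_significant(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            by_week = self._by_week(rng, n=10, weeks=("W1", "W4"))
            (res,) = longitudinal_deltas(by_week, "W1", n_shuffles=200, seed=seed)
            hits += res.p_value < 0.05
        assert hits <= 5  # binomial(30, 0.05) upper bound


class TestWeekVariabilityAnova:
    def test_constant_within_subject_gives_zero_f(self, rng):
        col = rng.standard_normal(10)
        table = np.tile(col[:, None], (1, 4))
        res = week_variability_anova(table)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_10_by_4(self, rng):
        res = week_variability_anova(rng.standard_normal((10, 4)))
        assert (res.df_between, res.df_within) == (3, 36)

    def test_matches_scipy_f_oneway(self, rng):
        table = rng.standard_normal((8, 5))
        res = week_variability_anova(table)
        f, p = stats.f_oneway(*(table[:, j] for j in range(5)))
        assert res.f_stat == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_null_p_values_uniform(self):
        # distributional oracle: under H0 the ANOVA p-value is Uniform(0,1)
        rng = np.random.default_rng(99)
        pvals = [
            week_variability_anova(rng.standard_normal((10, 4))).p_value
            for _ in range(10_000)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_missing_cells_error(self):
        table = np.ones((4, 3))
        table[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            week_variability_anova(table)


class TestWeekDistanceTable:
    def test_complete_case_distances(self, rng):
        w1 = patterns_from(rng.standard_normal((4, 45)), prefix="P")
        w4 = patterns_from(rng.standard_normal((4, 45)), prefix="P")[:3]
        table = week_distance_table({"W1": w1, "W4": w4}, "W1")
        assert table.shape == (3, 1)
        sid = table.index[0]
        a = next(p for p in w1 if p.subject_id == sid)
        b = next(p for p in w4 if p.subject_id == sid)
        assert table.loc[sid, "W4"] == pytest.approx(
            euclidean_delta(a.weights, b.weights)
        )
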