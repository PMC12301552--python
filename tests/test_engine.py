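import numpy as np
import pytest

from refintervals import (
    DegenerateDataError,
    MeasurandSeries,
    MethodChoice,
    MethodPolicy,
    analyze_measurand,
    assess_normality,
    bootstrap_limit_ci,
    ci_ri_ratio,
    compare_partitions,
    minmax_ri,
    nonparametric_percentile_ri,
    parametric_limits,
    parametric_ri,
    select_method,
)

Z = 1.959963984540054


def standardized_sample(n: int, seed: int = 0) -> np.ndarray:
    """A sample with exact zero mean and unit (n-1) SD."""
    x = np.random.default_rng(seed).standard_normal(n)
    x = x - x.mean()
    return x / x.std(ddof=1)


class TestAssessNormality:
    def test_gaussian_flag_matches_strict_gate(self, policy):
        rng = np.random.default_rng(1)
        for sample in (rng.normal(0, 1, 80), rng.lognormal(0, 1, 80)):
            res = assess_normality(sample, policy)
            assert res.gaussian == (res.p_value > policy.normality_alpha)

    def test_p_equal_to_alpha_is_not_gaussian(self):
        # strict '>' at the boundary: set the gate to the observed p itself
        x = np.random.default_rng(2).normal(0, 1, 60)
        p_obs = assess_normality(x).p_value
        res = assess_normality(x, MethodPolicy(normality_alpha=p_obs))
        assert res.gaussian is False

    def test_labels(self):
        x = np.random.default_rng(3).normal(0, 1, 200)
        res = assess_normality(x)
        assert res.distribution_label in ("G", "NG")
        assert res.distribution_label == ("G" if res.gaussian else "NG")

    def test_constant_not_assessable(self):
        with pytest.raises(DegenerateDataError):
            assess_normality(np.full(50, 3.0))

    def test_too_short_not_assessable(self):
        with pytest.raises(DegenerateDataError):
            assess_normality(np.array([1.0, 2.0]))


class TestSelectMethod:
    @pytest.mark.parametrize(
        "n, gaussian, expected",
        [
            (86, False, MethodChoice.NONPARAMETRIC_PERCENTILE),
            (86, True, MethodChoice.PARAMETRIC),
            (40, True, MethodChoice.PARAMETRIC),
            (40, False, MethodChoice.NONPARAMETRIC_PERCENTILE),
            (120, True, MethodChoice.PARAMETRIC),  # band extended upward
            (39, True, MethodChoice.MINMAX),
            (28, None, MethodChoice.MINMAX),
            (20, None, MethodChoice.MINMAX),
            (19, None, MethodChoice.DESCRIPTIVE_ONLY),
            (17, None, MethodChoice.DESCRIPTIVE_ONLY),
            (10, None, MethodChoice.DESCRIPTIVE_ONLY),
            (9, None, MethodChoice.NO_REPORT),
            (0, None, MethodChoice.NO_REPORT),
        ],
    )
    def test_band_routing(self, n, gaussian, expected, policy):
        assert select_method(n, gaussian, policy) is expected

    def test_unknown_verdict_in_full_band_routes_nonparametric(self, policy):
        assert select_method(86, None, policy) is MethodChoice.NONPARAMETRIC_PERCENTILE

    def test_labels(self):
        assert MethodChoice.PARAMETRIC.label == "P"
        assert MethodChoice.NONPARAMETRIC_PERCENTILE.label == "NP"
        assert MethodChoice.MINMAX.label == "NP"
        assert MethodChoice.DESCRIPTIVE_ONLY.label == "-"


class TestParametricRI:
    @pytest.mark.parametrize(
        "mean, sd, lower_2dp",
        [(48.17, 10.82, 26.96), (4.60, 0.87, 2.89), (31.63, 4.96, 21.91)],
    )
    def test_lower_limit_closed_form(self, mean, sd, lower_2dp, policy):
        lower, _ = parametric_limits(mean, sd, policy)
        assert round(lower, 2) == lower_2dp

    def test_standard_normal_limits(self, policy):
        lower, upper = parametric_limits(0.0, 1.0, policy)
        assert lower == pytest.approx(-1.959964, abs=1e-6)
        assert upper == pytest.approx(1.959964, abs=1e-6)

    def test_sample_path_matches_closed_form(self, policy):
        x = 48.17 + 10.82 * standardized_sample(86)
        lower, upper = parametric_ri(x, policy)
        assert lower == pytest.approx(48.17 - Z * 10.82, abs=1e-9)
        assert upper == pytest.approx(48.17 + Z * 10.82, abs=1e-9)

    def test_constant_input_degenerate(self, policy):
        with pytest.raises(DegenerateDataError):
            parametric_ri(np.full(10, 5.0), policy)


def oracle_percentile(values, p):
    """Brute-force sort-and-interpolate at rank p*(n+1), clamped to [1, n]."""
    x = sorted(values)
    n = len(x)
    rank = min(max(p * (n + 1), 1.0), float(n))
    lo = int(rank)
    frac = rank - lo
    if lo >= n:
        return x[-1]
    return x[lo - 1] + frac * (x[lo] - x[lo - 1])


class TestNonparametricPercentileRI:
    def test_integer_ranks_1_to_39(self, policy):
        lower, upper = nonparametric_percentile_ri(np.arange(1.0, 40.0), policy)
        assert (lower, upper) == (1.0, 39.0)

    def test_fractional_rank_crafted_n84(self, policy):
        # 2nd/3rd order statistics 9900/10000 -> rank 2.125 -> 9912.5
        x = np.concatenate([[9800.0, 9900.0, 10000.0], np.linspace(10100, 32800, 81)])
        lower, _ = nonparametric_percentile_ri(x, policy)
        assert lower == pytest.approx(9912.5)

    def test_matches_brute_force_oracle(self, policy):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(5, 200))
            x = rng.normal(0, 10, n)
            lower, upper = nonparametric_percentile_ri(x, policy)
            assert lower == pytest.approx(oracle_percentile(x, 0.025))
            assert upper == pytest.approx(oracle_percentile(x, 0.975))

    def test_limits_within_min_max(self, policy):
        x = np.random.default_rng(11).lognormal(0, 1, 55)
        lower, upper = nonparametric_percentile_ri(x, policy)
        assert x.min() <= lower <= upper <= x.max()

    def test_alternative_rank_convention(self):
        policy = MethodPolicy(quantile_convention="rank_n_minus_1")
        x = np.arange(1.0, 40.0)
        lower, upper = nonparametric_percentile_ri(x, policy)
        # numpy's default linear interpolation is the 1 + p*(n-1) convention
        assert lower == pytest.approx(np.quantile(x, 0.025))
        assert upper == pytest.approx(np.quantile(x, 0.975))


class TestMinMaxRI:
    def test_female_hb_extremes(self, policy):
        x = np.linspace(8.7, 16.8, 28)
        assert minmax_ri(x) == (8.7, 16.8)

    def test_arterial_ph_extremes(self):
        x = np.linspace(7.368, 7.515, 33)
        assert minmax_ri(x) == (7.368, 7.515)

    def test_two_equal_values(self):
        assert minmax_ri(np.array([5.0, 5.0])) == (5.0, 5.0)

    def test_single_value_degenerate(self):
        with pytest.raises(DegenerateDataError):
            minmax_ri(np.array([5.0]))


class TestBootstrapLimitCI:
    def test_constant_vector_zero_width(self, policy):
        lci, uci = bootstrap_limit_ci(np.full(30, 4.0), MethodChoice.PARAMETRIC, policy)
        assert lci == (4.0, 4.0) and uci == (4.0, 4.0)

    def test_deterministic_under_fixed_seed(self, policy):
        x = np.random.default_rng(1).normal(0, 1, 60)
        a = bootstrap_limit_ci(x, MethodChoice.PARAMETRIC, policy, np.random.default_rng(42))
        b = bootstrap_limit_ci(x, MethodChoice.PARAMETRIC, policy, np.random.default_rng(42))
        assert a == b

    def test_vectorized_path_matches_callable_estimator(self, policy):
        # dual route: same resample indices, independent limit computation
        x = np.random.default_rng(2).normal(10, 2, 50)
        fast = bootstrap_limit_ci(
            x, MethodChoice.PARAMETRIC, policy, np.random.default_rng(7)
        )
        slow = bootstrap_limit_ci(
            x, lambda v: parametric_ri(v, policy), policy, np.random.default_rng(7)
        )
        assert fast[0] == pytest.approx(slow[0])
        assert fast[1] == pytest.approx(slow[1])

    def test_percentile_method_dual_route(self, policy):
        x = np.random.default_rng(3).lognormal(0, 0.5, 60)
        fast = bootstrap_limit_ci(
            x, MethodChoice.NONPARAMETRIC_PERCENTILE, policy, np.random.default_rng(9)
        )
        slow = bootstrap_limit_ci(
            x,
            lambda v: nonparametric_percentile_ri(v, policy),
            policy,
            np.random.default_rng(9),
        )
        assert fast[0] == pytest.approx(slow[0])
        assert fast[1] == pytest.approx(slow[1])

    def test_ci_ordering(self, policy):
        x = np.random.default_rng(4).normal(0, 1, 80)
        (l1, l2), (u1, u2) = bootstrap_limit_ci(x, MethodChoice.PARAMETRIC, policy)
        assert l1 <= l2 and u1 <= u2


class TestCiRiRatio:
    def test_printed_row_arithmetic(self):
        # widths 1.53 / 8.16 from a published hemoglobin row
        assert ci_ri_ratio((7.9, 9.43), (8.62, 16.78)) == pytest.approx(0.1875, abs=5e-4)

    def test_zero_width_ci(self):
        assert ci_ri_ratio((5.0, 5.0), (0.0, 10.0)) == 0.0

    def test_ratio_above_one_permitted(self):
        assert ci_ri_ratio((0.0, 20.0), (0.0, 10.0)) == pytest.approx(2.0)

    def test_zero_width_ri_undefined(self):
        with pytest.raises(DegenerateDataError):
            ci_ri_ratio((1.0, 2.0), (5.0, 5.0))


class TestComparePartitions:
    def test_identical_samples_p_near_one(self, policy):
        x = np.random.default_rng(5).normal(0, 1, 40)
        assert compare_partitions(x, x, policy).p_value >= 0.99

    def test_well_separated_samples(self, policy):
        rng = np.random.default_rng(6)
        res = compare_partitions(rng.normal(0, 1, 50), rng.normal(5, 1, 50), policy)
        assert res.p_value < 1e-6
        assert res.significant

    def test_welch_option(self):
        policy = MethodPolicy(partition_test="welch")
        rng = np.random.default_rng(7)
        res = compare_partitions(rng.normal(0, 1, 30), rng.normal(3, 2, 30), policy)
        assert res.test == "welch" and res.p_value < 1e-3

    def test_degenerate_input(self, policy):
        with pytest.raises(DegenerateDataError):
            compare_partitions(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]), policy)


def _series(values, name="X", partition="All"):
    return MeasurandSeries(name, "u", partition, np.asarray(values, float))


class TestAnalyzeMeasurand:
    def test_descriptive_only_band(self, policy):
        rng = np.random.default_rng(1)
        res = analyze_measurand(_series(rng.normal(10, 3, 17)), policy)
        assert res.method is MethodChoice.DESCRIPTIVE_ONLY
        assert res.lower_limit is None and res.lrl_ci is None
        assert res.descriptive.n == 17

    def test_all_zero_series_short_circuits(self, policy):
        res = analyze_measurand(_series(np.zeros(87)), policy)
        assert res.method.label == "-"
        assert res.lower_limit is None and res.normality is None
        assert res.descriptive.n == 87

    def test_gaussian_full_band_parametric_closed_form(self, policy):
        # seed 2: screen-clean and comfortably Gaussian (Shapiro p ~ 0.96)
        x = 50.0 + 5.0 * standardized_sample(86, seed=2)
        res = analyze_measurand(_series(x), policy)
        assert res.method is MethodChoice.PARAMETRIC
        assert res.screen.removed == []
        assert res.lower_limit == pytest.approx(50 - Z * 5, abs=1e-9)
        assert res.upper_limit == pytest.approx(50 + Z * 5, abs=1e-9)
        assert res.lrl_ci is not None and res.url_ci is not None
        assert res.distribution_label == "G"

    def test_minmax_band_no_cis(self, policy):
        x = np.linspace(8.7, 16.8, 28)
        res = analyze_measurand(_series(x), policy)
        assert res.method is MethodChoice.MINMAX
        assert (res.lower_limit, res.upper_limit) == (8.7, 16.8)
        assert res.lrl_ci is None and res.url_ci is None
        assert res.normality is None

    def test_empty_series_no_report(self, policy):
        res = analyze_measurand(_series([]), policy)
        assert res.method is MethodChoice.NO_REPORT
        assert res.descriptive is None

    def test_deterministic_under_policy_seed(self, policy):
        x = np.random.default_rng(8).lognormal(1, 0.4, 70)
        a = analyze_measurand(_series(x), policy)
        b = analyze_measurand(_series(x), policy)
        assert a.lrl_ci == b.lrl_ci and a.url_ci == b.url_ci

    def test_ratio_flags_follow_threshold(self, policy):
        x = np.random.default_rng(9).normal(100, 10, 86)
        res = analyze_measurand(_series(x), policy)
        if res.lrl_ratio is not None:
            assert res.imprecise_flag_lower == (
                res.lrl_ratio > policy.ci_ratio_flag_threshold
            )
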