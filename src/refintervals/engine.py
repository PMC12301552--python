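"""Reference-interval inference: normality gate, method routing, limits, CIs.

The full sequence for one measurand/partition is :func:`analyze_measurand`:

1. iterative outlier screen;
2. descriptive statistics on the retained values;
3. Shapiro-Wilk normality assessment (only when the retained n reaches the
   full-method band), Gaussian iff p strictly exceeds the 0.2 gate;
4. method routing on the post-screening n:
   n >= 40 parametric/nonparametric-percentile, 20 <= n < 40 min-max,
   10 <= n < 20 descriptive values only, n < 10 no report;
5. reference limits by the routed method;
6. percentile-bootstrap 90% CIs of both limits (parametric and percentile
   methods only) plus CI-width / RI-width ratios and imprecision flags.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .model import (
    DescriptiveStats,
    MeasurandSeries,
    MethodPolicy,
    stable_substream_seed,
)
from .screening import OutlierScreenResult, iterative_screen

__all__ = [
    "NormalityAssessment",
    "MethodChoice",
    "ReferenceIntervalResult",
    "PartitionComparison",
    "assess_normality",
    "select_method",
    "parametric_ri",
    "parametric_limits",
    "nonparametric_percentile_ri",
    "rank_quantile",
    "minmax_ri",
    "bootstrap_limit_ci",
    "ci_ri_ratio",
    "compare_partitions",
    "analyze_measurand",
]


@dataclass(frozen=True)
class NormalityAssessment:
    """Shapiro-Wilk outcome; ``gaussian`` iff p strictly exceeds the gate."""

    w_stat: float
    p_value: float
    gaussian: bool

    @property
    def distribution_label(self) -> str:
        return "G" if self.gaussian else "NG"


class MethodChoice(enum.Enum):
    PARAMETRIC = "P"
    NONPARAMETRIC_PERCENTILE = "NP"
    MINMAX = "NP"  # printed label is also "NP": limits are sample min/max
    DESCRIPTIVE_ONLY = "-"
    NO_REPORT = "-"

    def __new__(cls, label: str) -> "MethodChoice":
        obj = object.__new__(cls)
        obj._value_ = len(cls.__members__)
        obj.label = label
        return obj


@dataclass(frozen=True)
class PartitionComparison:
    """Two-sided location comparison between two partitions of a measurand."""

    statistic: float
    p_value: float
    significant: bool
    test: str


@dataclass(frozen=True)
class ReferenceIntervalResult:
    """Everything one report row carries for a measurand/partition."""

    series: MeasurandSeries
    screen: OutlierScreenResult
    descriptive: DescriptiveStats | None
    normality: NormalityAssessment | None
    method: MethodChoice
    lower_limit: float | None = None
    upper_limit: float | None = None
    lrl_ci: tuple[float, float] | None = None
    url_ci: tuple[float, float] | None = None
    lrl_ratio: float | None = None
    url_ratio: float | None = None
    imprecise_flag_lower: bool = False
    imprecise_flag_upper: bool = False

    @property
    def distribution_label(self) -> str | None:
        return self.normality.distribution_label if self.normality else None

    @property
    def n(self) -> int:
        return self.descriptive.n if self.descriptive else 0


def assess_normality(
    values: np.ndarray, policy: MethodPolicy | None = None
) -> NormalityAssessment:
    """Shapiro-Wilk test with a strict ``p > normality_alpha`` Gaussian gate."""
    policy = policy or MethodPolicy()
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise DegenerateDataError(f"normality not assessable at n={arr.size}")
    if np.ptp(arr) == 0.0:
        raise DegenerateDataError("normality not assessable on constant input")
    w, p = stats.shapiro(arr)
    return NormalityAssessment(
        w_stat=float(w), p_value=float(p), gaussian=bool(p > policy.normality_alpha)
    )


def select_method(
    n: int, gaussian: bool | None, policy: MethodPolicy | None = None
) -> MethodChoice:
    """Route to an estimation method by post-screening sample size.

    Within the full band the Shapiro-Wilk verdict decides parametric vs
    nonparametric percentile; an unknown verdict there (constant data)
    falls back to the percentile method.
    """
    policy = policy or MethodPolicy()
    if n < 0:
        raise ValueError("n must be non-negative")
    full_lo, full_hi = policy.band_full
    mm_lo, mm_hi = policy.band_minmax
    desc_lo, desc_hi = policy.band_descriptive_only
    if n >= full_lo and (full_hi is None or n <= full_hi):
        if gaussian is True:
            return MethodChoice.PARAMETRIC
        return MethodChoice.NONPARAMETRIC_PERCENTILE
    if mm_lo <= n <= (mm_hi if mm_hi is not None else n):
        return MethodChoice.MINMAX
    if desc_lo <= n <= (desc_hi if desc_hi is not None else n):
        return MethodChoice.DESCRIPTIVE_ONLY
    return MethodChoice.NO_REPORT


def parametric_limits(
    mean: float, sd: float, policy: MethodPolicy | None = None
) -> tuple[float, float]:
    """Closed-form parametric limits mean -/+ z*sd (z = 0.975 normal quantile)."""
    policy = policy or MethodPolicy()
    z = policy.z_multiplier
    return (mean - z * sd, mean + z * sd)


def parametric_ri(
    values: np.ndarray, policy: MethodPolicy | None = None
) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("parametric limits require at least 2 values")
    if np.ptp(arr) == 0.0:
        raise DegenerateDataError("parametric limits undefined for constant input")
    return parametric_limits(float(np.mean(arr)), float(np.std(arr, ddof=1)), policy)


def rank_quantile(sorted_values: np.ndarray, p: float, convention: str) -> float:
    """Quantile by linear interpolation of order statistics.

    ``rank_n_plus_1`` places probability p at rank ``p*(n+1)`` (CLSI style);
    ``rank_n_minus_1`` at ``1 + p*(n-1)``.  Ranks are clamped to [1, n].
    """
    n = sorted_values.shape[-1]
    if n == 0:
        raise DegenerateDataError("quantile of empty sample")
    if convention == "rank_n_plus_1":
        rank = p * (n + 1)
    elif convention == "rank_n_minus_1":
        rank = 1.0 + p * (n - 1)
    else:
        raise ValueError(f"unknown quantile convention {convention!r}")
    rank = min(max(rank, 1.0), float(n))
    lo = int(math.floor(rank))
    frac = rank - lo
    base = sorted_values[..., lo - 1]
    if frac == 0.0 or lo >= n:
        return base
    return base + frac * (sorted_values[..., lo] - base)


def nonparametric_percentile_ri(
    values: np.ndarray, policy: MethodPolicy | None = None
) -> tuple[float, float]:
    """Limits at the lower_p/upper_p sample percentiles (rank-interpolated)."""
    policy = policy or MethodPolicy()
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise DegenerateDataError("percentile limits of empty sample")
    conv = policy.quantile_convention
    return (
        float(rank_quantile(arr, policy.lower_p, conv)),
        float(rank_quantile(arr, policy.upper_p, conv)),
    )


def minmax_ri(values: np.ndarray) -> tuple[float, float]:
    """Limits equal to the sample extremes, exactly."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("min-max limits require at least 2 values")
    return (float(np.min(arr)), float(np.max(arr)))


def _bootstrap_limits(
    values: np.ndarray,
    method: MethodChoice,
    policy: MethodPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(B,) arrays of resampled lower and upper limits, vectorized over B."""
    n = values.size
    idx = rng.integers(0, n, size=(policy.bootstrap_B, n))
    resamples = values[idx]
    if method is MethodChoice.PARAMETRIC:
        means = resamples.mean(axis=1)
        sds = resamples.std(axis=1, ddof=1)
        z = policy.z_multiplier
        return means - z * sds, means + z * sds
    ordered = np.sort(resamples, axis=1)
    conv = policy.quantile_convention
    lower = rank_quantile(ordered, policy.lower_p, conv)
    upper = rank_quantile(ordered, policy.upper_p, conv)
    return np.asarray(lower), np.asarray(upper)


def bootstrap_limit_ci(
    values: np.ndarray,
    method: MethodChoice | Callable[[np.ndarray], tuple[float, float]],
    policy: MethodPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile-bootstrap CIs of both reference limits.

    ``method`` is normally a :class:`MethodChoice` (vectorized resampling);
    a callable estimator ``values -> (lower, upper)`` is accepted for
    testing against independent implementations.  Each limit's CI is the
    central ``ci_level`` percentile interval of its B resampled estimates.
    """
    policy = policy or MethodPolicy()
    rng = rng if rng is not None else np.random.default_rng(policy.rng_seed)
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("bootstrap requires at least 2 values")
    if np.ptp(arr) == 0.0:
        v = float(arr[0])
        return ((v, v), (v, v))
    if isinstance(method, MethodChoice):
        lowers, uppers = _bootstrap_limits(arr, method, policy, rng)
    else:
        idx = rng.integers(0, arr.size, size=(policy.bootstrap_B, arr.size))
        pairs = [method(arr[row]) for row in idx]
        lowers = np.array([p[0] for p in pairs])
        uppers = np.array([p[1] for p in pairs])
    tail = (1.0 - policy.ci_level) / 2.0 * 100.0
    lo_ci = np.percentile(lowers, [tail, 100.0 - tail])
    hi_ci = np.percentile(uppers, [tail, 100.0 - tail])
    return (
        (float(lo_ci[0]), float(lo_ci[1])),
        (float(hi_ci[0]), float(hi_ci[1])),
    )


def ci_ri_ratio(ci: tuple[float, float], ri: tuple[float, float]) -> float:
    """Width of a limit's CI divided by the width of the reference interval."""
    ri_width = ri[1] - ri[0]
    if ri_width <= 0.0:
        raise DegenerateDataError("CI/RI ratio undefined for zero-width RI")
    return (ci[1] - ci[0]) / ri_width


def compare_partitions(
    a: np.ndarray, b: np.ndarray, policy: MethodPolicy | None = None
) -> PartitionComparison:
    """Two-sided two-sample location test between partitions.

    Defaults to the Wilcoxon rank-sum (Mann-Whitney) test; ``welch``
    selects Welch's unequal-variance t-test.
    """
    policy = policy or MethodPolicy()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateDataError("partition comparison needs n >= 3 per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return PartitionComparison(0.0, 1.0, False, policy.partition_test)
    if policy.partition_test == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return PartitionComparison(
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < policy.partition_test_alpha),
        test=policy.partition_test,
    )


def analyze_measurand(
    series: MeasurandSeries,
    policy: MethodPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceIntervalResult:
    """Run the full screen -> route -> estimate -> bootstrap pipeline."""
    policy = policy or MethodPolicy()
    if rng is None:
        rng = np.random.default_rng(
            stable_substream_seed(policy.rng_seed, series.measurand, series.partition)
        )
    screen = iterative_screen(series, policy)
    retained = screen.retained
    if retained.size == 0:
        return ReferenceIntervalResult(
            series=series,
            screen=screen,
            descriptive=None,
            normality=None,
            method=MethodChoice.NO_REPORT,
        )
    descriptive = DescriptiveStats.from_values(retained)
    constant = np.ptp(retained) == 0.0

    normality: NormalityAssessment | None = None
    # Shapiro-Wilk is not assessable above n=5000; such samples fall through
    # with an unknown verdict and route to the nonparametric percentile.
    if policy.band_full[0] <= retained.size <= 5000 and not constant:
        normality = assess_normality(retained, policy)

    if constant:
        # Degenerate panel rows (e.g. a count that is zero in every animal)
        # report descriptive values only — no distribution, no limits.
        return ReferenceIntervalResult(
            series=series,
            screen=screen,
            descriptive=descriptive,
            normality=None,
            method=MethodChoice.NO_REPORT,
        )

    method = select_method(
        retained.size, normality.gaussian if normality else None, policy
    )
    if method in (MethodChoice.DESCRIPTIVE_ONLY, MethodChoice.NO_REPORT):
        return ReferenceIntervalResult(
            series=series,
            screen=screen,
            descriptive=descriptive,
            normality=normality,
            method=method,
        )

    if method is MethodChoice.PARAMETRIC:
        lower, upper = parametric_ri(retained, policy)
    elif method is MethodChoice.NONPARAMETRIC_PERCENTILE:
        lower, upper = nonparametric_percentile_ri(retained, policy)
    else:
        lower, upper = minmax_ri(retained)

    lrl_ci = url_ci = None
    lrl_ratio = url_ratio = None
    flag_lo = flag_hi = False
    if method in (MethodChoice.PARAMETRIC, MethodChoice.NONPARAMETRIC_PERCENTILE):
        lrl_ci, url_ci = bootstrap_limit_ci(retained, method, policy, rng)
        if upper > lower:
            lrl_ratio = ci_ri_ratio(lrl_ci, (lower, upper))
            url_ratio = ci_ri_ratio(url_ci, (lower, upper))
            flag_lo = lrl_ratio > policy.ci_ratio_flag_threshold
            flag_hi = url_ratio > policy.ci_ratio_flag_threshold
    return ReferenceIntervalResult(
        series=series,
        screen=screen,
        descriptive=descriptive,
        normality=normality,
        method=method,
        lower_limit=float(lower),
        upper_limit=float(upper),
        lrl_ci=lrl_ci,
        url_ci=url_ci,
        lrl_ratio=lrl_ratio,
        url_ratio=url_ratio,
        imprecise_flag_lower=flag_lo,
        imprecise_flag_upper=flag_hi,
    )
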