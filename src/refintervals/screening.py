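"""Iterative outlier screening for reference-interval estimation.

Two single-pass detectors are combined by :func:`iterative_screen`:

* Horn screening (samples with n > 30): Tukey interquartile fences applied
  to the Box-Cox transform of the sample; every value whose transform falls
  strictly outside the fences is flagged.
* Dixon screening (n <= 30): gap-to-range ratios of the two extremes; the
  extreme with the larger ratio is flagged when the ratio reaches the
  rejection threshold (default 1/3), at most one value per pass.

Flagged values are removed and the screen reruns on the remainder — with the
detector re-chosen for the new n — until a pass flags nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import DegenerateDataError, DomainError
from .model import MeasurandSeries, MethodPolicy

__all__ = [
    "TransformResult",
    "FenceBounds",
    "OutlierScreenResult",
    "boxcox_transform",
    "horn_screen",
    "dixon_screen",
    "iterative_screen",
    "DIXON_CRITICAL_R10",
]

logger = logging.getLogger("refintervals")

#: Two-sided 95% critical values for Dixon's r10 ratio, n = 3..30
#: (Rorabacher 1991).  Used only when ``dixon_use_critical_table`` is set.
DIXON_CRITICAL_R10: dict[int, float] = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.298,
}


@dataclass(frozen=True)
class TransformResult:
    """Box-Cox transform outcome: exponent, positivity shift, transformed data."""

    lambda_hat: float
    shift: float
    transformed: np.ndarray


@dataclass(frozen=True)
class FenceBounds:
    """Tukey fences on the transformed scale."""

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


@dataclass
class OutlierScreenResult:
    """Retained/removed split plus the per-iteration audit trail.

    ``removed`` holds ``(value, iteration, method)`` triples; retained and
    removed values together are always a multiset-exact partition of the
    input.
    """

    retained: np.ndarray
    removed: list[tuple[float, int, str]] = field(default_factory=list)
    iterations: int = 0
    fences: FenceBounds | None = None
    transform: TransformResult | None = None

    @property
    def removed_values(self) -> list[float]:
        return [v for v, _, _ in self.removed]


def boxcox_transform(
    values: np.ndarray,
    lambda_search: tuple[float, float] = (-3.0, 3.0),
    shift: bool = True,
    lambda_fixed: float | None = None,
) -> TransformResult:
    """Box-Cox transform with the exponent chosen by profile likelihood.

    The exponent maximizes the Box-Cox log-likelihood over the closed
    ``lambda_search`` interval, unless ``lambda_fixed`` pins it.
    Non-positive inputs are shifted by ``1 - min`` first when ``shift`` is
    enabled; otherwise they are a domain error.  ``lambda = 0`` uses the log
    branch, else ``(x**lam - 1) / lam``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise DegenerateDataError("Box-Cox requires at least 3 values")
    if not np.all(np.isfinite(arr)):
        raise DomainError("Box-Cox input must be finite")
    offset = 0.0
    if np.min(arr) <= 0.0:
        if not shift:
            raise DomainError("non-positive values with shifting disabled")
        offset = 1.0 - float(np.min(arr))
    shifted = arr + offset
    if np.ptp(shifted) == 0.0:
        raise DegenerateDataError("constant input has no Box-Cox transform")
    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    else:
        lo, hi = lambda_search
        res = optimize.minimize_scalar(
            lambda lam: -stats.boxcox_llf(lam, shifted),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(res.x)
    return TransformResult(
        lambda_hat=lam, shift=offset, transformed=special.boxcox(shifted, lam)
    )


def _tukey_fences(transformed: np.ndarray, k: float) -> FenceBounds:
    # Quartiles by linear interpolation of order statistics (numpy "linear",
    # i.e. the type-7 convention); swappable only by changing this call site.
    q1, q3 = np.quantile(transformed, [0.25, 0.75], method="linear")
    iqr = float(q3 - q1)
    return FenceBounds(
        q1=float(q1),
        q3=float(q3),
        iqr=iqr,
        lower_fence=float(q1 - k * iqr),
        upper_fence=float(q3 + k * iqr),
    )


def _horn_flags(
    values: np.ndarray, policy: MethodPolicy
) -> tuple[np.ndarray, FenceBounds | None, TransformResult | None]:
    """Boolean flag mask for one Horn pass (all-False on degenerate input)."""
    none = np.zeros(values.size, dtype=bool)
    if values.size < 3 or np.ptp(values) == 0.0:
        return none, None, None
    tr = boxcox_transform(
        values,
        lambda_search=policy.boxcox_lambda_search,
        lambda_fixed=policy.boxcox_lambda_fixed,
    )
    fences = _tukey_fences(tr.transformed, policy.fence_k)
    # Strict comparison: values exactly on a fence are retained.
    flags = (tr.transformed < fences.lower_fence) | (
        tr.transformed > fences.upper_fence
    )
    return flags, fences, tr


def _dixon_flag_index(values: np.ndarray, policy: MethodPolicy) -> int | None:
    """Index of the single value flagged by one Dixon pass, or None."""
    n = values.size
    if n < 3:
        logger.warning("Dixon screen skipped: n=%d < 3", n)
        return None
    rng = float(np.ptp(values))
    if rng == 0.0:
        return None
    order = np.argsort(values, kind="stable")
    x = values[order]
    r_low = (x[1] - x[0]) / rng
    r_high = (x[-1] - x[-2]) / rng
    if policy.dixon_use_critical_table:
        threshold = DIXON_CRITICAL_R10.get(min(n, 30), DIXON_CRITICAL_R10[30])
    else:
        threshold = policy.dixon_ratio_threshold
    # One value at most per pass: the larger-ratio extreme (high side on a
    # tie); the iterative loop picks up the other extreme next pass.
    ratio, idx = (r_high, order[-1]) if r_high >= r_low else (r_low, order[0])
    if ratio >= threshold:
        return int(idx)
    return None


def horn_screen(
    values: np.ndarray, policy: MethodPolicy | None = None
) -> OutlierScreenResult:
    """Single Horn pass: Box-Cox + Tukey fences; may flag several values."""
    policy = policy or MethodPolicy()
    arr = np.asarray(values, dtype=float)
    flags, fences, tr = _horn_flags(arr, policy)
    return OutlierScreenResult(
        retained=arr[~flags],
        removed=[(float(v), 1, "horn") for v in arr[flags]],
        iterations=1,
        fences=fences,
        transform=tr,
    )


def dixon_screen(
    values: np.ndarray, policy: MethodPolicy | None = None
) -> OutlierScreenResult:
    """Single Dixon pass: flags at most one extreme by gap-to-range ratio."""
    policy = policy or MethodPolicy()
    arr = np.asarray(values, dtype=float)
    idx = _dixon_flag_index(arr, policy)
    keep = np.ones(arr.size, dtype=bool)
    removed: list[tuple[float, int, str]] = []
    if idx is not None:
        keep[idx] = False
        removed.append((float(arr[idx]), 1, "dixon"))
    return OutlierScreenResult(retained=arr[keep], removed=removed, iterations=1)


def iterative_screen(
    series: MeasurandSeries | np.ndarray, policy: MethodPolicy | None = None
) -> OutlierScreenResult:
    """Remove outliers until a pass flags nothing (or n drops below 3).

    The detector is re-chosen each pass on the current n: Horn when
    ``n >= horn_min_n`` (i.e. n > 30 at the default), Dixon otherwise.  The
    Box-Cox exponent is re-estimated on every Horn pass.
    """
    policy = policy or MethodPolicy()
    arr = (
        series.values if isinstance(series, MeasurandSeries) else np.asarray(series, float)
    )
    keep = np.ones(arr.size, dtype=bool)
    removed: list[tuple[float, int, str]] = []
    iterations = 0
    while True:
        idx = np.flatnonzero(keep)
        current = arr[idx]
        if current.size < 3:
            break
        iterations += 1
        if current.size >= policy.horn_min_n:
            flags, _, _ = _horn_flags(current, policy)
            method = "horn"
        else:
            flag_idx = _dixon_flag_index(current, policy)
            flags = np.zeros(current.size, dtype=bool)
            if flag_idx is not None:
                flags[flag_idx] = True
            method = "dixon"
        if not flags.any():
            break
        for v in current[flags]:
            removed.append((float(v), iterations, method))
        keep[idx[flags]] = False
    return OutlierScreenResult(retained=arr[keep], removed=removed, iterations=iterations)
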