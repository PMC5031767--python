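"""t-test computation and classification of outcomes against requirements.

Two variants are supported for the between-subjects comparison: the
classical pooled-variance Student t (default, df = n1 + n2 − 2) and the
Welch unequal-variance t.  Within-subject comparisons are paired t-tests
on the per-subject differences.  All p-values are two-sided; whether a
significant result counts as "success" additionally depends on the sign
of the observed mean difference (see :func:`meets_requirement`).

The numerics are delegated to :mod:`scipy.stats`; this module adds the
degenerate-sample guard, the observed-direction bookkeeping, and the
requirement classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import Requirement, Sign, TestSpec
from .exceptions import DegenerateSampleError

__all__ = [
    "Variant",
    "Direction",
    "TestResult",
    "two_sample_t",
    "paired_t",
    "meets_requirement",
]


class Variant(str, enum.Enum):
    POOLED = "pooled"
    WELCH = "welch"


class Direction(str, enum.Enum):
    """Sign of the observed mean difference (A − B, or m1 − m2)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    ZERO = "zero"


@dataclass(frozen=True)
class TestResult:
    __test__ = False

    test_id: str
    statistic: float
    df: float
    p_value: float
    direction: Direction
    significant: bool


def _direction(mean_diff: float) -> Direction:
    if mean_diff > 0:
        return Direction.POSITIVE
    if mean_diff < 0:
        return Direction.NEGATIVE
    return Direction.ZERO


def two_sample_t(
    xs,
    ys,
    variant: Variant = Variant.POOLED,
    alpha: float = 0.05,
    test_id: str = "",
) -> TestResult:
    """Two-sample t-test of mean(xs) − mean(ys), two-sided.

    Raises
    ------
    DegenerateSampleError
        If the pooled variance is zero (both samples constant), so no t
        statistic exists.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(xs, ddof=1) == 0.0 and np.var(ys, ddof=1) == 0.0:
        raise DegenerateSampleError("both samples are constant; t undefined")
    res = stats.ttest_ind(xs, ys, equal_var=(variant is Variant.POOLED))
    p = float(res.pvalue)
    return TestResult(
        test_id=test_id,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        direction=_direction(float(xs.mean() - ys.mean())),
        significant=p < alpha,
    )


def paired_t(diffs, alpha: float = 0.05, test_id: str = "") -> TestResult:
    """Paired (one-sample) t-test of the mean of *diffs* against zero."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.std(diffs, ddof=1) == 0.0:
        raise DegenerateSampleError("differences are constant; t undefined")
    res = stats.ttest_1samp(diffs, 0.0)
    p = float(res.pvalue)
    return TestResult(
        test_id=test_id,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        direction=_direction(float(diffs.mean())),
        significant=p < alpha,
    )


def meets_requirement(
    result: TestResult, spec: TestSpec, enforce_direction: bool = True
) -> bool:
    """Did the observed outcome satisfy the spec's requirement?

    ``SIGNIFICANT_IN_DIRECTION`` demands p < alpha *and* (when
    ``enforce_direction``) an observed sign matching ``expected_sign``;
    ``NON_SIGNIFICANT`` demands p ≥ alpha.  Ties at exactly alpha count
    as non-significant (measure zero under continuous models).
    """
    significant = result.p_value < spec.alpha
    if spec.required is Requirement.NON_SIGNIFICANT:
        return not significant
    if not significant:
        return False
    if not enforce_direction:
        return True
    if spec.expected_sign is Sign.POSITIVE:
        return result.direction is Direction.POSITIVE
    if spec.expected_sign is Sign.NEGATIVE:
        return result.direction is Direction.NEGATIVE
    return True
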