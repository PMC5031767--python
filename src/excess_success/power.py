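"""Closed-form noncentral-t outcome probabilities.

For a single two-sided t-test with true standardized effect d (between
subjects) or dz (paired differences), the probabilities of the three
possible outcomes — significant with the effect-aligned sign,
significant with the opposite sign, non-significant — are tail masses of
the noncentral t distribution with noncentrality

    δ = d · sqrt(n1·n2/(n1+n2))   (two-sample, df = n1 + n2 − 2)
    δ = dz · sqrt(n)              (paired,     df = n − 1)

These serve both as the fast path for power curves and as the
independent analytic oracle against which the Monte-Carlo engine is
checked (exact under normal populations with equal condition SDs and
the pooled-variance test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .design import Requirement, Sign, StudyDesign, TestKind, TestSpec
from .exceptions import KindMismatchError

__all__ = [
    "EffectSpec",
    "OutcomeProbabilities",
    "power_two_sample",
    "power_paired",
    "prob_outcome",
    "effect_for_test",
    "prob_outcome_for_design",
]


@dataclass(frozen=True)
class OutcomeProbabilities:
    """The three mutually exclusive outcomes of one two-sided t-test."""

    p_sig_in_direction: float
    p_sig_wrong_direction: float
    p_nonsig: float

    def __iter__(self):
        yield self.p_sig_in_direction
        yield self.p_sig_wrong_direction
        yield self.p_nonsig


@dataclass(frozen=True)
class EffectSpec:
    """A standardized true effect: d (between) or dz (paired), plus alpha.

    Exactly one of ``d``/``dz`` should be set; which one determines the
    test kind this effect can be paired with.
    """

    d: float | None = None
    dz: float | None = None
    alpha: float = 0.05


def _tail(t_crit: float, df: float, delta: float) -> float:
    # Far-tail cdf can underflow to nan in scipy's nct; the survival form
    # with negated noncentrality is the same mass and stays finite.
    mass = float(stats.nct.sf(t_crit, df, delta))
    if math.isnan(mass):
        mass = float(stats.nct.cdf(-t_crit, df, -delta))
    return 0.0 if math.isnan(mass) else mass


def _outcome_probs(delta: float, df: float, alpha: float) -> OutcomeProbabilities:
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = _tail(t_crit, df, delta)    # P(T > +t_crit)
    lower = _tail(t_crit, df, -delta)   # P(T < −t_crit), by symmetry
    if delta >= 0:
        in_dir, wrong = upper, lower
    else:
        in_dir, wrong = lower, upper
    return OutcomeProbabilities(in_dir, wrong, max(0.0, 1.0 - upper - lower))


def power_two_sample(
    d: float, n1: int, n2: int, alpha: float = 0.05
) -> OutcomeProbabilities:
    """Outcome probabilities for a pooled two-sample t-test.

    "In direction" means the sample difference has the same sign as d
    (for d = 0 the split is symmetric and either tail is reported as
    in-direction).  The three probabilities sum to 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    return _outcome_probs(delta, n1 + n2 - 2, alpha)


def power_paired(dz: float, n: int, alpha: float = 0.05) -> OutcomeProbabilities:
    """Outcome probabilities for a paired t-test on n differences."""
    if n < 2:
        raise ValueError("need n >= 2")
    return _outcome_probs(dz * math.sqrt(n), n - 1, alpha)


def _aligned(expected: Sign, effect: float) -> bool:
    # Is the required sign the one the true effect points toward?
    if effect == 0:
        return True  # symmetric: either tail has mass alpha/2
    return (effect > 0) == (expected is Sign.POSITIVE)


def prob_outcome(
    spec: TestSpec, effect: EffectSpec, sizes: Sequence[int]
) -> float:
    """Probability that one test meets its requirement, analytically.

    ``sizes`` is ``(n1, n2)`` for a between test and ``(n,)`` for a
    paired test.  For ``SIGNIFICANT_IN_DIRECTION`` the returned mass is
    the tail matching ``expected_sign`` (wrong-direction significance is
    not success); for ``NON_SIGNIFICANT`` it is the central mass.
    """
    if spec.kind is TestKind.BETWEEN_TWO_SAMPLE:
        if effect.d is None:
            raise KindMismatchError("between-subjects test needs effect.d")
        if len(sizes) != 2:
            raise ValueError("between test needs sizes (n1, n2)")
        probs = power_two_sample(effect.d, sizes[0], sizes[1], spec.alpha)
        true_effect = effect.d
    else:
        if effect.dz is None:
            raise KindMismatchError("paired test needs effect.dz")
        if len(sizes) != 1:
            raise ValueError("paired test needs sizes (n,)")
        probs = power_paired(effect.dz, sizes[0], spec.alpha)
        true_effect = effect.dz
    if spec.required is Requirement.NON_SIGNIFICANT:
        return probs.p_nonsig
    if _aligned(spec.expected_sign, true_effect):
        return probs.p_sig_in_direction
    return probs.p_sig_wrong_direction


def effect_for_test(design: StudyDesign, spec: TestSpec) -> tuple[EffectSpec, tuple[int, ...]]:
    """Standardized true effect implied by a design's population parameters.

    Between-subjects: d = (μA − μB)/σ_pooled with the per-condition SDs
    pooled using (n − 1) weights.  Paired: dz = (μ1 − μ2)/sd(diff) with
    sd(diff) = sqrt(σ1² + σ2² − 2ρσ1σ2).
    """
    if spec.kind is TestKind.BETWEEN_TWO_SAMPLE:
        ca = design.condition(spec.conditions[0])
        cb = design.condition(spec.conditions[1])
        mi = design.measure_labels.index(spec.measures[0])
        sa, sb = ca.model.sds[mi], cb.model.sds[mi]
        pooled_var = ((ca.n - 1) * sa**2 + (cb.n - 1) * sb**2) / (ca.n + cb.n - 2)
        d = (ca.model.means[mi] - cb.model.means[mi]) / math.sqrt(pooled_var)
        return EffectSpec(d=float(d), alpha=spec.alpha), (ca.n, cb.n)
    cond = design.condition(spec.conditions[0])
    i1 = design.measure_labels.index(spec.measures[0])
    i2 = design.measure_labels.index(spec.measures[1])
    s1, s2 = cond.model.sds[i1], cond.model.sds[i2]
    rho = cond.model.correlations[i1, i2]
    sd_diff = math.sqrt(s1**2 + s2**2 - 2.0 * rho * s1 * s2)
    dz = (cond.model.means[i1] - cond.model.means[i2]) / sd_diff
    return EffectSpec(dz=float(dz), alpha=spec.alpha), (cond.n,)


def prob_outcome_for_design(design: StudyDesign, spec: TestSpec) -> float:
    """Convenience wrapper: derive the effect from the design, then score it."""
    effect, sizes = effect_for_test(design, spec)
    return prob_outcome(spec, effect, sizes)
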