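"""Monte-Carlo estimation of a study's full-success probability.

Each simulated replication draws fresh samples from the multivariate
normal population model of every condition (measures are jointly normal
with the design's correlation matrix), applies every test in the success
criterion, and records whether *all* requirements were met.  The joint
success probability is the fraction of fully successful replications;
per-test marginal rates are counted on the same replications, so the
conjunction bound p_hat ≤ min(marginals) holds exactly.

Replications are processed in fixed-size chunks, each driven by its own
child stream spawned from the master seed (numpy ``SeedSequence``), so
estimates are bitwise reproducible from the seed while the heavy work —
the normal draws and the t statistics — stays vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ConditionSpec,
    Requirement,
    Sign,
    StudyDesign,
    SuccessCriterion,
    TestKind,
    TestSpec,
    validate_design,
)
from .engine import TestResult, Variant, meets_requirement, paired_t, two_sample_t
from .exceptions import DegenerateSampleError, InsufficientRepsError, InvalidDesignError

__all__ = ["SuccessEstimate", "sample_condition", "simulate_once", "estimate_success"]

#: replications per child RNG stream; fixed so a given seed always maps to
#: the same draws regardless of how much memory is available.
CHUNK = 4096


@dataclass(frozen=True)
class SuccessEstimate:
    """Monte-Carlo estimate of the joint success probability.

    ``mc_se`` is the binomial standard error sqrt(p̂(1−p̂)/reps); all
    stochastic tolerances in this package are expressed in multiples of
    it.  ``per_test_rates`` are the marginal requirement-met rates
    counted on the same replications.
    """

    p_hat: float
    reps: int
    mc_se: float
    per_test_rates: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_test_rates", dict(self.per_test_rates))


def _transform(model) -> tuple[np.ndarray, np.ndarray]:
    """(mu, A) with A·Aᵀ = Σ, via symmetric eigendecomposition (PSD-safe)."""
    cov = model.covariance()
    w, v = np.linalg.eigh(cov)
    a = v * np.sqrt(np.clip(w, 0.0, None))
    return model.means, a


def sample_condition(cond: ConditionSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one condition's data: n independent subjects × measures."""
    mu, a = _transform(cond.model)
    z = rng.standard_normal((cond.n, len(mu)))
    return pd.DataFrame(z @ a.T + mu, columns=list(cond.model.measure_labels))


def simulate_once(
    design: StudyDesign,
    criterion: SuccessCriterion,
    rng: np.random.Generator,
    variant: Variant = Variant.POOLED,
    enforce_direction: bool = True,
) -> tuple[list[TestResult], bool]:
    """One simulated replication: fresh data, every test, joint success."""
    data = {c.label: sample_condition(c, rng) for c in design.conditions}
    results: list[TestResult] = []
    success = True
    for spec in criterion.tests:
        if spec.kind is TestKind.BETWEEN_TWO_SAMPLE:
            xs = data[spec.conditions[0]][spec.measures[0]].to_numpy()
            ys = data[spec.conditions[1]][spec.measures[0]].to_numpy()
            res = two_sample_t(xs, ys, variant, spec.alpha, spec.test_id)
        else:
            frame = data[spec.conditions[0]]
            diffs = (frame[spec.measures[0]] - frame[spec.measures[1]]).to_numpy()
            res = paired_t(diffs, spec.alpha, spec.test_id)
        results.append(res)
        success = success and meets_requirement(res, spec, enforce_direction)
    return results, success


def _evaluate_chunk(
    data: Mapping[str, np.ndarray],
    measure_index: Mapping[str, int],
    criterion: SuccessCriterion,
    variant: Variant,
    enforce_direction: bool,
) -> np.ndarray:
    """Requirement-met flags for one chunk; shape (n_tests, chunk_reps)."""
    met = []
    for spec in criterion.tests:
        if spec.kind is TestKind.BETWEEN_TWO_SAMPLE:
            x = data[spec.conditions[0]][:, :, measure_index[spec.measures[0]]]
            y = data[spec.conditions[1]][:, :, measure_index[spec.measures[0]]]
            res = stats.ttest_ind(x, y, axis=1, equal_var=(variant is Variant.POOLED))
            p = np.asarray(res.pvalue)
            diff = x.mean(axis=1) - y.mean(axis=1)
        else:
            frame = data[spec.conditions[0]]
            diffs = (
                frame[:, :, measure_index[spec.measures[0]]]
                - frame[:, :, measure_index[spec.measures[1]]]
            )
            res = stats.ttest_1samp(diffs, 0.0, axis=1)
            p = np.asarray(res.pvalue)
            diff = diffs.mean(axis=1)
        if np.isnan(p).any():
            raise DegenerateSampleError(
                f"test '{spec.test_id}' hit a zero-variance sample; "
                "the design is degenerate"
            )
        significant = p < spec.alpha
        if spec.required is Requirement.NON_SIGNIFICANT:
            met.append(~significant)
        elif not enforce_direction:
            met.append(significant)
        elif spec.expected_sign is Sign.POSITIVE:
            met.append(significant & (diff > 0))
        else:
            met.append(significant & (diff < 0))
    return np.stack(met)


def estimate_success(
    design: StudyDesign,
    criterion: SuccessCriterion,
    reps: int = 100_000,
    seed: int = 0,
    *,
    variant: Variant = Variant.POOLED,
    enforce_direction: bool = True,
    validate: bool = True,
) -> SuccessEstimate:
    """Estimate P(every test meets its requirement) by simulation.

    Parameters
    ----------
    reps
        Number of simulated replications (≥ 100).
    seed
        Master seed; identical inputs give bitwise-identical estimates.
    variant
        Between-subjects test variant (pooled Student or Welch).
    enforce_direction
        If False, any significant result satisfies a significance
        requirement regardless of sign (diagnostic use only).
    """
    if reps < 100:
        raise InsufficientRepsError(
            f"reps={reps} gives a Monte-Carlo SE too large to be meaningful"
        )
    if validate:
        violations = validate_design(design, criterion)
        if violations:
            raise InvalidDesignError(violations)

    variant = Variant(variant)
    measure_index = {m: i for i, m in enumerate(design.measure_labels)}
    transforms = {c.label: (_transform(c.model), c.n) for c in design.conditions}

    n_chunks = math.ceil(reps / CHUNK)
    children = np.random.SeedSequence(seed).spawn(n_chunks)
    n_tests = len(criterion.tests)
    met_counts = np.zeros(n_tests, dtype=np.int64)
    joint_count = 0
    done = 0
    for chunk_idx in range(n_chunks):
        creps = min(CHUNK, reps - done)
        rng = np.random.default_rng(children[chunk_idx])
        data = {}
        for cond in design.conditions:
            (mu, a), n = transforms[cond.label]
            z = rng.standard_normal((creps, n, len(mu)))
            data[cond.label] = z @ a.T + mu
        met = _evaluate_chunk(data, measure_index, criterion, variant, enforce_direction)
        met_counts += met.sum(axis=1)
        joint_count += int(met.all(axis=0).sum())
        done += creps

    p_hat = joint_count / reps
    return SuccessEstimate(
        p_hat=p_hat,
        reps=reps,
        mc_se=math.sqrt(p_hat * (1.0 - p_hat) / reps),
        per_test_rates={
            spec.test_id: met_counts[i] / reps for i, spec in enumerate(criterion.tests)
        },
        seed=seed,
    )
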