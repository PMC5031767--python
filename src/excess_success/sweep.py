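"""Success-vs-sample-size curves and multi-study aggregation.

When a success criterion mixes significance and non-significance
requirements, the joint success probability typically peaks at an
intermediate per-condition sample size and then declines: larger n
drives the power of the "should be significant" tests toward 1 but also
pushes any small true effect behind a "should be non-significant" test
across the significance threshold.  :func:`success_curve` traces that
curve and :func:`find_optimum` reports its ceiling.

For a set of studies analyzed from independent samples, the probability
that *every* study fully succeeds in direct replication is the product
of the per-study success probabilities; :func:`aggregate_product`
computes it and flags sets whose joint probability is implausibly low
("too good to be true").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign, SuccessCriterion, with_sample_size
from .engine import Variant
from .montecarlo import SuccessEstimate, estimate_success

__all__ = [
    "SweepResult",
    "MultiStudyResult",
    "success_curve",
    "find_optimum",
    "aggregate_product",
]

#: default sweep grid: brackets both small-sample designs and the
#: large-n decline of mixed criteria.
DEFAULT_GRID = tuple(range(5, 201, 5))


@dataclass(frozen=True)
class SweepResult:
    """A success curve over equal per-condition sample sizes."""

    n_grid: tuple[int, ...]
    estimates: tuple[SuccessEstimate, ...]
    n_star: int
    p_max: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per grid point, marginal columns per test."""
        rows = []
        for n, est in zip(self.n_grid, self.estimates):
            row = {"n": n, "p_hat": est.p_hat, "mc_se": est.mc_se, "reps": est.reps}
            for test_id, rate in est.per_test_rates.items():
                row[f"marginal_{test_id}"] = rate
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MultiStudyResult:
    """Joint replication-success probability for a set of studies."""

    per_study: dict[str, float]
    p_tes: float
    threshold: float
    excess_flag: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_study", dict(self.per_study))


def success_curve(
    design_template: StudyDesign,
    criterion: SuccessCriterion,
    n_grid: Sequence[int] = DEFAULT_GRID,
    reps_per_point: int = 10_000,
    seed: int = 0,
    *,
    variant: Variant = Variant.POOLED,
    enforce_direction: bool = True,
) -> SweepResult:
    """Estimate joint success at each grid n (equal allocation).

    Every condition's sample size is replaced by the grid value; each
    grid point gets an independent seed derived from the master seed, so
    points are independent but the whole curve is reproducible.
    """
    n_grid = tuple(int(n) for n in n_grid)
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])) or n_grid[0] < 2:
        raise ValueError("n_grid must be strictly increasing with min >= 2")
    point_seeds = np.random.default_rng(seed).integers(2**31, size=len(n_grid))
    estimates = tuple(
        estimate_success(
            with_sample_size(design_template, n),
            criterion,
            reps=reps_per_point,
            seed=int(s),
            variant=variant,
            enforce_direction=enforce_direction,
        )
        for n, s in zip(n_grid, point_seeds)
    )
    n_star, p_max = _argmax(n_grid, estimates)
    return SweepResult(n_grid=n_grid, estimates=estimates, n_star=n_star, p_max=p_max)


def _argmax(n_grid, estimates) -> tuple[int, float]:
    p = [e.p_hat for e in estimates]
    best = int(np.argmax(p))  # first occurrence -> smallest n on ties
    return n_grid[best], p[best]


def find_optimum(sweep: SweepResult) -> tuple[int, float]:
    """(n*, p_max): the curve's ceiling; ties break toward smaller n."""
    return _argmax(sweep.n_grid, sweep.estimates)


def aggregate_product(
    per_study: Mapping[str, float], threshold: float = 0.1
) -> MultiStudyResult:
    """Product of per-study success probabilities, with the excess flag.

    A set of uniformly "successful" studies whose joint replication
    probability falls below *threshold* is flagged as showing excess
    success.  The threshold is a reporting convention, not a property of
    the data, so it is always carried alongside the product.
    """
    if not per_study:
        raise ValueError("need at least one study")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    for label, p in per_study.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"OUT_OF_RANGE: study '{label}' probability {p} not in [0, 1]")
    p_tes = math.prod(per_study.values())
    return MultiStudyResult(
        per_study=dict(per_study),
        p_tes=p_tes,
        threshold=threshold,
        excess_flag=p_tes < threshold,
    )
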