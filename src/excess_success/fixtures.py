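"""Synthetic study generators and the three-condition priming template.

Everything here produces designs that pass validation by construction,
so the rest of the toolkit is testable without any external data:

* :func:`make_random_design` draws a random homoscedastic multi-condition,
  multi-measure design plus a success criterion over it;
* :func:`study1_template` builds the structure of the subliminal-priming
  detection experiment the toolkit was written around — three priming
  conditions (white-prime n=13, no-prime n=12, black-prime n=14), two
  correlated within-subject measures (frames to detect crime-relevant
  vs crime-irrelevant objects), and a seven-test success criterion
  (five significant-in-direction, two non-significant).  The template
  deliberately ships with NO numeric population parameters: the original
  article's means/SDs/correlations are only available in its supplement,
  and fabricated defaults must not masquerade as them.  Supply a
  parameter CSV via :func:`load_parameters` or construct the
  :class:`~excess_success.design.MeasureModel` objects explicitly.

Parameter CSV schema (one row per condition × measure)::

    condition,measure,mean,sd,corr_<m1>,corr_<m2>,...

where the ``corr_*`` columns hold that measure's row of the condition's
correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    ConditionSpec,
    MeasureModel,
    Requirement,
    Sign,
    StudyDesign,
    SuccessCriterion,
    TestKind,
    TestSpec,
)
from .exceptions import ParseError
from .power import effect_for_test

__all__ = [
    "FixtureConfig",
    "make_random_design",
    "study1_template",
    "STUDY1_MEASURES",
    "STUDY1_CONDITIONS",
    "load_parameters",
    "write_parameters",
]

STUDY1_MEASURES = ("crime_relevant", "crime_irrelevant")
#: condition label -> reported sample size
STUDY1_CONDITIONS = {"white-prime": 13, "no-prime": 12, "black-prime": 14}


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the random design generator.

    ``effect_range`` bounds the standardized mean offsets of non-reference
    conditions (the first condition is the reference at offset 0), so
    reference-vs-other contrasts have |d| inside the range.
    ``corr_range`` bounds the *magnitude* of the between-measure
    correlations (signs are random); matrices are built from signed
    one-factor loadings and are therefore positive semidefinite by
    construction.  ``mix`` gives the probabilities of drawing a
    significance vs a non-significance requirement for each test.
    """

    seed: int = 0
    n_conditions: int = 3
    n_measures: int = 2
    n_tests: int = 4
    effect_range: tuple[float, float] = (0.2, 0.8)
    corr_range: tuple[float, float] = (0.1, 0.6)
    n_range: tuple[int, int] = (10, 30)
    mix: tuple[float, float] = (0.7, 0.3)

    def validate(self) -> None:
        if self.n_conditions < 1 or self.n_measures < 1 or self.n_tests < 1:
            raise ValueError("n_conditions, n_measures, n_tests must be >= 1")
        if self.n_conditions < 2 and self.n_measures < 2:
            raise ValueError("need >= 2 conditions or >= 2 measures to form any test")
        lo, hi = self.effect_range
        if lo > hi:
            raise ValueError("effect_range must be non-empty")
        clo, chi = self.corr_range
        if not (0.0 <= clo <= chi < 1.0):
            raise ValueError("corr_range (correlation magnitudes) must lie within [0, 1)")
        if self.n_range[0] < 2 or self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must be non-empty with min >= 2")
        if min(self.mix) < 0 or not math.isclose(sum(self.mix), 1.0):
            raise ValueError("mix must be two non-negative proportions summing to 1")


def _random_correlation(rng: np.random.Generator, m: int, lo: float, hi: float) -> np.ndarray:
    """PSD by construction: r_ij = s_i s_j sqrt(t_i t_j), unit diagonal."""
    t = rng.uniform(lo, hi, size=m)
    s = rng.choice([-1.0, 1.0], size=m)
    loadings = s * np.sqrt(t)
    r = np.outer(loadings, loadings)
    np.fill_diagonal(r, 1.0)
    return r


def make_random_design(cfg: FixtureConfig) -> tuple[StudyDesign, SuccessCriterion]:
    """Draw a valid (design, criterion) pair, deterministic given cfg.seed.

    Populations are homoscedastic (one SD per measure, shared across
    conditions) and the first condition sits at the reference means, so
    the standardized contrast of any other condition against it falls
    inside ``effect_range`` in magnitude.  Expected signs of
    significance requirements follow the true population direction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    measures = tuple(f"m{j + 1}" for j in range(cfg.n_measures))
    sds = rng.uniform(0.5, 2.0, size=cfg.n_measures)
    base = rng.uniform(10.0, 100.0, size=cfg.n_measures)
    corr = _random_correlation(rng, cfg.n_measures, *cfg.corr_range)

    conditions = []
    for i in range(cfg.n_conditions):
        if i == 0:
            means = base.copy()
        else:
            offset = rng.uniform(*cfg.effect_range, size=cfg.n_measures)
            signs = rng.choice([-1.0, 1.0], size=cfg.n_measures)
            means = base + signs * offset * sds
        conditions.append(
            ConditionSpec(
                label=f"cond{i + 1}",
                n=int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1)),
                model=MeasureModel(measures, means, sds, corr),
            )
        )
    design = StudyDesign("synthetic", tuple(conditions))

    tests = []
    for k in range(cfg.n_tests):
        can_within = cfg.n_measures >= 2
        can_between = cfg.n_conditions >= 2
        within = can_within and (not can_between or rng.random() < 0.4)
        required = (
            Requirement.SIGNIFICANT_IN_DIRECTION
            if rng.random() < cfg.mix[0]
            else Requirement.NON_SIGNIFICANT
        )
        if within:
            c = conditions[int(rng.integers(cfg.n_conditions))].label
            m1, m2 = rng.choice(cfg.n_measures, size=2, replace=False)
            spec = TestSpec.within(
                f"t{k + 1}", c, measures[m1], measures[m2], required
            )
        else:
            i, j = rng.choice(cfg.n_conditions, size=2, replace=False)
            m = measures[int(rng.integers(cfg.n_measures))]
            spec = TestSpec.between(
                f"t{k + 1}", conditions[i].label, conditions[j].label, m, required
            )
        if required is Requirement.SIGNIFICANT_IN_DIRECTION:
            effect, _ = effect_for_test(design, spec)
            true = effect.d if spec.kind is TestKind.BETWEEN_TWO_SAMPLE else effect.dz
            sign = Sign.NEGATIVE if true < 0 else Sign.POSITIVE
            spec = TestSpec(
                spec.test_id, spec.kind, spec.conditions, spec.measures,
                required, sign, spec.alpha,
            )
        tests.append(spec)
    return design, SuccessCriterion(tuple(tests))


def study1_template(
    params: Mapping[str, MeasureModel], alpha: float = 0.05
) -> tuple[StudyDesign, SuccessCriterion]:
    """The 3-condition × 2-measure priming design with its 7-test criterion.

    *params* maps each condition label in :data:`STUDY1_CONDITIONS` to a
    :class:`MeasureModel` over :data:`STUDY1_MEASURES` (fewer frames =
    faster detection).  The expected directions encode the original
    claims: black priming speeds detection of crime-relevant objects
    (negative shifts), white priming slows it (positive shifts), and
    priming has no effect on crime-irrelevant objects.
    """
    missing = set(STUDY1_CONDITIONS) - set(params)
    if missing:
        raise ValueError(f"missing parameters for conditions: {sorted(missing)}")
    for label, model in params.items():
        if tuple(model.measure_labels) != STUDY1_MEASURES:
            raise ValueError(
                f"condition '{label}' must model measures {STUDY1_MEASURES}, "
                f"got {model.measure_labels}"
            )
    design = StudyDesign(
        "study1",
        tuple(
            ConditionSpec(label, n, params[label])
            for label, n in STUDY1_CONDITIONS.items()
        ),
    )
    rel, irrel = STUDY1_MEASURES
    sig = Requirement.SIGNIFICANT_IN_DIRECTION
    nonsig = Requirement.NON_SIGNIFICANT
    criterion = SuccessCriterion(
        (
            # claim: priming tunes detection of crime-relevant objects
            TestSpec.between("rel_white_vs_black", "white-prime", "black-prime", rel, sig, Sign.POSITIVE, alpha),
            TestSpec.between("rel_black_vs_none", "black-prime", "no-prime", rel, sig, Sign.NEGATIVE, alpha),
            TestSpec.within("black_rel_vs_irrel", "black-prime", rel, irrel, sig, Sign.NEGATIVE, alpha),
            TestSpec.between("rel_white_vs_none", "white-prime", "no-prime", rel, sig, Sign.POSITIVE, alpha),
            TestSpec.within("white_rel_vs_irrel", "white-prime", rel, irrel, sig, Sign.POSITIVE, alpha),
            # claim: the tuning is specific to crime-relevant objects
            TestSpec.between("irrel_black_vs_none", "black-prime", "no-prime", irrel, nonsig, Sign.NONE, alpha),
            TestSpec.between("irrel_white_vs_none", "white-prime", "no-prime", irrel, nonsig, Sign.NONE, alpha),
        )
    )
    return design, criterion


def load_parameters(path) -> dict[str, MeasureModel]:
    """Read condition population parameters from the CSV schema above."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    required_cols = {"condition", "measure", "mean", "sd"}
    missing = required_cols - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    models: dict[str, MeasureModel] = {}
    for condition, block in table.groupby("condition", sort=False):
        measures = tuple(block["measure"].tolist())
        corr_cols = [f"corr_{m}" for m in measures]
        absent = [c for c in corr_cols if c not in table.columns]
        if absent:
            raise ParseError(f"{path}: condition '{condition}' missing {absent}")
        if block[["mean", "sd"]].isna().any().any() or block[corr_cols].isna().any().any():
            raise ParseError(f"{path}: condition '{condition}' has missing values")
        models[str(condition)] = MeasureModel(
            measure_labels=measures,
            means=block["mean"].to_numpy(),
            sds=block["sd"].to_numpy(),
            correlations=block[corr_cols].to_numpy(),
        )
    if not models:
        raise ParseError(f"{path}: no parameter rows found")
    return models


def write_parameters(models: Mapping[str, MeasureModel], path) -> None:
    """Inverse of :func:`load_parameters` (round-trips exactly)."""
    rows = []
    for condition, model in models.items():
        for i, measure in enumerate(model.measure_labels):
            row = {
                "condition": condition,
                "measure": measure,
                "mean": model.means[i],
                "sd": model.sds[i],
            }
            for j, other in enumerate(model.measure_labels):
                row[f"corr_{other}"] = model.correlations[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
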