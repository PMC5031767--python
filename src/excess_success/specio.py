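"""Declarative YAML study specs and CSV/JSON result serialization.

The spec format is a strictly validated, versioned YAML document: human
authored, diff-able, and citable in meta-research reports.  Unknown
fields are errors (strict mode), every structural violation is reported
with its location, and numbers round-trip at full precision.

Schema (``spec_version: 1``)::

    spec_version: 1
    label: my-paper
    tes_threshold: 0.1          # optional, default 0.1
    studies:
      - study_label: study1
        measures: [m1, m2]
        conditions:
          - label: c1
            n: 13
            means: [1.0, 2.0]
            sds: [1.0, 1.0]
            correlations: [[1.0, 0.3], [0.3, 1.0]]
        tests:
          - id: t1
            kind: between            # between | within
            conditions: [c1, c2]     # within: a single condition
            measures: [m1]           # within: the two paired measures
            required: significant    # significant | non_significant
            expected_sign: positive  # positive | negative | none
            alpha: 0.05              # optional, default 0.05
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    ConditionSpec,
    MeasureModel,
    StudyDesign,
    SuccessCriterion,
    TestKind,
    TestSpec,
    validate_design,
)
from .exceptions import InvalidDesignError, ParseError, SchemaVersionError
from .montecarlo import SuccessEstimate
from .sweep import MultiStudyResult

__all__ = ["PaperSpec", "read_spec", "write_spec", "write_report", "read_report"]

SPEC_VERSION = 1

REPORT_COLUMNS = [
    "record", "study", "test_id", "requirement", "marginal_rate",
    "p_hat", "mc_se", "reps", "seed", "p_tes", "threshold", "excess_flag",
]


@dataclass(frozen=True)
class PaperSpec:
    """A set of studies analyzed together, with the excess-success threshold."""

    label: str
    studies: tuple[tuple[StudyDesign, SuccessCriterion], ...]
    tes_threshold: float = 0.1


def _require_keys(mapping: dict, allowed: set[str], required: set[str], where: str) -> None:
    if not isinstance(mapping, dict):
        raise ParseError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ParseError(f"{where}: unknown field(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ParseError(f"{where}: missing required field(s) {sorted(missing)}")


def _parse_condition(doc: dict, measures: Sequence[str], where: str) -> ConditionSpec:
    _require_keys(
        doc,
        {"label", "n", "means", "sds", "correlations"},
        {"label", "n", "means", "sds", "correlations"},
        where,
    )
    model = MeasureModel(
        measure_labels=tuple(measures),
        means=doc["means"],
        sds=doc["sds"],
        correlations=doc["correlations"],
    )
    return ConditionSpec(label=str(doc["label"]), n=int(doc["n"]), model=model)


def _parse_test(doc: dict, where: str) -> TestSpec:
    _require_keys(
        doc,
        {"id", "kind", "conditions", "measures", "required", "expected_sign", "alpha"},
        {"id", "kind", "conditions", "measures", "required"},
        where,
    )
    kind = {"between": TestKind.BETWEEN_TWO_SAMPLE, "within": TestKind.WITHIN_PAIRED}.get(
        doc["kind"]
    )
    if kind is None:
        raise ParseError(f"{where}: kind must be 'between' or 'within', got {doc['kind']!r}")
    try:
        return TestSpec(
            test_id=str(doc["id"]),
            kind=kind,
            conditions=tuple(doc["conditions"]),
            measures=tuple(doc["measures"]),
            required=doc["required"],
            expected_sign=doc.get("expected_sign", "none"),
            alpha=float(doc.get("alpha", 0.05)),
        )
    except ValueError as exc:
        raise ParseError(f"{where}: {exc}") from exc


def _parse_study(doc: dict, where: str) -> tuple[StudyDesign, SuccessCriterion]:
    _require_keys(
        doc,
        {"study_label", "measures", "conditions", "tests"},
        {"study_label", "measures", "conditions", "tests"},
        where,
    )
    measures = list(doc["measures"])
    conditions = tuple(
        _parse_condition(c, measures, f"{where}.conditions[{i}]")
        for i, c in enumerate(doc["conditions"])
    )
    design = StudyDesign(study_label=str(doc["study_label"]), conditions=conditions)
    tests = tuple(
        _parse_test(t, f"{where}.tests[{i}]") for i, t in enumerate(doc["tests"])
    )
    return design, SuccessCriterion(tests)


def read_spec(path) -> PaperSpec:
    """Parse and fully validate a YAML study spec.

    Raises :class:`ParseError` (unknown/missing fields, bad enums),
    :class:`SchemaVersionError` (wrong ``spec_version``), or
    :class:`InvalidDesignError` carrying every design violation.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _require_keys(
        doc,
        {"spec_version", "label", "tes_threshold", "studies"},
        {"spec_version", "label", "studies"},
        str(path),
    )
    if doc["spec_version"] != SPEC_VERSION:
        raise SchemaVersionError(
            f"{path}: spec_version {doc['spec_version']!r} unsupported "
            f"(this reader handles {SPEC_VERSION})"
        )
    threshold = float(doc.get("tes_threshold", 0.1))
    if not 0.0 < threshold < 1.0:
        raise ParseError(f"{path}: tes_threshold must be in (0, 1)")
    studies = tuple(
        _parse_study(s, f"{path}.studies[{i}]") for i, s in enumerate(doc["studies"])
    )
    labels = [d.study_label for d, _ in studies]
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: study labels not unique: {labels}")
    violations = []
    for design, criterion in studies:
        violations.extend(validate_design(design, criterion))
    if violations:
        raise InvalidDesignError(violations)
    return PaperSpec(label=str(doc["label"]), studies=studies, tes_threshold=threshold)


def _test_to_doc(t: TestSpec) -> dict:
    return {
        "id": t.test_id,
        "kind": "between" if t.kind is TestKind.BETWEEN_TWO_SAMPLE else "within",
        "conditions": list(t.conditions),
        "measures": list(t.measures),
        "required": t.required.value,
        "expected_sign": t.expected_sign.value,
        "alpha": t.alpha,
    }


def write_spec(spec: PaperSpec, path) -> None:
    """Serialize a PaperSpec; ``read_spec(write_spec(s)) == s`` field-for-field."""
    studies = []
    for design, criterion in spec.studies:
        studies.append(
            {
                "study_label": design.study_label,
                "measures": list(design.measure_labels),
                "conditions": [
                    {
                        "label": c.label,
                        "n": int(c.n),
                        "means": c.model.means.tolist(),
                        "sds": c.model.sds.tolist(),
                        "correlations": c.model.correlations.tolist(),
                    }
                    for c in design.conditions
                ],
                "tests": [_test_to_doc(t) for t in criterion.tests],
            }
        )
    doc = {
        "spec_version": SPEC_VERSION,
        "label": spec.label,
        "tes_threshold": spec.tes_threshold,
        "studies": studies,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_report(
    study_reports: Sequence[tuple[str, SuccessCriterion, SuccessEstimate]],
    path,
    fmt: str = "json",
    aggregate: MultiStudyResult | None = None,
) -> None:
    """Serialize estimation results.

    CSV is a long table (:data:`REPORT_COLUMNS`): one ``marginal`` row per
    test, one ``study`` row per estimate, one ``aggregate`` row when a
    multi-study product is supplied.  JSON mirrors the full data model at
    full float precision (round-trips via :func:`read_report`).
    """
    path = Path(path)
    if fmt == "json":
        doc = {
            "studies": [
                {
                    "study": label,
                    "p_hat": est.p_hat,
                    "mc_se": est.mc_se,
                    "reps": est.reps,
                    "seed": est.seed,
                    "marginals": [
                        {
                            "test_id": t.test_id,
                            "requirement": t.required.value,
                            "rate": est.per_test_rates[t.test_id],
                        }
                        for t in criterion.tests
                    ],
                }
                for label, criterion, est in study_reports
            ],
            "aggregate": None
            if aggregate is None
            else {
                "per_study": aggregate.per_study,
                "p_tes": aggregate.p_tes,
                "threshold": aggregate.threshold,
                "excess_flag": aggregate.excess_flag,
            },
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    if fmt != "csv":
        raise ValueError(f"unknown report format {fmt!r}")
    rows = []
    for label, criterion, est in study_reports:
        for t in criterion.tests:
            rows.append(
                {
                    "record": "marginal",
                    "study": label,
                    "test_id": t.test_id,
                    "requirement": t.required.value,
                    "marginal_rate": est.per_test_rates[t.test_id],
                }
            )
        rows.append(
            {
                "record": "study",
                "study": label,
                "p_hat": est.p_hat,
                "mc_se": est.mc_se,
                "reps": est.reps,
                "seed": est.seed,
            }
        )
    if aggregate is not None:
        rows.append(
            {
                "record": "aggregate",
                "p_tes": aggregate.p_tes,
                "threshold": aggregate.threshold,
                "excess_flag": aggregate.excess_flag,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_report(path) -> dict:
    """Load a JSON report back into plain dicts (exact float round-trip)."""
    return json.loads(Path(path).read_text())
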