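"""Three-dimension quality assessment with weighted scoring.

Quality is rated along three standard dimensions:

* **Completeness** — required cells are present (minimal and mandatory
  requirement checks; minimal variables are a fortiori mandatory).
* **Conformance** — cells adhere to length limits, datatype
  restrictions and the permissible-value lists of the dictionary.
* **Plausibility** — numeric values fall inside their declared ranges.

Each executed check yields one pass/fail finding. Per rule type, the
score is ``weight x pass / total`` on the 0-100 scale, and the report
total is the sum of the unrounded per-type scores, rounded half-up to
two decimals for display only. A rule type with no executed checks
contributes its full weight (an absent defect class never penalizes).

Datatype rules attach to parse-constrained datatypes (integer, decimal,
interval, boolean). For coded variables the permissible-value check
subsumes type conformance, and any text conforms to ``string``, so
neither carries a separate datatype check. Missing cells trigger only
completeness rules — missingness is attributed once, never double-counted
into conformance or plausibility.
"""

from __future__ import annotations

import csv
import decimal
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .dictionary_model import SchemaDefinition, VariableDefinition
from .errors import ConfigurationError
from .redcap_io import PatientRecord

RULE_TYPES = ("minimal_req", "mandatory_req", "length", "datatype", "permissible", "range")

RULE_DIMENSION = {
    "minimal_req": "Completeness",
    "mandatory_req": "Completeness",
    "length": "Conformance",
    "datatype": "Conformance",
    "permissible": "Conformance",
    "range": "Plausibility",
}

#: Reference weight configuration: half the weight on the minimal
#: requirements, the rest split evenly. Overridable; must sum to 100.
DEFAULT_WEIGHTS = {
    "minimal_req": 50,
    "mandatory_req": 10,
    "length": 10,
    "datatype": 10,
    "permissible": 10,
    "range": 10,
}

_TYPED_DATATYPES = {"integer", "decimal", "interval", "boolean"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (display policy; 44.444 -> 44.44, 7.5 -> 7.50)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class QCRule:
    rule_type: str
    variable: str
    parameters: object = None

    @property
    def dimension(self) -> str:
        return RULE_DIMENSION[self.rule_type]


@dataclass(frozen=True)
class QCFinding:
    patient_id: str
    variable: str
    rule_type: str
    outcome: str  # "pass" | "fail"
    detail: str = ""


@dataclass
class DimensionTally:
    dimension: str
    rule_type: str
    fail: int
    pass_: int
    weight: float

    @property
    def total(self) -> int:
        return self.fail + self.pass_

    @property
    def score(self) -> float:
        return score_dimension(self.fail, self.pass_, self.weight)


@dataclass
class QualityReport:
    tallies: list[DimensionTally]
    findings: list[QCFinding] = field(default_factory=list)
    record_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def total_fail(self) -> int:
        return sum(t.fail for t in self.tallies)

    @property
    def total_pass(self) -> int:
        return sum(t.pass_ for t in self.tallies)

    @property
    def total_checks(self) -> int:
        return sum(t.total for t in self.tallies)

    @property
    def total_score(self) -> float:
        """Unrounded aggregate; round with ``round_half_up`` for display."""
        return sum(t.score for t in self.tallies)

    def to_dict(self) -> dict:
        return {
            "tallies": [
                {
                    "dimension": t.dimension,
                    "rule_type": t.rule_type,
                    "fail": t.fail,
                    "pass": t.pass_,
                    "total": t.total,
                    "weight": t.weight,
                    "score": round_half_up(t.score),
                }
                for t in self.tallies
            ],
            "total": {
                "fail": self.total_fail,
                "pass": self.total_pass,
                "checks": self.total_checks,
                "score": round_half_up(self.total_score),
            },
            "findings": [
                {
                    "patient_id": f.patient_id,
                    "variable": f.variable,
                    "rule_type": f.rule_type,
                    "outcome": f.outcome,
                    "detail": f.detail,
                }
                for f in self.findings
            ],
            "record_scores": self.record_scores,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "QualityReport":
        tallies = [
            DimensionTally(
                dimension=t["dimension"],
                rule_type=t["rule_type"],
                fail=t["fail"],
                pass_=t["pass"],
                weight=t["weight"],
            )
            for t in doc["tallies"]
        ]
        findings = [
            QCFinding(
                patient_id=f["patient_id"],
                variable=f["variable"],
                rule_type=f["rule_type"],
                outcome=f["outcome"],
                detail=f.get("detail", ""),
            )
            for f in doc.get("findings", [])
        ]
        return cls(tallies=tallies, findings=findings, record_scores=doc.get("record_scores", {}))


def compile_rules(schema: SchemaDefinition) -> list[QCRule]:
    """Derive the QC rule set from the dictionary.

    Per non-identifier variable: a minimal requirement check iff the
    level is minimal; a mandatory requirement check iff the level is
    minimal or mandatory; a length check iff ``max_length`` is set; a
    datatype check iff the datatype is parse-constrained; a
    permissible-value check iff the variable is coded; a range check iff
    a range is declared. The patient identifier is enforced at parse
    time and carries no QC rules.
    """
    rules: list[QCRule] = []
    for v in schema.data_variables:
        if v.requirement_level == "minimal":
            rules.append(QCRule("minimal_req", v.name))
        if v.requirement_level in ("minimal", "mandatory"):
            rules.append(QCRule("mandatory_req", v.name))
        if v.max_length is not None:
            rules.append(QCRule("length", v.name, v.max_length))
        if v.datatype in _TYPED_DATATYPES:
            rules.append(QCRule("datatype", v.name, v.datatype))
        if v.datatype == "code":
            rules.append(QCRule("permissible", v.name, tuple(e.internal_code for e in v.value_set)))
        if v.range is not None:
            rules.append(QCRule("range", v.name, v.range))
    return rules


def _evaluate(rule: QCRule, record: PatientRecord) -> Optional[QCFinding]:
    """Evaluate one rule on one record; None when the check is skipped."""
    cell = record.cell(rule.variable)
    if rule.rule_type in ("minimal_req", "mandatory_req"):
        if cell.is_missing:
            return QCFinding(record.patient_id, rule.variable, rule.rule_type, "fail",
                             "required value missing")
        return QCFinding(record.patient_id, rule.variable, rule.rule_type, "pass")
    # conformance / plausibility never executes on missing cells
    if cell.is_missing:
        return None
    if rule.rule_type == "length":
        if len(cell.raw) > rule.parameters:
            return QCFinding(record.patient_id, rule.variable, "length", "fail",
                             f"length {len(cell.raw)} exceeds {rule.parameters}")
        return QCFinding(record.patient_id, rule.variable, "length", "pass")
    if rule.rule_type == "datatype":
        if cell.parsed is None:
            return QCFinding(record.patient_id, rule.variable, "datatype", "fail",
                             f"value {cell.raw!r} does not parse as {rule.parameters}")
        return QCFinding(record.patient_id, rule.variable, "datatype", "pass")
    if rule.rule_type == "permissible":
        if cell.raw not in rule.parameters:
            return QCFinding(record.patient_id, rule.variable, "permissible", "fail",
                             f"code {cell.raw!r} not in permissible values")
        return QCFinding(record.patient_id, rule.variable, "permissible", "pass")
    if rule.rule_type == "range":
        if cell.parsed is None:
            return None  # unparseable numerics are the datatype rule's finding
        lo, hi = rule.parameters
        if not (lo <= cell.parsed <= hi):
            return QCFinding(record.patient_id, rule.variable, "range", "fail",
                             f"value {cell.parsed} outside [{lo}, {hi}]")
        return QCFinding(record.patient_id, rule.variable, "range", "pass")
    raise ValueError(f"unknown rule type {rule.rule_type!r}")


def check_weights(weights: dict[str, float], rules: list[QCRule]) -> None:
    for rt in {r.rule_type for r in rules}:
        if rt not in weights:
            raise ConfigurationError(f"no weight configured for rule type {rt!r}")
    total = sum(weights.values())
    if abs(total - 100) > 1e-9:
        raise ConfigurationError(f"weights must sum to 100, got {total}")


def run_qc(
    records: list[PatientRecord],
    rules: list[QCRule],
    weights: dict[str, float] | None = None,
) -> QualityReport:
    """Execute every applicable (record, rule) check and tally the report."""
    if not records:
        raise ValueError("run_qc requires at least one record")
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    check_weights(weights, rules)
    findings: list[QCFinding] = []
    for record in records:
        for rule in rules:
            finding = _evaluate(rule, record)
            if finding is not None:
                findings.append(finding)
    order = [rt for rt in RULE_TYPES if rt in weights]
    tallies = [
        DimensionTally(
            dimension=RULE_DIMENSION[rt],
            rule_type=rt,
            fail=sum(1 for f in findings if f.rule_type == rt and f.outcome == "fail"),
            pass_=sum(1 for f in findings if f.rule_type == rt and f.outcome == "pass"),
            weight=weights[rt],
        )
        for rt in order
    ]
    # per-patient pass fraction per dimension, weighted by the summed
    # weight of the dimension's rule types
    dim_weight: dict[str, float] = {}
    for rt, w in weights.items():
        dim_weight[RULE_DIMENSION[rt]] = dim_weight.get(RULE_DIMENSION[rt], 0) + w
    record_scores: dict[str, dict[str, float]] = {}
    for record in records:
        mine = [f for f in findings if f.patient_id == record.patient_id]
        per_dim: dict[str, float] = {}
        for dim, w in dim_weight.items():
            fails = sum(1 for f in mine if f.outcome == "fail" and RULE_DIMENSION[f.rule_type] == dim)
            passes = sum(1 for f in mine if f.outcome == "pass" and RULE_DIMENSION[f.rule_type] == dim)
            per_dim[dim] = round_half_up(score_dimension(fails, passes, w))
        record_scores[record.patient_id] = per_dim
    return QualityReport(tallies=tallies, findings=findings, record_scores=record_scores)


def score_dimension(fail: int, pass_: int, weight: float) -> float:
    """``weight x pass / (fail + pass)`` on the 0-100 scale, unrounded.

    Zero executed checks score the full weight (vacuously satisfied).
    """
    if fail < 0 or pass_ < 0 or weight < 0:
        raise ValueError("fail, pass and weight must be non-negative")
    total = fail + pass_
    if total == 0:
        return float(weight)
    return weight * pass_ / total


def aggregate_report(tallies: list[DimensionTally]) -> QualityReport:
    """Build a report from tallies alone (the totals-row arithmetic)."""
    weight_sum = sum(t.weight for t in tallies)
    if abs(weight_sum - 100) > 1e-9:
        raise ConfigurationError(f"tally weights must sum to 100, got {weight_sum}")
    return QualityReport(tallies=list(tallies))


def render_report(report: QualityReport) -> str:
    """Plain-text scorecard: Dimension, Type, Fail, Pass, Total, Weight, Score."""
    rows = [("Dimension", "Type", "Fail", "Pass", "Total", "Weight", "Score")]
    for t in report.tallies:
        rows.append(
            (
                t.dimension,
                t.rule_type,
                str(t.fail),
                str(t.pass_),
                str(t.total),
                f"{t.weight:g}",
                f"{round_half_up(t.score):.2f}%",
            )
        )
    rows.append(
        (
            "Total:",
            "",
            str(report.total_fail),
            str(report.total_pass),
            str(report.total_checks),
            f"{sum(t.weight for t in report.tallies):g}",
            f"{round_half_up(report.total_score):.2f}%",
        )
    )
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    lines = []
    for r in rows:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines)


def write_report_json(report: QualityReport, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
    return path


def findings_csv(report: QualityReport) -> str:
    """Findings as CSV text (patient_id, variable, rule_type, outcome, detail)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["patient_id", "variable", "rule_type", "outcome", "detail"])
    for f in report.findings:
        writer.writerow([f.patient_id, f.variable, f.rule_type, f.outcome, f.detail])
    return buf.getvalue()
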