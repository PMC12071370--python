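"""Schema-conformant synthetic cohorts with bookkept defect injection.

Real study data cannot be shipped, so every pipeline stage is exercised
on generated cohorts: rows drawn cell-by-cell from the dictionary
(coded cells uniformly from value sets, numerics within declared
ranges, intervals within plausible clinical bounds), deterministic
under a seed. Correlation structure between variables is deliberately
not modelled.

``inject_errors`` then plants an exact number of rule violations per
quality-check type at mutually non-overlapping cells, logging every
site, so the QC engine and the generator act as mutual oracles: the
engine must recover exactly the injected defect counts.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .dictionary_model import (
    OntologyCoding,
    SchemaDefinition,
    ValueSetEntry,
    VariableDefinition,
)
from .errors import InjectionError
from .pseudonymization import hash_patient_id
from .redcap_io import CellValue, PatientRecord, make_cell
from .terminology import SNOMED_CT

DEMO_SITE_SALT = "site-demo-salt"
DEMO_PLATFORM_SALT = "platform-demo-salt"

_WORDS = (
    "stable", "irregular", "spiculated", "well-defined", "suspicious",
    "benign-appearing", "calcified", "multifocal", "unilateral", "bilateral",
)

# injection processing order (matches the scorecard row order)
_INJECT_ORDER = ("minimal_req", "mandatory_req", "length", "datatype", "permissible", "range")


@dataclass
class InjectionLog:
    """Bookkeeping of every planted defect site, per rule type."""

    sites: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {rt: len(s) for rt, s in self.sites.items()}

    @property
    def expected_fails(self) -> dict[str, int]:
        """Fail counts the QC engine must report.

        A blanked minimal cell fails both the minimal and the mandatory
        requirement check (minimal variables are a fortiori mandatory),
        so the mandatory count carries that cascade.
        """
        out = dict(self.counts)
        if out.get("minimal_req"):
            out["mandatory_req"] = out.get("mandatory_req", 0) + out["minimal_req"]
        return out

    def all_sites(self) -> set[tuple[str, str]]:
        return {site for sites in self.sites.values() for site in sites}

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "expected_fails": self.expected_fails,
            "sites": {rt: [list(s) for s in sites] for rt, sites in self.sites.items()},
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
        return path


def _compliant_raw(vdef: VariableDefinition, rng: random.Random) -> str:
    if vdef.datatype == "code":
        return rng.choice(vdef.value_set).internal_code
    if vdef.datatype == "integer":
        lo, hi = vdef.range if vdef.range else (0, 120)
        return str(rng.randint(int(lo), int(hi)))
    if vdef.datatype == "decimal":
        lo, hi = vdef.range if vdef.range else (0.0, 100.0)
        return f"{rng.uniform(lo, hi):.1f}"
    if vdef.datatype == "interval":
        unit = rng.choice(("days", "weeks", "months"))
        upper = {"days": 365, "weeks": 52, "months": 36}[unit]
        return f"{rng.randint(0, upper)} {unit}"
    if vdef.datatype == "boolean":
        return rng.choice(("0", "1"))
    # string
    word = rng.choice(_WORDS)
    if vdef.max_length is not None:
        word = word[: vdef.max_length]
    return word


def generate_cohort(schema: SchemaDefinition, n: int, seed: int) -> list[PatientRecord]:
    """Generate *n* fully compliant records, deterministic under *seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    records = []
    for i in range(n):
        pid = hash_patient_id(f"PAT{i:05d}", DEMO_SITE_SALT, DEMO_PLATFORM_SALT)
        cells = {
            v.name: make_cell(_compliant_raw(v, rng), v) for v in schema.data_variables
        }
        records.append(PatientRecord(patient_id=pid, schema_id=schema.schema_id, cells=cells))
    return records


def _eligible(rule_type: str, schema: SchemaDefinition) -> list[VariableDefinition]:
    vs = schema.data_variables
    if rule_type == "minimal_req":
        return [v for v in vs if v.requirement_level == "minimal"]
    if rule_type == "mandatory_req":
        return [v for v in vs if v.requirement_level == "mandatory"]
    if rule_type == "length":
        return [v for v in vs if v.max_length is not None and v.datatype == "string"]
    if rule_type == "datatype":
        return [v for v in vs if v.datatype in ("integer", "decimal", "interval", "boolean")]
    if rule_type == "permissible":
        return [v for v in vs if v.datatype == "code"]
    if rule_type == "range":
        return [v for v in vs if v.range is not None]
    raise ValueError(f"unknown rule type {rule_type!r}")


def _defect_raw(rule_type: str, vdef: VariableDefinition) -> str:
    if rule_type in ("minimal_req", "mandatory_req"):
        return ""
    if rule_type == "length":
        return "X" * (vdef.max_length + 5)
    if rule_type == "datatype":
        return "not_a_number"
    if rule_type == "permissible":
        return "__INVALID__"
    # range: out by at least one unit
    hi = vdef.range[1]
    return str(int(hi) + 1) if vdef.datatype == "integer" else f"{hi + 1.5:.1f}"


def inject_errors(
    records: list[PatientRecord],
    spec: dict[str, int],
    schema: SchemaDefinition,
    seed: int,
) -> tuple[list[PatientRecord], InjectionLog]:
    """Plant exactly the requested defects at non-overlapping cells.

    ``spec`` maps rule type to an injection-site count. Requirement
    injections blank the cell; conformance/plausibility injections
    overwrite it with a value violating exactly that rule. Raises
    ``InjectionError`` when a request exceeds the eligible capacity.
    """
    rng = random.Random(seed)
    records = copy.deepcopy(records)
    by_id = {r.patient_id: r for r in records}
    used: set[tuple[str, str]] = set()
    log = InjectionLog()
    for rule_type in _INJECT_ORDER:
        want = spec.get(rule_type, 0)
        if want == 0:
            log.sites.setdefault(rule_type, [])
            continue
        pool = [
            (r.patient_id, v.name)
            for r in records
            for v in _eligible(rule_type, schema)
            if (r.patient_id, v.name) not in used
        ]
        if want > len(pool):
            raise InjectionError(
                f"{rule_type}: requested {want} defects but only {len(pool)} eligible cells"
            )
        chosen = rng.sample(pool, want)
        for pid, name in chosen:
            vdef = schema.variable(name)
            raw = _defect_raw(rule_type, vdef)
            by_id[pid].cells[name] = (
                CellValue(raw="") if raw == "" else make_cell(raw, vdef)
            )
            used.add((pid, name))
        log.sites[rule_type] = sorted(chosen)
    return records, log


def _vset(prefix: str, k: int = 3) -> list[ValueSetEntry]:
    return [
        ValueSetEntry(
            internal_code=str(j + 1),
            label=f"{prefix} level {j + 1}",
            coding=OntologyCoding(system=SNOMED_CT, code=f"{prefix}{j + 1:03d}", display=""),
        )
        for j in range(k)
    ]


def scoring_report_demo_schema() -> SchemaDefinition:
    """Single-record schema sized for the reference scorecard worked example.

    The reference scoring report tallies 18 minimal and 35 mandatory
    requirement checks; since both are per-record-constant sums, their
    coprime totals force a one-record cohort, and the schema must carry
    the full check budget itself: 18 minimal + 17 mandatory + 23
    recommended coded variables (58 permissible checks, 3 of which get
    blanked), 40 parse-typed variables (4 with ranges) and 11
    length-limited strings.
    """
    variables: list[VariableDefinition] = [
        VariableDefinition(
            name="patient_id",
            identifier=True,
            requirement_level="minimal",
            datatype="string",
            resource_kind="Patient",
            element_path="Patient.identifier",
        )
    ]

    def coded(name: str, level: str, serial: int) -> VariableDefinition:
        return VariableDefinition(
            name=name,
            requirement_level=level,
            datatype="code",
            resource_kind="Observation",
            resource_group=name,
            element_path="Observation.valueCodeableConcept",
            value_set=_vset(str(100000 + serial)),
        )

    serial = 0
    for i in range(18):
        variables.append(coded(f"min_code_{i:02d}", "minimal", serial))
        serial += 1
    for i in range(17):
        variables.append(coded(f"man_code_{i:02d}", "mandatory", serial))
        serial += 1
    for i in range(23):
        variables.append(coded(f"rec_code_{i:02d}", "recommended", serial))
        serial += 1
    for i in range(40):
        variables.append(
            VariableDefinition(
                name=f"num_{i:02d}",
                requirement_level="recommended",
                datatype="integer",
                resource_kind="Observation",
                resource_group=f"num_{i:02d}",
                element_path="Observation.valueInteger",
                range=(0, 100) if i < 4 else None,
            )
        )
    for i in range(11):
        variables.append(
            VariableDefinition(
                name=f"text_{i:02d}",
                requirement_level="recommended",
                datatype="string",
                resource_kind="DiagnosticReport",
                resource_group=f"text_{i:02d}",
                element_path="DiagnosticReport.conclusion",
                max_length=20,
            )
        )
    return SchemaDefinition(schema_id="scoring_report_demo", variables=variables)


#: Injection-site counts reproducing the reference scorecard: two blanked
#: minimal cells (cascading into the mandatory count), one further
#: blanked mandatory cell, one overlong string, three out-of-set codes
#: and one out-of-range number.
SCORING_REPORT_INJECTION = {
    "minimal_req": 2,
    "mandatory_req": 1,
    "length": 1,
    "datatype": 0,
    "permissible": 3,
    "range": 1,
}


def scoring_report_demo_cohort(seed: int) -> tuple[SchemaDefinition, list[PatientRecord], InjectionLog]:
    """Generate the one-record cohort whose scorecard is the worked example."""
    schema = scoring_report_demo_schema()
    records = generate_cohort(schema, n=1, seed=seed)
    records, log = inject_errors(records, SCORING_REPORT_INJECTION, schema, seed=seed + 1)
    return schema, records, log
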