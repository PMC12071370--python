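"""Independent brute-force QC oracle.

Re-evaluates every cell directly from the variable definitions with its
own parsing logic, sharing nothing with the rule engine, so the two can
be compared check-for-check on small cohorts.
"""

from __future__ import annotations

from oncoharmonizer.dictionary_model import SchemaDefinition
from oncoharmonizer.redcap_io import PatientRecord

_PARSE_TYPES = ("integer", "decimal", "interval", "boolean")


def _conforms(raw: str, datatype: str) -> bool:
    if datatype == "integer":
        try:
            int(raw)
            return True
        except ValueError:
            return False
    if datatype == "decimal":
        # reject nan/inf spellings the strict parser refuses
        if any(ch.isalpha() for ch in raw):
            return False
        try:
            float(raw)
            return True
        except ValueError:
            return False
    if datatype == "interval":
        parts = raw.split()
        return (
            len(parts) == 2
            and parts[0].isdigit()
            and parts[1] in ("days", "weeks", "months")
        )
    if datatype == "boolean":
        return raw.lower() in ("0", "1", "true", "false")
    raise AssertionError(datatype)


def _number(raw: str, datatype: str) -> float:
    return int(raw) if datatype == "integer" else float(raw)


def brute_force_checks(
    records: list[PatientRecord], schema: SchemaDefinition
) -> set[tuple[str, str, str, str]]:
    """All executed checks as (patient_id, variable, rule_type, outcome) tuples."""
    out: set[tuple[str, str, str, str]] = set()
    for rec in records:
        for v in schema.variables:
            if v.identifier:
                continue
            raw = rec.cells[v.name].raw if v.name in rec.cells else ""
            missing = raw == ""
            if v.requirement_level == "minimal":
                out.add((rec.patient_id, v.name, "minimal_req", "fail" if missing else "pass"))
            if v.requirement_level in ("minimal", "mandatory"):
                out.add((rec.patient_id, v.name, "mandatory_req", "fail" if missing else "pass"))
            if missing:
                continue
            if v.max_length is not None:
                out.add((rec.patient_id, v.name, "length",
                         "fail" if len(raw) > v.max_length else "pass"))
            if v.datatype in _PARSE_TYPES:
                out.add((rec.patient_id, v.name, "datatype",
                         "pass" if _conforms(raw, v.datatype) else "fail"))
            if v.datatype == "code":
                ok = raw in {e.internal_code for e in v.value_set}
                out.add((rec.patient_id, v.name, "permissible", "pass" if ok else "fail"))
            if v.range is not None and v.datatype in ("integer", "decimal"):
                if _conforms(raw, v.datatype):
                    val = _number(raw, v.datatype)
                    ok = v.range[0] <= val <= v.range[1]
                    out.add((rec.patient_id, v.name, "range", "pass" if ok else "fail"))
    return out


def brute_force_tallies(
    records: list[PatientRecord], schema: SchemaDefinition
) -> dict[str, tuple[int, int]]:
    """rule_type -> (fail, pass) recomputed from the brute-force checks."""
    checks = brute_force_checks(records, schema)
    out: dict[str, tuple[int, int]] = {}
    for rt in ("minimal_req", "mandatory_req", "length", "datatype", "permissible", "range"):
        fails = sum(1 for c in checks if c[2] == rt and c[3] == "fail")
        passes = sum(1 for c in checks if c[2] == rt and c[3] == "pass")
        out[rt] = (fails, passes)
    return out
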