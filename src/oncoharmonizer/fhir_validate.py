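"""Independent structural and terminology validator for emitted bundles.

Re-checks every bundle against its own R4B structural tables and the
dictionary's value sets, sharing no code with the builder so it can act
as an oracle over the ETL output. Checks: resource-type legality,
required elements, fixed status code sets, datatype conformance of
quantities and periods, URN format and uniqueness, Patient-first and
single-Patient rules, reference closure, and membership of every coded
value in the dictionary.

Errors make a bundle invalid; warnings (e.g. a period not anchored at
the epoch pseudo-date) do not.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .dictionary_model import SchemaDefinition

# Validator-side structural tables, maintained independently of the builder.
_LEGAL_TYPES = {
    "Patient",
    "Condition",
    "Observation",
    "Procedure",
    "MedicationAdministration",
    "DiagnosticReport",
}

_REQUIRED = {
    "Patient": ("identifier",),
    "Condition": ("subject",),
    "Observation": ("status", "code", "subject"),
    "Procedure": ("status", "subject"),
    "MedicationAdministration": ("status", "medicationCodeableConcept", "subject"),
    "DiagnosticReport": ("status", "code", "subject"),
}

_STATUS_CODES = {
    "Observation": {
        "registered", "preliminary", "final", "amended", "corrected",
        "cancelled", "entered-in-error", "unknown",
    },
    "Procedure": {
        "preparation", "in-progress", "not-done", "on-hold", "stopped",
        "completed", "entered-in-error", "unknown",
    },
    "MedicationAdministration": {
        "in-progress", "not-done", "on-hold", "completed",
        "entered-in-error", "stopped", "unknown",
    },
    "DiagnosticReport": {
        "registered", "partial", "preliminary", "final", "amended",
        "corrected", "appended", "cancelled", "entered-in-error", "unknown",
    },
}

_GENDER_CODES = {"male", "female", "other", "unknown"}

_KNOWN_SYSTEM_URIS = {
    "http://snomed.info/sct",
    "http://loinc.org",
    "http://www.nlm.nih.gov/research/umls/rxnorm",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl",
    "http://terminology.hl7.org/CodeSystem/icd-o-3",
}
_KNOWN_SYSTEM_PREFIXES = ("http://hl7.org/fhir/", "http://terminology.hl7.org/CodeSystem/")

_URN_RE = re.compile(
    r"^urn:uuid:[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
)
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

#: CodeableConcept-bearing element names whose codes must come from the
#: dictionary's value sets, keyed by resource kind.
_BOUND_ELEMENTS = {
    "Condition": ("code",),
    "Observation": ("valueCodeableConcept",),
    "Procedure": ("code",),
    "MedicationAdministration": ("medicationCodeableConcept",),
}

_EPOCH_ISO = "1970-01-01"


@dataclass(frozen=True)
class ValidationFinding:
    file: str
    path: str
    severity: str  # "error" | "warning"
    rule: str
    message: str


@dataclass
class CohortSummary:
    files_checked: int
    valid_count: int
    findings: list[ValidationFinding]

    @property
    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)


def _allowed_codes(schema: SchemaDefinition) -> dict[tuple[str, str], set[str]]:
    """(resource kind, element name) -> set of codes the dictionary admits."""
    out: dict[tuple[str, str], set[str]] = {}
    for v in schema.variables:
        if v.datatype != "code":
            continue
        leaf = v.element_path.split(".", 1)[1]
        key = (v.resource_kind, leaf)
        out.setdefault(key, set()).update(e.coding.code for e in v.value_set)
    return out


def _check_coding_lists(res: dict, kind: str, fname: str, findings: list) -> None:
    def walk(node, path):
        if isinstance(node, dict):
            codings = node.get("coding")
            if isinstance(codings, list):
                for i, c in enumerate(codings):
                    sys_uri = c.get("system", "")
                    if not sys_uri or not c.get("code"):
                        findings.append(ValidationFinding(
                            fname, f"{path}.coding[{i}]", "error", "coding-incomplete",
                            "coding requires non-empty system and code"))
                    elif sys_uri not in _KNOWN_SYSTEM_URIS and not any(
                        sys_uri.startswith(p) for p in _KNOWN_SYSTEM_PREFIXES
                    ):
                        findings.append(ValidationFinding(
                            fname, f"{path}.coding[{i}].system", "error", "system-unknown",
                            f"system {sys_uri!r} outside the admitted terminology families"))
            for k, v in node.items():
                if k != "coding":
                    walk(v, f"{path}.{k}")
        elif isinstance(node, list):
            for i, item in enumerate(node):
                walk(item, f"{path}[{i}]")

    walk(res, kind)


def _check_periods_and_quantities(res: dict, kind: str, fname: str, findings: list) -> None:
    for name, val in res.items():
        path = f"{kind}.{name}"
        if name.endswith("Period") and isinstance(val, dict):
            start, end = val.get("start"), val.get("end")
            for label, d in (("start", start), ("end", end)):
                if not isinstance(d, str) or not _DATE_RE.match(d):
                    findings.append(ValidationFinding(
                        fname, f"{path}.{label}", "error", "date-format",
                        f"{label} must be an ISO date, got {d!r}"))
            if (isinstance(start, str) and isinstance(end, str)
                    and _DATE_RE.match(start) and _DATE_RE.match(end)):
                if date.fromisoformat(end) < date.fromisoformat(start):
                    findings.append(ValidationFinding(
                        fname, path, "error", "period-order", "period end precedes start"))
                if start != _EPOCH_ISO:
                    findings.append(ValidationFinding(
                        fname, f"{path}.start", "warning", "epoch-anchor",
                        "period does not start at the epoch pseudo-date"))
        if name in ("valueQuantity", "onsetAge") and isinstance(val, dict):
            if not isinstance(val.get("value"), (int, float)) or isinstance(val.get("value"), bool):
                findings.append(ValidationFinding(
                    fname, f"{path}.value", "error", "quantity-datatype",
                    f"quantity value must be numeric, got {val.get('value')!r}"))
        if name == "valueInteger" and (not isinstance(val, int) or isinstance(val, bool)):
            findings.append(ValidationFinding(
                fname, path, "error", "integer-datatype",
                f"valueInteger must be an integer, got {val!r}"))


def validate_bundle(source, schema: SchemaDefinition) -> list[ValidationFinding]:
    """Validate one bundle (path, JSON text, or already-parsed dict)."""
    fname = "<memory>"
    if isinstance(source, dict):
        doc = source
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            return [ValidationFinding(fname, "", "error", "unparseable",
                                      f"not valid JSON: {exc}")]
    else:
        p = Path(source)
        fname = p.name
        try:
            doc = json.loads(p.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            return [ValidationFinding(fname, "", "error", "unparseable",
                                      f"not valid JSON: {exc}")]

    findings: list[ValidationFinding] = []
    if doc.get("resourceType") != "Bundle":
        findings.append(ValidationFinding(fname, "resourceType", "error", "bundle-type",
                                          "document is not a Bundle"))
        return findings
    if doc.get("type") != "collection":
        findings.append(ValidationFinding(fname, "Bundle.type", "error", "bundle-type",
                                          f"bundle type must be 'collection', got {doc.get('type')!r}"))
    entries = doc.get("entry", [])
    urns = []
    patient_urns = []
    for i, entry in enumerate(entries):
        urn = entry.get("fullUrl", "")
        urns.append(urn)
        if not _URN_RE.match(urn):
            findings.append(ValidationFinding(
                fname, f"Bundle.entry[{i}].fullUrl", "error", "urn-format",
                f"fullUrl {urn!r} is not a urn:uuid"))
        res = entry.get("resource", {})
        if res.get("resourceType") == "Patient":
            patient_urns.append(urn)
    if len(set(urns)) != len(urns):
        findings.append(ValidationFinding(fname, "Bundle.entry", "error", "urn-unique",
                                          "entry fullUrls are not distinct"))
    if len(patient_urns) != 1:
        findings.append(ValidationFinding(
            fname, "Bundle.entry", "error", "single-patient",
            f"bundle must hold exactly one Patient resource, found {len(patient_urns)}"))
    elif entries and entries[0].get("resource", {}).get("resourceType") != "Patient":
        findings.append(ValidationFinding(fname, "Bundle.entry[0]", "error", "patient-first",
                                          "the Patient resource must be the first entry"))
    allowed = _allowed_codes(schema)
    for i, entry in enumerate(entries):
        res = entry.get("resource", {})
        kind = res.get("resourceType")
        epath = f"Bundle.entry[{i}]"
        if kind not in _LEGAL_TYPES:
            findings.append(ValidationFinding(fname, f"{epath}.resourceType", "error",
                                              "resource-type", f"illegal resource type {kind!r}"))
            continue
        for req in _REQUIRED[kind]:
            if req not in res:
                findings.append(ValidationFinding(
                    fname, f"{kind}.{req}", "error", "required-element",
                    f"required element {kind}.{req} is missing"))
        if "status" in res and kind in _STATUS_CODES:
            if res["status"] not in _STATUS_CODES[kind]:
                findings.append(ValidationFinding(
                    fname, f"{kind}.status", "error", "status-code",
                    f"status {res['status']!r} outside the fixed HL7 set"))
        if kind == "Patient" and "gender" in res and res["gender"] not in _GENDER_CODES:
            findings.append(ValidationFinding(
                fname, "Patient.gender", "error", "status-code",
                f"gender {res['gender']!r} outside the administrative-gender set"))
        if kind != "Patient":
            ref = res.get("subject", {}).get("reference")
            if ref is not None and ref not in patient_urns:
                findings.append(ValidationFinding(
                    fname, f"{kind}.subject", "error", "reference-closure",
                    f"subject reference {ref!r} does not resolve to the bundle's Patient"))
        _check_coding_lists(res, kind, fname, findings)
        _check_periods_and_quantities(res, kind, fname, findings)
        for element in _BOUND_ELEMENTS.get(kind, ()):
            cc = res.get(element)
            if not isinstance(cc, dict):
                continue
            allowed_codes = allowed.get((kind, element), set())
            for j, coding in enumerate(cc.get("coding", [])):
                code = coding.get("code")
                if code and code not in allowed_codes:
                    findings.append(ValidationFinding(
                        fname, f"{kind}.{element}.coding[{j}].code", "error", "terminology",
                        f"code {code!r} not in the dictionary value set for {kind}.{element}"))
    return findings


def validate_cohort(directory: str | Path, schema: SchemaDefinition) -> CohortSummary:
    """Validate every ``*.json`` bundle in a directory."""
    directory = Path(directory)
    files = sorted(directory.glob("*.json"))
    findings: list[ValidationFinding] = []
    valid = 0
    for f in files:
        fs = validate_bundle(f, schema)
        findings.extend(fs)
        if not any(x.severity == "error" for x in fs):
            valid += 1
    if not files:
        findings.append(ValidationFinding(str(directory), "", "warning", "empty-directory",
                                          "no bundle files found"))
    return CohortSummary(files_checked=len(files), valid_count=valid, findings=findings)


def render_summary(summary: CohortSummary) -> str:
    lines = [f"bundles checked: {summary.files_checked}  valid: {summary.valid_count}"]
    for f in summary.findings:
        lines.append(f"[{f.severity}] {f.file} {f.path}: ({f.rule}) {f.message}")
    return "\n".join(lines)
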