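"""Record-to-bundle transformation: the standardization step of the pipeline.

Each harmonized row becomes one FHIR R4B bundle of type ``collection``:
the Patient resource first, then one resource per (resource kind,
resource group) pair populated from the dictionary bindings. Every
resource is addressed by a ``urn:uuid:`` URN; clinical resources
reference the Patient through it.

Where ingestion was lenient, the ETL is strict: an unmappable coded
value or a structural violation aborts the bundle with an error naming
the element path.

Missing-data policy: value-bearing Observation elements carry the HL7
data-absent-reason coding ``unknown`` when the value was not provided;
optional elements elsewhere are simply omitted; a group whose cells are
all missing yields no resource (Observations excepted); a missing
medication agent with other medication facts present is an error.
"""

from __future__ import annotations

import json
import random
import uuid
from dataclasses import dataclass, field
from pathlib import Path

from . import fhir_schema
from .dictionary_model import SchemaDefinition, VariableDefinition, resolve_code
from .errors import BuildError
from .pseudonymization import TimeInterval, recode_interval
from .redcap_io import CellValue, PatientRecord
from .terminology import DATA_ABSENT_REASON, UCUM


class IdFactory:
    """UUIDv4 source; seed it for byte-reproducible cohort transforms."""

    def __init__(self, seed: int | None = None):
        self._rng = random.Random(seed) if seed is not None else None

    def new_urn(self) -> str:
        if self._rng is None:
            u = uuid.uuid4()
        else:
            u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
        return f"urn:uuid:{u}"


@dataclass
class ResourceDoc:
    resource_kind: str
    urn: str
    elements: dict
    subject_urn: str | None = None

    def to_json(self) -> dict:
        doc = {"resourceType": self.resource_kind}
        doc.update(self.elements)
        return doc


@dataclass
class BundleDoc:
    urn: str
    entries: list[ResourceDoc] = field(default_factory=list)
    bundle_type: str = "collection"

    def to_json(self) -> dict:
        return {
            "resourceType": "Bundle",
            "id": self.urn.removeprefix("urn:uuid:"),
            "type": self.bundle_type,
            "entry": [{"fullUrl": e.urn, "resource": e.to_json()} for e in self.entries],
        }


def _codeable_concept(coding) -> dict:
    cc = {"coding": [{"system": coding.system, "code": coding.code}]}
    if coding.display:
        cc["coding"][0]["display"] = coding.display
    return cc


def _quantity(value, unit: str | None) -> dict:
    q = {"value": value}
    if unit:
        q.update({"unit": unit, "system": UCUM, "code": unit})
    return q


def _period(interval: TimeInterval) -> dict:
    p = recode_interval(interval)
    return {"start": p.start.isoformat(), "end": p.end.isoformat()}


_ABSENT = {
    "coding": [
        {"system": DATA_ABSENT_REASON, "code": "unknown", "display": "Unknown"}
    ]
}


def build_patient(record: PatientRecord, schema: SchemaDefinition, urn: str) -> ResourceDoc:
    """Patient resource: hashed identifier plus dictionary-bound demographics."""
    id_vars = [v for v in schema.variables if v.identifier]
    if len(id_vars) != 1:
        raise BuildError("Patient.identifier", f"schema declares {len(id_vars)} patient identifiers")
    if not record.patient_id:
        raise BuildError("Patient.identifier", "record has no patient identifier")
    elements: dict = {
        "identifier": [
            {"system": fhir_schema.PATIENT_ID_SYSTEM, "value": record.patient_id}
        ]
    }
    for v in schema.data_variables:
        if v.resource_kind != "Patient":
            continue
        cell = record.cell(v.name)
        if cell.is_missing:
            continue
        if v.element_path == "Patient.gender":
            elements["gender"] = resolve_code(v, cell.raw).code
        else:
            raise BuildError(v.element_path, "unsupported Patient element")
    return ResourceDoc("Patient", urn, elements)


def _populate(elements: dict, v: VariableDefinition, cell: CellValue) -> None:
    """Place one parsed cell onto the element tree per its dictionary binding."""
    leaf = v.element_path.split(".", 1)[1]
    if cell.parsed is None:
        raise BuildError(v.element_path, f"value {cell.raw!r} does not conform to {v.datatype}")
    if leaf == "code" or leaf == "valueCodeableConcept" or leaf == "medicationCodeableConcept":
        elements[leaf] = _codeable_concept(resolve_code(v, cell.raw))
    elif leaf == "onsetAge":
        elements["onsetAge"] = _quantity(cell.parsed, v.unit or "a")
    elif leaf == "valueQuantity":
        elements["valueQuantity"] = _quantity(cell.parsed, v.unit)
    elif leaf == "valueInteger":
        elements["valueInteger"] = cell.parsed
    elif leaf == "valueString":
        elements["valueString"] = cell.parsed
    elif leaf == "valueBoolean":
        elements["valueBoolean"] = cell.parsed
    elif leaf in ("onsetPeriod", "effectivePeriod", "performedPeriod"):
        elements[leaf] = _period(cell.parsed)
    elif leaf == "conclusion":
        elements["conclusion"] = cell.parsed
    elif leaf == "dosage.dose":
        elements.setdefault("dosage", {})["dose"] = _quantity(cell.parsed, v.unit)
    elif leaf == "extension.totalCycles":
        elements.setdefault("extension", []).append(
            {"url": fhir_schema.EXT_TOTAL_CYCLES, "valueInteger": cell.parsed}
        )
    elif leaf == "extension.cumulativeDose":
        elements.setdefault("extension", []).append(
            {"url": fhir_schema.EXT_CUMULATIVE_DOSE, "valueQuantity": _quantity(cell.parsed, v.unit)}
        )
    else:
        raise BuildError(v.element_path, "unsupported element path")


def build_clinical_resource(
    kind: str,
    group: list[tuple[VariableDefinition, CellValue]],
    subject_urn: str,
    urn: str,
) -> ResourceDoc | None:
    """Condition / Observation / Procedure / DiagnosticReport builder.

    Returns None when a non-Observation group is entirely missing.
    Observations are still emitted in that case, carrying the
    data-absent-reason coding instead of a value.
    """
    kinds = {v.resource_kind for v, _ in group}
    if kinds != {kind}:
        raise BuildError(kind, f"group mixes resource kinds {sorted(kinds)}")
    all_missing = all(c.is_missing for _, c in group)
    if all_missing and kind != "Observation":
        return None
    elements: dict = {}
    if kind in fhir_schema.FIXED_STATUS:
        elements["status"] = fhir_schema.FIXED_STATUS[kind]
    concept = next((v.concept_coding for v, _ in group if v.concept_coding), None)
    if kind in ("Observation", "DiagnosticReport"):
        if concept is None:
            raise BuildError(f"{kind}.code", "group defines no concept coding")
        elements["code"] = _codeable_concept(concept)
    elements["subject"] = {"reference": subject_urn}
    value_seen = False
    for v, cell in group:
        if cell.is_missing:
            continue
        _populate(elements, v, cell)
        if v.element_path in fhir_schema.OBSERVATION_VALUE_PATHS:
            value_seen = True
    for v, _ in group:
        for coding in v.fixed_codings:
            elements.setdefault("category", []).append(_codeable_concept(coding))
    if kind == "Observation" and not value_seen:
        has_value_binding = any(
            v.element_path in fhir_schema.OBSERVATION_VALUE_PATHS for v, _ in group
        )
        if has_value_binding:
            elements["dataAbsentReason"] = _ABSENT
    return ResourceDoc(kind, urn, elements, subject_urn=subject_urn)


def build_medication_administration(
    group: list[tuple[VariableDefinition, CellValue]],
    subject_urn: str,
    id_factory: IdFactory,
) -> list[ResourceDoc]:
    """One MedicationAdministration per agent code in the group.

    The resource holds a single medication entry, so the per-dose
    amount lives on ``dosage.dose`` while total cycles and cumulative
    dose travel as documented extensions, and the treatment interval is
    recoded into epoch pseudo-dates on ``effectivePeriod``.
    """
    agent_leaf = "MedicationAdministration.medicationCodeableConcept"
    agents = [(v, c) for v, c in group if v.element_path == agent_leaf]
    others = [(v, c) for v, c in group if v.element_path != agent_leaf]
    if all(c.is_missing for _, c in group):
        return []
    live_agents = [(v, c) for v, c in agents if not c.is_missing]
    if not live_agents:
        raise BuildError(agent_leaf, "medication facts present but agent code missing")
    resources = []
    for v, cell in live_agents:
        elements: dict = {
            "status": fhir_schema.FIXED_STATUS["MedicationAdministration"],
            "medicationCodeableConcept": _codeable_concept(resolve_code(v, cell.raw)),
            "subject": {"reference": subject_urn},
        }
        for ov, oc in others:
            if oc.is_missing:
                continue
            _populate(elements, ov, oc)
        resources.append(
            ResourceDoc("MedicationAdministration", id_factory.new_urn(), elements, subject_urn)
        )
    return resources


def map_record_to_bundle(
    record: PatientRecord, schema: SchemaDefinition, id_factory: IdFactory | None = None
) -> BundleDoc:
    """Transform one harmonized row into its patient bundle."""
    id_factory = id_factory or IdFactory()
    bundle = BundleDoc(urn=id_factory.new_urn())
    patient = build_patient(record, schema, id_factory.new_urn())
    bundle.entries.append(patient)
    # group in schema order by (kind, resource group)
    groups: dict[tuple[str, str], list[tuple[VariableDefinition, CellValue]]] = {}
    for v in schema.data_variables:
        if v.resource_kind == "Patient":
            continue
        groups.setdefault((v.resource_kind, v.resource_group), []).append(
            (v, record.cell(v.name))
        )
    for (kind, _), group in groups.items():
        if kind == "MedicationAdministration":
            bundle.entries.extend(
                build_medication_administration(group, patient.urn, id_factory)
            )
        else:
            res = build_clinical_resource(kind, group, patient.urn, id_factory.new_urn())
            if res is not None:
                bundle.entries.append(res)
    _check_bundle(bundle)
    return bundle


def _check_bundle(bundle: BundleDoc) -> None:
    urns = [bundle.urn] + [e.urn for e in bundle.entries]
    if len(set(urns)) != len(urns):
        raise BuildError("Bundle.entry.fullUrl", "URNs are not distinct")
    patients = [e for e in bundle.entries if e.resource_kind == "Patient"]
    if len(patients) != 1 or bundle.entries[0].resource_kind != "Patient":
        raise BuildError("Bundle.entry", "bundle must hold exactly one Patient, first")
    for e in bundle.entries[1:]:
        if e.subject_urn != patients[0].urn:
            raise BuildError(f"{e.resource_kind}.subject", "dangling subject reference")


def serialize_bundle(bundle: BundleDoc, out_dir: str | Path, patient_id: str | None = None) -> Path:
    """Write the bundle as one JSON file named by the patient hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if patient_id is None:
        patient_id = bundle.entries[0].elements["identifier"][0]["value"]
    path = out_dir / f"{patient_id}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.to_json(), fh, indent=2, ensure_ascii=False)
        fh.write("\n")
    return path


def bundle_from_json(doc: dict) -> BundleDoc:
    """Rebuild a BundleDoc from its serialized JSON form."""
    entries = []
    patient_urn = None
    for entry in doc.get("entry", []):
        res = dict(entry["resource"])
        kind = res.pop("resourceType")
        subject = res.get("subject", {}).get("reference")
        rd = ResourceDoc(kind, entry["fullUrl"], res, subject_urn=subject)
        if kind == "Patient":
            patient_urn = rd.urn
        entries.append(rd)
    del patient_urn  # subject URNs already carried per-resource
    return BundleDoc(
        urn=f"urn:uuid:{doc['id']}", entries=entries, bundle_type=doc.get("type", "collection")
    )


def transform_cohort(
    records: list[PatientRecord],
    schema: SchemaDefinition,
    out_dir: str | Path,
    seed: int | None = None,
) -> list[Path]:
    """Bundle and serialize a whole cohort; one file per patient."""
    id_factory = IdFactory(seed)
    paths = []
    for record in records:
        bundle = map_record_to_bundle(record, schema, id_factory)
        paths.append(serialize_bundle(bundle, out_dir, patient_id=record.patient_id))
    return paths
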