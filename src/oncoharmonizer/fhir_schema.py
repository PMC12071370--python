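"""Builder-side FHIR R4B structural subset.

Tables describing which element paths the dictionary may bind, per
resource kind, and which raw datatypes each path accepts. This is a
pragmatic subset of the R4B definitions: required elements, datatype
constraints and fixed status codes — not full profile conformance.

The independent validator keeps its own tables (see ``fhir_validate``)
so that it can act as an oracle over the builder's output.
"""

from __future__ import annotations

RESOURCE_KINDS = (
    "Patient",
    "Condition",
    "Observation",
    "Procedure",
    "MedicationAdministration",
    "DiagnosticReport",
)

#: kind -> element path -> raw datatypes the path accepts
ELEMENT_PATHS: dict[str, dict[str, set[str]]] = {
    "Patient": {
        "Patient.identifier": {"string"},
        "Patient.gender": {"code"},
    },
    "Condition": {
        "Condition.code": {"code"},
        "Condition.onsetAge": {"integer", "decimal"},
        "Condition.onsetPeriod": {"interval"},
    },
    "Observation": {
        "Observation.valueCodeableConcept": {"code"},
        "Observation.valueQuantity": {"integer", "decimal"},
        "Observation.valueInteger": {"integer"},
        "Observation.valueString": {"string"},
        "Observation.valueBoolean": {"boolean"},
        "Observation.effectivePeriod": {"interval"},
    },
    "Procedure": {
        "Procedure.code": {"code"},
        "Procedure.performedPeriod": {"interval"},
    },
    "MedicationAdministration": {
        "MedicationAdministration.medicationCodeableConcept": {"code"},
        "MedicationAdministration.dosage.dose": {"integer", "decimal"},
        "MedicationAdministration.extension.totalCycles": {"integer"},
        "MedicationAdministration.extension.cumulativeDose": {"integer", "decimal"},
        "MedicationAdministration.effectivePeriod": {"interval"},
    },
    "DiagnosticReport": {
        "DiagnosticReport.code": {"code"},
        "DiagnosticReport.conclusion": {"string"},
    },
}

#: Fixed status codes applied from HL7/FHIR terminology at build time.
FIXED_STATUS: dict[str, str] = {
    "Observation": "final",
    "Procedure": "completed",
    "MedicationAdministration": "completed",
    "DiagnosticReport": "final",
}

#: Observation value[x] choice paths — these fall under the missing-data
#: policy (a dataAbsentReason is emitted when the value is not provided).
OBSERVATION_VALUE_PATHS = {
    "Observation.valueCodeableConcept",
    "Observation.valueQuantity",
    "Observation.valueInteger",
    "Observation.valueString",
    "Observation.valueBoolean",
}

#: Identifier system for the project-level hashed patient id.
PATIENT_ID_SYSTEM = "https://oncoharmonizer.dev/fhir/NamingSystem/patient-id"

#: Artifact-defined extension URIs for medication facts FHIR cannot hold
#: in a single MedicationAdministration entry.
EXT_TOTAL_CYCLES = "https://oncoharmonizer.dev/fhir/StructureDefinition/total-cycles"
EXT_CUMULATIVE_DOSE = "https://oncoharmonizer.dev/fhir/StructureDefinition/cumulative-dose"


def is_valid_element_path(resource_kind: str, element_path: str) -> bool:
    return element_path in ELEMENT_PATHS.get(resource_kind, {})


def path_accepts(resource_kind: str, element_path: str, datatype: str) -> bool:
    return datatype in ELEMENT_PATHS.get(resource_kind, {}).get(element_path, set())
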