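"""Record-to-bundle transformation and serialization."""

import json

import pytest

from oncoharmonizer import IdFactory, generate_cohort, map_record_to_bundle, transform_cohort
from oncoharmonizer.dictionary_model import (
    OntologyCoding,
    SchemaDefinition,
    ValueSetEntry,
    VariableDefinition,
)
from oncoharmonizer.errors import BuildError, UnmappedValueError
from oncoharmonizer.fhir_etl import (
    build_clinical_resource,
    build_medication_administration,
    bundle_from_json,
    serialize_bundle,
)
from oncoharmonizer.fhir_schema import EXT_TOTAL_CYCLES
from oncoharmonizer.redcap_io import CellValue, PatientRecord, make_cell
from oncoharmonizer.terminology import RXNORM, SNOMED_CT


def _patient_only_schema():
    return SchemaDefinition(
        schema_id="p",
        variables=[
            VariableDefinition(name="patient_id", identifier=True, datatype="string",
                               resource_kind="Patient", element_path="Patient.identifier"),
            VariableDefinition(
                name="sex", datatype="code", resource_kind="Patient",
                element_path="Patient.gender",
                value_set=[ValueSetEntry(
                    internal_code="1",
                    coding=OntologyCoding(
                        system="http://hl7.org/fhir/administrative-gender", code="female"),
                )],
            ),
        ],
    )


def _record(schema, **raws):
    cells = {}
    for v in schema.data_variables:
        cells[v.name] = make_cell(raws.get(v.name, ""), v)
    return PatientRecord(patient_id="a" * 64, schema_id=schema.schema_id, cells=cells)


def test_patient_only_record_yields_single_resource_bundle():
    schema = _patient_only_schema()
    bundle = map_record_to_bundle(_record(schema, sex="1"), schema, IdFactory(0))
    assert len(bundle.entries) == 1
    patient = bundle.entries[0].to_json()
    assert patient["resourceType"] == "Patient"
    assert patient["gender"] == "female"
    assert patient["identifier"][0]["value"] == "a" * 64


def test_demo_record_resource_census(demo_schema):
    record = generate_cohort(demo_schema, 1, seed=4)[0]
    bundle = map_record_to_bundle(record, demo_schema, IdFactory(0))
    kinds = [e.resource_kind for e in bundle.entries]
    # dictionary grouping predicts: Patient, 2 Conditions (classification
    # + diagnosis), 2 Observations, 1 Procedure, 1 MedicationAdministration,
    # 1 DiagnosticReport
    assert kinds[0] == "Patient"
    assert sorted(kinds) == sorted(
        ["Patient", "Condition", "Condition", "Observation", "Observation",
         "Procedure", "MedicationAdministration", "DiagnosticReport"]
    )
    patient_urn = bundle.entries[0].urn
    assert all(e.subject_urn == patient_urn for e in bundle.entries[1:])


def test_case_control_lands_on_condition(demo_schema):
    # the case/control classification is modelled as a Condition (so it
    # can carry age at diagnosis), not as an Observation
    record = generate_cohort(demo_schema, 1, seed=4)[0]
    record.cells["case_control"] = make_cell("0", demo_schema.variable("case_control"))
    bundle = map_record_to_bundle(record, demo_schema, IdFactory(0))
    conditions = [e.to_json() for e in bundle.entries if e.resource_kind == "Condition"]
    codes = {c["coding"][0]["code"] for cond in conditions for c in [cond["code"]]}
    assert "20376005" in codes  # benign-lesion control code on a Condition


def test_unmapped_code_aborts_strictly(demo_schema):
    record = generate_cohort(demo_schema, 1, seed=4)[0]
    record.cells["diagnosis"] = make_cell("77", demo_schema.variable("diagnosis"))
    with pytest.raises(UnmappedValueError):
        map_record_to_bundle(record, demo_schema, IdFactory(0))


def test_observation_missing_value_carries_absent_reason(demo_schema):
    record = generate_cohort(demo_schema, 1, seed=4)[0]
    record.cells["her2_status"] = CellValue(raw="")
    bundle = map_record_to_bundle(record, demo_schema, IdFactory(0))
    her2 = next(
        e.to_json() for e in bundle.entries
        if e.resource_kind == "Observation"
        and e.to_json()["code"]["coding"][0]["code"] == "48676-1"
    )
    assert "valueCodeableConcept" not in her2
    assert her2["dataAbsentReason"]["coding"][0]["code"] == "unknown"


def test_generic_grading_scale_value_set():
    # histology grading on a generic SNOMED scale ("1 on a scale of 1 to 5")
    grade = VariableDefinition(
        name="grade", datatype="code", resource_kind="Observation",
        element_path="Observation.valueCodeableConcept",
        concept_coding=OntologyCoding(system=SNOMED_CT, code="371469007"),
        value_set=[
            ValueSetEntry(internal_code=str(i),
                          coding=OntologyCoding(system=SNOMED_CT, code=f"4435400{i}",
                                                display=f"Grade {i} on a scale of 1 to 5"))
            for i in range(1, 6)
        ],
    )
    res = build_clinical_resource(
        "Observation", [(grade, make_cell("1", grade))], "urn:uuid:x", "urn:uuid:y"
    )
    doc = res.to_json()
    assert doc["valueCodeableConcept"]["coding"][0]["system"] == SNOMED_CT
    assert doc["status"] == "final"


def _med_group(agent_raw="1", cycles_raw="", interval_raw=""):
    agent = VariableDefinition(
        name="agent", datatype="code", resource_kind="MedicationAdministration",
        element_path="MedicationAdministration.medicationCodeableConcept",
        value_set=[
            ValueSetEntry(internal_code="1",
                          coding=OntologyCoding(system=RXNORM, code="3639")),
            ValueSetEntry(internal_code="2",
                          coding=OntologyCoding(system=RXNORM, code="56946")),
        ],
    )
    cycles = VariableDefinition(
        name="cycles", datatype="integer", resource_kind="MedicationAdministration",
        element_path="MedicationAdministration.extension.totalCycles",
    )
    interval = VariableDefinition(
        name="interval", datatype="interval", resource_kind="MedicationAdministration",
        element_path="MedicationAdministration.effectivePeriod",
    )
    return [
        (agent, make_cell(agent_raw, agent)),
        (cycles, make_cell(cycles_raw, cycles)),
        (interval, make_cell(interval_raw, interval)),
    ]


def test_medication_epoch_recoding_and_cycles_extension():
    group = _med_group(agent_raw="1", cycles_raw="6", interval_raw="4 months")
    resources = build_medication_administration(group, "urn:uuid:p", IdFactory(0))
    assert len(resources) == 1
    doc = resources[0].to_json()
    assert doc["effectivePeriod"] == {"start": "1970-01-01", "end": "1970-05-01"}
    ext = {e["url"]: e for e in doc["extension"]}
    assert ext[EXT_TOTAL_CYCLES]["valueInteger"] == 6
    assert doc["status"] == "completed"


def test_medication_agent_only_minimal_resource():
    resources = build_medication_administration(_med_group("2"), "urn:uuid:p", IdFactory(0))
    assert len(resources) == 1
    doc = resources[0].to_json()
    assert doc["medicationCodeableConcept"]["coding"][0]["code"] == "56946"
    assert "extension" not in doc and "effectivePeriod" not in doc


def test_two_agents_one_group_two_resources():
    group = _med_group("1")
    agent2 = group[0][0].model_copy(update={"name": "agent2"})
    group.append((agent2, make_cell("2", agent2)))
    resources = build_medication_administration(group, "urn:uuid:p", IdFactory(0))
    assert len(resources) == 2


def test_medication_facts_without_agent_error():
    group = _med_group(agent_raw="", cycles_raw="6")
    with pytest.raises(BuildError):
        build_medication_administration(group, "urn:uuid:p", IdFactory(0))


def test_two_identifier_variables_error():
    schema = _patient_only_schema()
    dup = schema.variables[0].model_copy(update={"name": "patient_id2"})
    schema.variables.append(dup)
    with pytest.raises(BuildError):
        map_record_to_bundle(_record(schema, sex="1"), schema, IdFactory(0))


def test_serialize_parse_serialize_byte_identical(demo_schema, tmp_path):
    records = generate_cohort(demo_schema, 3, seed=5)
    paths = transform_cohort(records, demo_schema, tmp_path / "out", seed=1)
    assert len(paths) == 3
    for p in paths:
        doc = json.loads(p.read_text(encoding="utf-8"))
        assert doc["resourceType"] == "Bundle" and doc["type"] == "collection"
        again = serialize_bundle(bundle_from_json(doc), tmp_path / "again")
        assert again.read_bytes() == p.read_bytes()


def test_seeded_transform_is_byte_reproducible(demo_schema, tmp_path):
    records = generate_cohort(demo_schema, 4, seed=6)
    paths1 = transform_cohort(records, demo_schema, tmp_path / "run1", seed=42)
    paths2 = transform_cohort(records, demo_schema, tmp_path / "run2", seed=42)
    for p1, p2 in zip(paths1, paths2):
        assert p1.name == p2.name
        assert p1.read_bytes() == p2.read_bytes()
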