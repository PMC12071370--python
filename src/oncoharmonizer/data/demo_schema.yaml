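# Demo data schema: breast-lesion use case, 12 clinical variables plus
# the hashed patient identifier, spanning all six supported FHIR
# resource kinds. Representative of a production schema, not authentic:
# per-kind variable counts — Patient 1, Condition 3, Observation 2,
# Procedure 2, MedicationAdministration 3, DiagnosticReport 1.
schema_id: demo_breast
use_cases:
  - breast lesion case/control classification
  - neoadjuvant treatment response
variables:
  - name: patient_id
    identifier: true
    requirement_level: minimal
    datatype: string
    resource_kind: Patient
    element_path: Patient.identifier

  - name: sex
    requirement_level: minimal
    datatype: code
    resource_kind: Patient
    element_path: Patient.gender
    value_set:
      - internal_code: "1"
        label: Female
        coding: {system: "http://hl7.org/fhir/administrative-gender", code: female, display: Female}
      - internal_code: "2"
        label: Male
        coding: {system: "http://hl7.org/fhir/administrative-gender", code: male, display: Male}
      - internal_code: "3"
        label: Other
        sentinel_other: true
        coding: {system: "http://hl7.org/fhir/administrative-gender", code: other, display: Other}

  - name: case_control
    requirement_level: minimal
    datatype: code
    resource_kind: Condition
    resource_group: classification
    element_path: Condition.code
    value_set:
      - internal_code: "1"
        label: Case (malignant lesion)
        coding: {system: "http://snomed.info/sct", code: "363346000", display: Malignant neoplastic disease}
      - internal_code: "0"
        label: Control (benign lesion)
        coding: {system: "http://snomed.info/sct", code: "20376005", display: Benign neoplastic disease}

  - name: diagnosis
    requirement_level: minimal
    datatype: code
    resource_kind: Condition
    resource_group: diagnosis
    element_path: Condition.code
    value_set:
      - internal_code: "1"
        label: Invasive ductal carcinoma
        coding: {system: "http://terminology.hl7.org/CodeSystem/icd-o-3", code: "8500/3", display: Infiltrating duct carcinoma}
      - internal_code: "2"
        label: Invasive lobular carcinoma
        coding: {system: "http://terminology.hl7.org/CodeSystem/icd-o-3", code: "8520/3", display: Lobular carcinoma}
      - internal_code: "3"
        label: Ductal carcinoma in situ
        coding: {system: "http://terminology.hl7.org/CodeSystem/icd-o-3", code: "8500/2", display: "Intraductal carcinoma, noninfiltrating"}
      - internal_code: "9"
        label: Other histology
        sentinel_other: true
        # grouped "other" category expressed as a SNOMED post-coordinated expression
        coding: {system: "http://snomed.info/sct", code: "64572001:116676008=399981008", display: "Disease with neoplasm, other histology"}

  - name: age_at_diagnosis
    requirement_level: minimal
    datatype: integer
    resource_kind: Condition
    resource_group: diagnosis
    element_path: Condition.onsetAge
    unit: a
    range: [18, 100]

  - name: tumor_size_mm
    requirement_level: mandatory
    datatype: decimal
    resource_kind: Observation
    resource_group: tumor_size
    element_path: Observation.valueQuantity
    unit: mm
    range: [0, 500]
    concept_coding: {system: "http://loinc.org", code: "21889-1", display: Size Tumor}

  - name: her2_status
    requirement_level: mandatory
    datatype: code
    resource_kind: Observation
    resource_group: her2
    element_path: Observation.valueCodeableConcept
    concept_coding: {system: "http://loinc.org", code: "48676-1", display: "HER2 [Interpretation] in Tissue"}
    value_set:
      - internal_code: "1"
        label: HER2 positive
        coding: {system: "http://snomed.info/sct", code: "431396003", display: HER2 positive carcinoma of breast}
      - internal_code: "0"
        label: HER2 negative
        coding: {system: "http://snomed.info/sct", code: "431397007", display: HER2 negative carcinoma of breast}
      - internal_code: "9"
        label: Other / equivocal
        sentinel_other: true
        coding: {system: "http://snomed.info/sct", code: "397468009:363713009=82334004", display: "HER2 interpretation, indeterminate"}

  - name: surgery_type
    requirement_level: mandatory
    datatype: code
    resource_kind: Procedure
    resource_group: surgery
    element_path: Procedure.code
    value_set:
      - internal_code: "1"
        label: Mastectomy
        coding: {system: "http://snomed.info/sct", code: "69031006", display: Excision of breast tissue}
      - internal_code: "2"
        label: Breast-conserving surgery
        coding: {system: "http://snomed.info/sct", code: "64368001", display: Partial mastectomy}
      - internal_code: "3"
        label: No surgery
        coding: {system: "http://snomed.info/sct", code: "787108001", display: Surgical procedure declined}

  - name: time_diag_to_surgery
    requirement_level: recommended
    datatype: interval
    resource_kind: Procedure
    resource_group: surgery
    element_path: Procedure.performedPeriod

  - name: chemo_agent
    requirement_level: mandatory
    datatype: code
    resource_kind: MedicationAdministration
    resource_group: chemo
    element_path: MedicationAdministration.medicationCodeableConcept
    value_set:
      - internal_code: "1"
        label: Doxorubicin
        coding: {system: "http://www.nlm.nih.gov/research/umls/rxnorm", code: "3639", display: Doxorubicin}
      - internal_code: "2"
        label: Paclitaxel
        coding: {system: "http://www.nlm.nih.gov/research/umls/rxnorm", code: "56946", display: Paclitaxel}
      - internal_code: "3"
        label: Cyclophosphamide
        coding: {system: "http://www.nlm.nih.gov/research/umls/rxnorm", code: "3002", display: Cyclophosphamide}

  - name: chemo_cycles
    requirement_level: recommended
    datatype: integer
    resource_kind: MedicationAdministration
    resource_group: chemo
    element_path: MedicationAdministration.extension.totalCycles
    range: [1, 12]

  - name: chemo_interval
    requirement_level: recommended
    datatype: interval
    resource_kind: MedicationAdministration
    resource_group: chemo
    element_path: MedicationAdministration.effectivePeriod

  - name: imaging_conclusion
    requirement_level: recommended
    datatype: string
    resource_kind: DiagnosticReport
    resource_group: imaging
    element_path: DiagnosticReport.conclusion
    max_length: 100
    concept_coding: {system: "http://loinc.org", code: "19005-8", display: "Radiology Imaging study [Impression]"}
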