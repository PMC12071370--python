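# oncoharmonizer

Standardizing multicenter oncology cohort data for AI research is mostly
plumbing — and the plumbing is where interoperability fails.
`oncoharmonizer` implements that plumbing as a single dictionary-driven
pipeline: harmonized patient-level CSV exports (one row per patient, in
the raw-coded export dialect of REDCap-style capture systems) are scored
for quality along three standard dimensions, pseudonymized, and emitted
as HL7 FHIR R4B JSON bundles — one file per patient — with terminology
bindings to SNOMED CT, ICD-O-3, LOINC, RxNorm, NCIT and the HL7/FHIR
code systems. It is written for data engineers and stewards of clinical
research consortia who need a reproducible, testable path from a capture
database to an archival FHIR representation.

Everything is driven by a machine-readable **data dictionary** (one YAML
document per data schema) binding each variable to its datatype, one of
three requirement levels (*minimal* ⊂ *mandatory*; *recommended*), a
value set with ontology codes, constraints, and a FHIR resource kind +
element path. The same dictionary drives both quality control and the
ETL, so the two can never drift apart.

## Quality scoring

For each quality-check type *t* (minimal_req, mandatory_req, length,
datatype, permissible, range — grouped into the Completeness,
Conformance and Plausibility dimensions) with `fail_t` failures,
`pass_t` passes and configured weight `w_t` (Σ w_t = 100):

```
score_t = w_t · pass_t / (fail_t + pass_t)        (full w_t when no check ran)
total   = Σ_t score_t                              (unrounded terms; display
                                                    rounded half-up to 2 dp)
```

Missing cells are attributed to Completeness only; conformance and
plausibility checks skip them, so one defect is never counted twice.

## Pseudonymization

Patient identifiers are double-hashed (SHA-256, site salt then platform
salt). Calendar dates are never collected: durations arrive as time
intervals (`"4 months"`, `"6 weeks"`, …) and, where a FHIR element
demands dates (MedicationAdministration's effective element), are
recoded into pseudo-periods anchored at 1970-01-01 whose span preserves
the interval — e.g. 4 months → 1970-01-01/1970-05-01.

## Worked example

Generate a 20-patient synthetic cohort against the shipped demo schema,
planting two blanked minimal cells, three out-of-set codes and one
out-of-range number, then score it:

```bash
oncoharmonizer generate --schema src/oncoharmonizer/data/demo_schema.yaml \
    --n 20 --seed 7 --inject "minimal_req=2,permissible=3,range=1" --out cohort.csv
oncoharmonizer qc --schema src/oncoharmonizer/data/demo_schema.yaml --input cohort.csv
```

```
Dimension     Type           Fail  Pass  Total  Weight  Score
Completeness  minimal_req    2     78    80     50      48.75%
Completeness  mandatory_req  2     158   160    10      9.88%
Conformance   length         0     20    20     10      10.00%
Conformance   datatype       0     99    99     10      10.00%
Conformance   permissible    3     116   119    10      9.75%
Plausibility  range          1     58    59     10      9.83%
Total:                       8     529   537    100     98.20%
```

Reading it: the two blanked minimal cells fail both requirement rows
(minimal is a fortiori mandatory) and, being blank, were skipped by the
conformance rows — hence 99 of 100 typed cells executed a datatype
check. The total, 98.20 %, is the weight-scaled pass fraction summed
over the six rows before rounding.

Continue the pipeline — standardize and independently validate:

```bash
oncoharmonizer transform --schema src/oncoharmonizer/data/demo_schema.yaml \
    --input cohort.csv --out-dir bundles/ --seed 7 --lenient
oncoharmonizer validate --schema src/oncoharmonizer/data/demo_schema.yaml --dir bundles/
```

`transform` writes one FHIR R4B `collection` bundle per patient, named
by the patient hash, Patient resource first, every clinical resource
referencing it by `urn:uuid:`. In strict mode (default) an unmappable
code aborts the run; `--lenient` skips the offending patient.
`validate` re-checks structure, status codes, reference closure and
value-set membership with tables independent of the builder, and exits
non-zero on any error.

Two medication facts FHIR cannot hold in a single
MedicationAdministration entry travel as documented extensions:

* `https://oncoharmonizer.dev/fhir/StructureDefinition/total-cycles` (valueInteger)
* `https://oncoharmonizer.dev/fhir/StructureDefinition/cumulative-dose` (valueQuantity)

## Layout

```
src/oncoharmonizer/
  dictionary_model.py   # dictionary types, loader, validator, code resolution
  redcap_io.py          # CSV export dialect: lenient parse, exact round-trip
  qc_engine.py          # rules, findings, weighted scorecard
  pseudonymization.py   # double hashing, epoch interval recoding
  fhir_etl.py           # record -> bundle transformation + serialization
  fhir_validate.py      # independent structural/terminology validator
  synthetic_cohort.py   # seeded generator + bookkept defect injection
  cli.py                # oncoharmonizer generate|qc|transform|validate
  data/demo_schema.yaml # shipped demo dictionary (12 variables + id)
```

See `docs/methods.md` for the design rationale and known limitations.
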