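# Methods

## The model

The pipeline treats clinical-data standardization as three composable
transforms over one shared artifact, the data dictionary:

1. **Ingest** — capture-form CSV exports are parsed leniently: a cell
   that does not conform to its declared datatype is retained with its
   raw text and surfaces as a conformance finding rather than an ingest
   failure. Only two conditions are fatal, because no downstream
   interpretation is possible: a missing patient-identifier column and
   duplicated patient identifiers.
2. **Quality scoring** — every applicable (record, rule) pair yields
   exactly one pass/fail finding; scores are weight-scaled pass
   fractions per check type, summed unrounded and rounded half-up to
   two decimals only for display.
3. **Standardization** — each row becomes one FHIR R4B bundle of type
   `collection` (archival storage, not server transactions), Patient
   first, all resources addressed by `urn:uuid:` URNs. ETL is strict
   where ingest was lenient: an unmappable code aborts the patient's
   bundle.

An independent validator re-checks emitted bundles from its own
structural tables, deliberately sharing no code with the builder, so the
two act as mutual oracles in the test suite.

## Quality-scoring semantics

Check types and dimensions: minimal_req and mandatory_req
(Completeness), length, datatype and permissible (Conformance), range
(Plausibility).

* **Requirement checks always execute.** A minimal variable is a
  fortiori mandatory, so a blanked minimal cell fails both requirement
  checks. Recommended variables carry no completeness requirement.
* **Missing cells skip conformance and plausibility.** Missingness is
  attributed once, to Completeness; without this rule a single blank
  would depress up to three dimensions at once and the scores would no
  longer be interpretable per dimension.
* **Datatype checks attach to parse-constrained datatypes** (integer,
  decimal, interval, boolean). A coded cell's type conformance is
  exactly its membership in the permissible-value list — a separate
  datatype check would double-count the same property — and any text
  conforms to `string`. An unparseable numeric additionally skips its
  range check (the datatype finding owns that defect).
* **Vacuous checks keep full weight.** A check type with zero executed
  checks contributes its entire weight. The alternative — renormalizing
  the remaining weights — silently changes what the configured weights
  mean; with the vacuous-truth rule, a score of 100 is equivalent to
  zero failures, which is the property users actually read off the
  total.
* **Rounding.** Half-up to two decimals, display only. Aggregation must
  use unrounded terms: in the reference scorecard the rounded row scores
  sum to 89.62 while the correctly aggregated total is 89.63.
* **Default weights** put 50 on minimal requirements and 10 on each
  other check type (sum 100), matching the reference configuration; any
  weighting summing to 100 may be supplied.
* **Record-level ratings** are emitted per patient and dimension using
  the same formula with the dimension's summed weight. No automatic
  record filtering is performed — the threshold, if any, is the
  operator's call (`--min-score` gates the process exit status only).

## Pseudonymization

* Identifier hashing is SHA-256 applied twice — `sha256(platform_salt +
  sha256(site_salt + local_id))`, lowercase hex. SHA-256 was chosen for
  ubiquity and testability; salts are supplied via configuration and
  never logged. This is pseudonymization, not anonymization: with the
  salts and source data the mapping is reversible by construction.
* Interval recoding anchors every pseudo-period at 1970-01-01. Weeks
  are exactly 7 days; months are calendar months added from day 1,
  which is never ambiguous because the anchor is the 1st. The inverse
  (`decode_period`) exists for round-trip testing and refuses spans
  that are not exactly representable in the requested unit.
* Period-typed FHIR elements receive the pseudo-period directly; the
  epoch recoding into plain dates exists for elements that only accept
  dates (the MedicationAdministration effective element).

## FHIR subset and modelling choices

The implemented R4B subset covers the six resource kinds the data model
needs (Patient, Condition, Observation, Procedure,
MedicationAdministration, DiagnosticReport): required elements, datatype
constraints on the bound element paths, and fixed status codes from the
HL7 terminology (`final` / `completed`). It is not full profile
conformance — no StructureDefinition authoring, no terminology-server
lookups (terminology validation is membership-in-dictionary only), no
SNOMED expression-grammar parsing (post-coordinated expressions are
carried as opaque strings; they are representation, not computation).

Notable modelling decisions:

* Case/control classification lives on a Condition (its own resource
  group), not an Observation, so it can sit beside age at diagnosis.
* One MedicationAdministration per agent; per-dose amount on
  `dosage.dose`; total cycles and cumulative dose as documented
  extensions (the resource holds a single medication entry).
* Missing data: value-bearing Observation elements carry the HL7
  data-absent-reason coding `unknown` (the code system's closest member
  for "not provided"); optional elements elsewhere are omitted; a
  non-Observation group that is entirely missing yields no resource;
  required inputs that are missing abort the build.
* UUIDs are version 4; a seeded factory makes whole-cohort transforms
  byte-reproducible for testing and auditability.

## The synthetic cohort generator

No real cohort ships with the package, so the generator emulates the
harmonized per-schema table: coded cells drawn uniformly from the value
sets, numerics uniform within declared ranges (defaults 0–120 for
unconstrained integers, 0–100 for decimals), intervals within plausible
clinical bounds (≤ 365 days / 52 weeks / 36 months), short free-text
strings truncated to any length limit. All draws come from one seeded
stream per call. Deliberately **not** modelled: correlation structure
between variables, site effects, realistic marginal distributions, and
organic missingness (all missingness is injected). Passing tests
therefore demonstrate the pipeline's bookkeeping and transformation
correctness on structurally realistic data, not robustness to the
messiness of real clinical exports.

Defect injection plants an exact number of violations per check type at
mutually non-overlapping cells (blank a required cell; overlong string;
non-numeric token; out-of-set code; out-of-range by at least one unit)
and logs every site, so the generator and the QC engine verify each
other: the engine must recover the injected counts exactly, including
the minimal→mandatory cascade.

### The scoring-report demonstration schema

The reference scorecard tallies 18 minimal and 35 mandatory requirement
checks. Both counts are per-record-constant sums, so their being coprime
forces a one-record cohort, and the schema itself must carry the full
check budget: 18 minimal + 17 mandatory + 23 recommended coded
variables (58 permissible checks, three of which are blanked by the
completeness injections), 40 integer variables (4 with ranges) and 11
length-limited strings. With the documented injection profile (2
minimal blanks, 1 mandatory blank, 1 overlong string, 3 out-of-set
codes, 1 out-of-range number) the executed tallies are 18/35/11/40/55/4
with fails 2/3/1/0/3/1 for any seed — the structure, not the random
draw, fixes the scorecard. The schema is wider than a typical capture
schema (which carries roughly 8–39 variables); it exists to realize the
worked example end to end.

## Numerical and procedural details

* Rounding uses `decimal.Decimal` with `ROUND_HALF_UP`; Python's
  built-in banker's rounding would print 44.45 vs 44.44 class errors on
  half-cent boundaries.
* CSV round-trips are exact at the raw level: write→parse→write is
  byte-identical (comma-delimited, minimal quoting, UTF-8, empty string
  as the sole missing marker — "NA"/"NULL" spellings deliberately fail
  datatype conformance so sloppy missingness is visible in QC).
* Bundle serialization is deterministic: stable element insertion
  order, two-space indentation, trailing newline; serialize→parse→
  serialize is byte-identical.
* Test problem sizes: cohorts of 1–50 records and around a hundred
  seeds for the engine/oracle equivalence sweep — small enough to run
  the whole suite in seconds while exercising every code path.

## Known limitations

* Demo schemas are representative, not authentic production schemas;
  value sets are illustrative.
* Checkbox-style multi-valued capture fields are unsupported (the demo
  schemas are single-valued).
* The validator checks the implemented subset, not full R4B profile
  conformance; a bundle passing here may still fail an official
  profile validator over constraints this subset does not model.
* Ontology release versions are recorded as metadata only and never
  validated against terminology services.
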