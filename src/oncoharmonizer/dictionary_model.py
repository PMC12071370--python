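"""Machine-readable data dictionary: the single config that drives QC and ETL.

A dictionary (one YAML document per data schema) binds every captured
variable to its datatype, requirement level, value set with ontology
codes, constraints (length, numeric range), and the FHIR resource kind /
element path it standardizes into. Three requirement levels exist:
*minimal* (essential ground-truth fields), *mandatory* (enriching model
inputs) and *recommended* (optional added value). Minimal variables are
a fortiori mandatory.

Document layout (keys are fixed)::

    schema_id: demo_breast
    use_cases: [breast-lesion classification]
    variables:
      - name: sex
        requirement_level: minimal
        datatype: code
        resource_kind: Patient
        element_path: Patient.gender
        value_set:
          - internal_code: "1"
            label: Female
            coding: {system: "http://hl7.org/fhir/administrative-gender",
                     code: female, display: Female}

Optional per-variable keys: ``identifier`` (bool, marks the patient-id
column), ``resource_group`` (variables sharing a kind and group populate
one resource), ``max_length``, ``range`` ([min, max]), ``unit`` (UCUM
code for quantities), ``concept_coding`` (the ontology code identifying
the variable itself, e.g. the LOINC code of an observation),
``fixed_codings`` and ``sentinel_other`` (marks the grouped "other"
value-set entry, typically a SNOMED post-coordinated expression).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import fhir_schema, terminology
from .errors import DictionaryError, UnmappedValueError

RequirementLevel = Literal["minimal", "mandatory", "recommended"]
Datatype = Literal["code", "integer", "decimal", "string", "interval", "boolean"]


class OntologyCoding(BaseModel):
    """One terminology binding: system URI, code, human-readable display."""

    model_config = ConfigDict(frozen=True)

    system: str
    code: str = Field(min_length=1)
    display: str = ""


class ValueSetEntry(BaseModel):
    """Binds one raw capture-form code to its ontology coding."""

    internal_code: str
    label: str = ""
    coding: OntologyCoding
    sentinel_other: bool = False


class VariableDefinition(BaseModel):
    """One dictionary entry for a captured clinical variable."""

    name: str
    schema_id: str = ""
    requirement_level: RequirementLevel = "recommended"
    datatype: Datatype
    identifier: bool = False
    value_set: list[ValueSetEntry] = Field(default_factory=list)
    max_length: Optional[int] = Field(default=None, gt=0)
    range: Optional[tuple[float, float]] = None
    resource_kind: Literal[
        "Patient",
        "Condition",
        "Observation",
        "Procedure",
        "MedicationAdministration",
        "DiagnosticReport",
    ]
    element_path: str
    resource_group: str = "main"
    unit: Optional[str] = None
    concept_coding: Optional[OntologyCoding] = None
    fixed_codings: list[OntologyCoding] = Field(default_factory=list)


class SchemaDefinition(BaseModel):
    """One data schema: an ordered list of variable definitions."""

    schema_id: str
    use_cases: list[str] = Field(default_factory=list)
    variables: list[VariableDefinition]

    def variable(self, name: str) -> VariableDefinition:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def identifier_variable(self) -> VariableDefinition:
        for v in self.variables:
            if v.identifier:
                return v
        raise DictionaryError([f"schema {self.schema_id!r}: no patient-identifier variable"])

    @property
    def data_variables(self) -> list[VariableDefinition]:
        """Variables other than the patient identifier."""
        return [v for v in self.variables if not v.identifier]


def validate_dictionary(schema: SchemaDefinition) -> list[str]:
    """Check every dictionary invariant; return one message per violation.

    Violations are data, not exceptions — an empty list means the schema
    is valid.
    """
    out: list[str] = []
    names = [v.name for v in schema.variables]
    for n in sorted({n for n in names if names.count(n) > 1}):
        out.append(f"variable {n!r}: duplicate name within schema")
    if sum(1 for v in schema.variables if v.identifier) != 1:
        out.append(
            f"schema {schema.schema_id!r}: exactly one patient-identifier variable required"
        )
    for v in schema.variables:
        where = f"variable {v.name!r}"
        if v.datatype == "code" and not v.value_set:
            out.append(f"{where}: coded variable requires a non-empty value set")
        if v.datatype != "code" and v.value_set:
            out.append(f"{where}: value set only permitted for datatype=code")
        if v.range is not None:
            if v.datatype not in ("integer", "decimal"):
                out.append(f"{where}: range only permitted for numeric datatypes")
            elif v.range[0] > v.range[1]:
                out.append(f"{where}: range lower bound {v.range[0]} exceeds upper {v.range[1]}")
        if not fhir_schema.is_valid_element_path(v.resource_kind, v.element_path):
            out.append(
                f"{where}: element path {v.element_path!r} is not a supported "
                f"{v.resource_kind} element"
            )
        elif not fhir_schema.path_accepts(v.resource_kind, v.element_path, v.datatype):
            out.append(
                f"{where}: element path {v.element_path!r} does not accept datatype "
                f"{v.datatype!r}"
            )
        codes = [e.internal_code for e in v.value_set]
        for c in sorted({c for c in codes if codes.count(c) > 1}):
            out.append(f"{where}: duplicate internal code {c!r} in value set")
        all_codings = [e.coding for e in v.value_set] + v.fixed_codings
        if v.concept_coding is not None:
            all_codings.append(v.concept_coding)
        for coding in all_codings:
            if not terminology.is_registered_system(coding.system):
                out.append(f"{where}: system {coding.system!r} outside the terminology registry")
            if terminology.is_postcoordinated(coding.code) and not terminology.is_snomed(
                coding.system
            ):
                out.append(
                    f"{where}: post-coordinated expression {coding.code!r} only "
                    "permitted under SNOMED CT"
                )
    return out


def _format_pydantic_error(exc: ValidationError) -> list[str]:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        msgs.append(f"{loc}: {err['msg']}")
    return msgs


def load_dictionary(path: str | Path) -> SchemaDefinition:
    """Load and validate one schema dictionary from its YAML document.

    Raises ``DictionaryError`` listing *every* violation found, or a
    ``yaml.YAMLError`` (which carries line/column context) on a file
    that is not parseable at all.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DictionaryError([f"{path}: document root must be a mapping"])
    try:
        schema = SchemaDefinition.model_validate(doc)
    except ValidationError as exc:
        raise DictionaryError(_format_pydantic_error(exc)) from exc
    # denormalize schema_id onto each variable
    schema = schema.model_copy(
        update={
            "variables": [
                v.model_copy(update={"schema_id": schema.schema_id}) for v in schema.variables
            ]
        }
    )
    violations = validate_dictionary(schema)
    if violations:
        raise DictionaryError(violations)
    return schema


def serialize_dictionary(schema: SchemaDefinition, path: str | Path) -> Path:
    """Write a schema back to YAML such that ``load_dictionary`` round-trips it."""
    path = Path(path)
    doc = schema.model_dump(mode="json", exclude_defaults=True)
    doc.setdefault("schema_id", schema.schema_id)
    doc.setdefault("variables", [])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
    return path


def resolve_code(vdef: VariableDefinition, internal_code: str) -> OntologyCoding:
    """Look up the ontology coding bound to a raw internal code.

    Total over the value set; an unknown code raises
    ``UnmappedValueError`` naming the variable and the offending code.
    """
    if vdef.datatype != "code":
        raise ValueError(f"variable {vdef.name!r} is not coded")
    for entry in vdef.value_set:
        if entry.internal_code == internal_code:
            return entry.coding
    raise UnmappedValueError(vdef.name, internal_code)


def demo_schema_path() -> Path:
    """Path of the demo dictionary shipped with the package."""
    return Path(__file__).parent / "data" / "demo_schema.yaml"


def load_demo_schema() -> SchemaDefinition:
    return load_dictionary(demo_schema_path())
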