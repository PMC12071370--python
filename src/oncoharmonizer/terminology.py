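"""Closed terminology registry.

Six terminology families are admitted: SNOMED CT for general clinical
concepts, ICD-O-3 for histology, LOINC for test observations, RxNorm for
medication, NCIT for concepts missing from the others, and the HL7/FHIR
code systems for status-like elements fixed by FHIR itself. Version
strings are carried as metadata only; no terminology server is consulted.
"""

from __future__ import annotations

# Canonical system URIs.
SNOMED_CT = "http://snomed.info/sct"
LOINC = "http://loinc.org"
RXNORM = "http://www.nlm.nih.gov/research/umls/rxnorm"
NCIT = "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl"
ICD_O_3 = "http://terminology.hl7.org/CodeSystem/icd-o-3"

# HL7/FHIR code systems are a family of URIs rather than a single one.
HL7_PREFIXES = (
    "http://hl7.org/fhir/",
    "http://terminology.hl7.org/CodeSystem/",
)

UCUM = "http://unitsofmeasure.org"

DATA_ABSENT_REASON = "http://terminology.hl7.org/CodeSystem/data-absent-reason"

#: family name -> exact URI (HL7 handled via prefixes)
REGISTRY: dict[str, str] = {
    "SNOMED CT": SNOMED_CT,
    "LOINC": LOINC,
    "RxNorm": RXNORM,
    "NCIT": NCIT,
    "ICD-O-3": ICD_O_3,
}

#: Terminology release versions used when the data model was authored,
#: recorded as provenance metadata only.
ONTOLOGY_VERSIONS: dict[str, str] = {
    "SNOMED CT": "International 2022-12-31",
    "ICD-O-3": "20220429",
    "LOINC": "2.73",
    "RxNorm": "2023-01-03",
    "NCIT": "23.8d",
}


def is_registered_system(uri: str) -> bool:
    """True iff *uri* belongs to one of the six admitted terminology families."""
    if uri in REGISTRY.values():
        return True
    return any(uri.startswith(p) for p in HL7_PREFIXES)


def is_snomed(uri: str) -> bool:
    return uri == SNOMED_CT


# SNOMED compositional grammar punctuation; any of these marks a
# post-coordinated expression rather than a plain concept id.
_POSTCOORDINATION_CHARS = ":+=|({"


def is_postcoordinated(code: str) -> bool:
    """Heuristic: does *code* look like a SNOMED compositional-grammar expression?"""
    return any(ch in code for ch in _POSTCOORDINATION_CHARS)
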