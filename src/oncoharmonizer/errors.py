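"""Exception hierarchy for the harmonization pipeline.

Ingestion is lenient (bad cells become QC findings); the ETL stage is
strict (bad cells abort the bundle build). The split is reflected here:
parse-time problems that must stop the run are fatal errors, everything
else surfaces as data.
"""


class OncoharmonizerError(Exception):
    """Base class for all package errors."""


class DictionaryError(OncoharmonizerError):
    """A data dictionary failed validation. Carries every violation found."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "dictionary validation failed with %d violation(s):\n%s"
            % (len(self.violations), "\n".join("  - " + v for v in self.violations))
        )


class UnmappedValueError(OncoharmonizerError):
    """A raw categorical code has no entry in the variable's value set."""

    def __init__(self, variable: str, code: str):
        self.variable = variable
        self.code = code
        super().__init__(f"variable {variable!r}: internal code {code!r} not in value set")


class CsvFormatError(OncoharmonizerError):
    """The CSV file violates the expected export dialect (e.g. no identifier column)."""


class IntegrityError(OncoharmonizerError):
    """Cross-row integrity breach, e.g. duplicated patient identifiers."""


class ConfigurationError(OncoharmonizerError):
    """Invalid run configuration (weights not summing to 100, missing weight, ...)."""


class BuildError(OncoharmonizerError):
    """A FHIR resource could not be populated without violating its structure."""

    def __init__(self, element_path: str, message: str):
        self.element_path = element_path
        super().__init__(f"{element_path}: {message}")


class InjectionError(OncoharmonizerError):
    """A defect-injection request exceeds the number of eligible cells."""
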