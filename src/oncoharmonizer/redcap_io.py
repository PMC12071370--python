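"""CSV interchange in the REDCap raw-export dialect.

One row per patient, first row header, comma-delimited, UTF-8,
double-quote quoting. Categorical cells hold the raw internal codes of
the capture form (never labels); the empty string is the only missing
marker. Ingestion is deliberately lenient: a cell that fails to parse
under its declared datatype is retained with its raw text and a logged
parse note — it surfaces later as a datatype-conformance QC failure
rather than an ingest crash.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .dictionary_model import SchemaDefinition, VariableDefinition
from .errors import CsvFormatError, IntegrityError
from .pseudonymization import TimeInterval

logger = logging.getLogger(__name__)

_INT_RE = re.compile(r"^[+-]?\d+$")
_DEC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_INTERVAL_RE = re.compile(r"^(\d+)\s+(days|weeks|months)$")
_BOOL_MAP = {"0": False, "1": True, "false": False, "true": True}


@dataclass(frozen=True)
class CellValue:
    """One cell: the raw on-disk text plus its typed parse (None = missing/unparseable)."""

    raw: str
    parsed: object = None

    @property
    def is_missing(self) -> bool:
        return self.raw == ""


def parse_typed(raw: str, datatype: str) -> Optional[object]:
    """Parse *raw* under the declared datatype; None when it does not conform."""
    if raw == "":
        return None
    if datatype == "code" or datatype == "string":
        return raw
    if datatype == "integer":
        return int(raw) if _INT_RE.match(raw) else None
    if datatype == "decimal":
        return float(raw) if _DEC_RE.match(raw) else None
    if datatype == "interval":
        m = _INTERVAL_RE.match(raw)
        return TimeInterval(int(m.group(1)), m.group(2)) if m else None
    if datatype == "boolean":
        return _BOOL_MAP.get(raw.lower())
    raise ValueError(f"unknown datatype {datatype!r}")


def make_cell(raw: str, vdef: VariableDefinition) -> CellValue:
    return CellValue(raw=raw, parsed=parse_typed(raw, vdef.datatype))


@dataclass
class PatientRecord:
    """One harmonized row: hashed patient id plus variable -> cell mapping."""

    patient_id: str
    schema_id: str
    cells: dict[str, CellValue] = field(default_factory=dict)

    def cell(self, name: str) -> CellValue:
        return self.cells.get(name, CellValue(raw=""))


def _header(schema: SchemaDefinition) -> list[str]:
    """Identifier column first, then the remaining variables in schema order."""
    id_name = schema.identifier_variable.name
    return [id_name] + [v.name for v in schema.variables if v.name != id_name]


def parse_export(path: str | Path, schema: SchemaDefinition) -> list[PatientRecord]:
    """Parse a REDCap-style export CSV into patient records, in file order.

    Fatal errors: missing identifier column (``CsvFormatError``) and
    duplicated patient identifiers (``IntegrityError`` listing them).
    Cell-level problems are never fatal (see module docstring).
    """
    path = Path(path)
    id_name = schema.identifier_variable.name
    known = {v.name: v for v in schema.variables}
    records: list[PatientRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError(f"{path}: empty file, header row required") from None
        if id_name not in header:
            raise CsvFormatError(f"{path}: identifier column {id_name!r} missing from header")
        unknown = [c for c in header if c not in known]
        if unknown:
            logger.warning("%s: ignoring %d column(s) not in schema: %s", path, len(unknown), unknown)
        for row_no, row in enumerate(reader, start=2):
            row_map = dict(zip(header, row))
            pid = row_map.get(id_name, "")
            cells: dict[str, CellValue] = {}
            for col, raw in row_map.items():
                vdef = known.get(col)
                if vdef is None or vdef.identifier:
                    continue
                cell = make_cell(raw, vdef)
                if raw != "" and cell.parsed is None:
                    logger.info(
                        "%s row %d, column %r: value %r does not parse as %s",
                        path, row_no, col, raw, vdef.datatype,
                    )
                cells[col] = cell
            records.append(PatientRecord(patient_id=pid, schema_id=schema.schema_id, cells=cells))
    seen: dict[str, int] = {}
    for r in records:
        seen[r.patient_id] = seen.get(r.patient_id, 0) + 1
    dups = sorted(pid for pid, k in seen.items() if k > 1)
    if dups:
        raise IntegrityError(f"{path}: duplicate patient identifiers: {dups}")
    return records


def write_import_csv(
    records: list[PatientRecord], schema: SchemaDefinition, path: str | Path
) -> Path:
    """Serialize records to the REDCap import dialect; inverse of ``parse_export``."""
    path = Path(path)
    mixed = {r.schema_id for r in records} - {schema.schema_id}
    if mixed:
        raise IntegrityError(f"records from foreign schema(s) {sorted(mixed)}")
    header = _header(schema)
    id_name = header[0]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(header)
        for r in records:
            writer.writerow(
                [r.patient_id] + [r.cell(name).raw for name in header[1:]]
            )
    return path
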