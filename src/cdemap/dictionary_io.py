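"""Reading and writing clinical data dictionaries and mapping files.

Three built-in schema profiles cover the dictionary layouts of the major
Alzheimer's-research data resources: NACC-style (``Form`` / ``Short
descriptor``), ADNI-style (``Phase``/``FLDNAME``/``TBLNAME``/``CRFNAME``/
``TEXT``/``TYPE``/``CODE``/``UNITS``) and NIH-CDE-style (``Name`` /
``Question Texts``).  Every dictionary, whatever its layout, is read into a
flat list of :class:`DataElement` records so that the rest of the pipeline
is schema-agnostic.  A custom profile can be loaded from a small JSON file
mapping canonical field names to CSV headers.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "ValueType",
    "DataElement",
    "SchemaProfile",
    "RejectedRow",
    "ReadResult",
    "SchemaError",
    "DuplicateElementError",
    "BUILTIN_PROFILES",
    "get_profile",
    "make_element_id",
    "read_dictionary",
    "read_dictionary_frame",
    "write_mappings",
    "read_mappings",
    "write_rejects",
    "load_form_name_lookup",
]


class Source(str, Enum):
    NACC = "NACC"
    ADNI = "ADNI"
    CDE = "CDE"
    SYNTH = "SYNTH"


class ValueType(str, Enum):
    NUMERICAL = "numerical"
    CATEGORICAL = "categorical"
    DATE = "date"
    TEXT = "text"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """A CSV file does not provide the columns a profile maps."""


class DuplicateElementError(ValueError):
    """Two rows produced the same element_id."""


@dataclass(frozen=True)
class DataElement:
    """One entry of a data dictionary.

    ``form_name`` holds the form/CRF/CDE-name context and ``descriptor`` the
    question or short description; their concatenation is the text that the
    similarity backends score.
    """

    element_id: str
    source: Source
    form_name: str = ""
    descriptor: str = ""
    field_name: Optional[str] = None
    table_name: Optional[str] = None
    phase: Optional[str] = None
    value_type: ValueType = ValueType.UNKNOWN
    unit: Optional[str] = None
    value_codes: Optional[str] = None

    @property
    def combined_text(self) -> str:
        """Form/CRF name and descriptor joined; this is the text scored for mapping."""
        return f"{self.form_name} {self.descriptor}".strip()

    def with_form_name(self, form_name: str) -> "DataElement":
        return replace(self, form_name=form_name)


@dataclass(frozen=True)
class SchemaProfile:
    """How one dictionary layout maps onto the canonical element fields.

    ``column_map`` maps canonical field names (``form_name``, ``descriptor``,
    ``field_name``, ``table_name``, ``phase``, ``value_type``, ``unit``,
    ``value_codes``) to CSV headers; canonical fields a layout does not carry
    are simply absent.  ``value_type_codes`` translates the layout's raw type
    codes (e.g. ADNI's ``N``) to :class:`ValueType`.
    """

    profile_name: str
    source: Source
    column_map: dict[str, str]
    value_type_codes: dict[str, ValueType] = field(default_factory=dict)

    CANONICAL_FIELDS = (
        "form_name",
        "descriptor",
        "field_name",
        "table_name",
        "phase",
        "value_type",
        "unit",
        "value_codes",
    )

    def __post_init__(self) -> None:
        unknown = set(self.column_map) - set(self.CANONICAL_FIELDS)
        if unknown:
            raise SchemaError(f"unknown canonical fields in column_map: {sorted(unknown)}")
        headers = list(self.column_map.values())
        if len(headers) != len(set(headers)):
            raise SchemaError("two canonical fields map to the same CSV column")

    @classmethod
    def from_json(cls, path: str | Path) -> "SchemaProfile":
        spec = json.loads(Path(path).read_text())
        codes = {k: ValueType(v) for k, v in spec.get("value_type_codes", {}).items()}
        return cls(
            profile_name=spec["profile_name"],
            source=Source(spec.get("source", "SYNTH")),
            column_map=spec["column_map"],
            value_type_codes=codes,
        )


_ADNI_TYPE_CODES = {
    "N": ValueType.NUMERICAL,
    "T": ValueType.TEXT,
    "D": ValueType.DATE,
    "S": ValueType.TEXT,
}

NACC_PROFILE = SchemaProfile(
    profile_name="nacc",
    source=Source.NACC,
    column_map={
        "form_name": "Form",
        "descriptor": "Short descriptor",
        "value_codes": "Value codes",
        "unit": "Unit",
    },
)

ADNI_PROFILE = SchemaProfile(
    profile_name="adni",
    source=Source.ADNI,
    column_map={
        "phase": "Phase",
        "field_name": "FLDNAME",
        "table_name": "TBLNAME",
        "form_name": "CRFNAME",
        "descriptor": "TEXT",
        "value_type": "TYPE",
        "value_codes": "CODE",
        "unit": "UNITS",
    },
    value_type_codes=_ADNI_TYPE_CODES,
)

CDE_PROFILE = SchemaProfile(
    profile_name="cde",
    source=Source.CDE,
    column_map={
        "form_name": "Name",
        "descriptor": "Question Texts",
        "value_codes": "Permissible values",
        "unit": "Unit",
    },
)

# synthetic dictionaries reuse the NACC/ADNI layouts but are their own source,
# so element ids match the generator's planted-truth table
SYNTH_NACC_PROFILE = SchemaProfile(
    profile_name="synth-nacc",
    source=Source.SYNTH,
    column_map=dict(NACC_PROFILE.column_map),
)
SYNTH_ADNI_PROFILE = SchemaProfile(
    profile_name="synth-adni",
    source=Source.SYNTH,
    column_map=dict(ADNI_PROFILE.column_map),
    value_type_codes=dict(_ADNI_TYPE_CODES),
)

BUILTIN_PROFILES: dict[str, SchemaProfile] = {
    "nacc": NACC_PROFILE,
    "adni": ADNI_PROFILE,
    "cde": CDE_PROFILE,
    "synth-nacc": SYNTH_NACC_PROFILE,
    "synth-adni": SYNTH_ADNI_PROFILE,
}


def get_profile(name: str) -> SchemaProfile:
    try:
        return BUILTIN_PROFILES[name.lower()]
    except KeyError:
        raise SchemaError(
            f"unknown profile {name!r}; built-ins are {sorted(BUILTIN_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class RejectedRow:
    row_index: int  # 1-based data-row index
    reason: str
    raw: dict


@dataclass
class ReadResult:
    elements: list[DataElement]
    rejects: list[RejectedRow]

    def __len__(self) -> int:
        return len(self.elements)


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def _slug(text: str) -> str:
    return _SLUG_RE.sub("-", text.lower()).strip("-") or "form"


def make_element_id(
    source: Source,
    form_name: str,
    row_index: int,
    field_name: Optional[str] = None,
    table_name: Optional[str] = None,
    phase: Optional[str] = None,
) -> str:
    """Deterministic element identifier.

    ``<source>:<table or form slug>:<field name or r####>`` with an
    ``@<phase>`` suffix when the row carries a study-phase label, so that the
    same variable collected in several phases stays unique until
    deduplication collapses it.
    """
    middle = table_name if table_name else _slug(form_name)
    tail = field_name if field_name else f"r{row_index:04d}"
    eid = f"{source.value}:{middle}:{tail}"
    if phase:
        eid += f"@{phase}"
    return eid


def read_dictionary_frame(
    df: pd.DataFrame,
    profile: SchemaProfile,
    source: Optional[Source] = None,
) -> ReadResult:
    """Turn an already-parsed CSV table into elements plus rejects.

    Rows are never silently dropped: every data row ends up either in
    ``elements`` or in ``rejects`` with a reason.
    """
    src = source or profile.source
    missing = [c for c in profile.column_map.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"profile {profile.profile_name!r} expects missing column(s): {missing}"
        )
    if df.empty:
        logger.warning("dictionary file has a header but no data rows")
        return ReadResult([], [])

    def cell(row: dict, canonical: str) -> str:
        col = profile.column_map.get(canonical)
        if col is None:
            return ""
        val = row.get(col, "")
        return str(val).strip() if val is not None else ""

    elements: list[DataElement] = []
    rejects: list[RejectedRow] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        form = cell(row, "form_name")
        desc = cell(row, "descriptor")
        if not form and not desc:
            rejects.append(RejectedRow(i, "form_name and descriptor both empty", row))
            continue
        raw_type = cell(row, "value_type")
        vtype = profile.value_type_codes.get(raw_type.upper(), ValueType.UNKNOWN)
        field_name = cell(row, "field_name") or None
        table_name = cell(row, "table_name") or None
        phase = cell(row, "phase") or None
        eid = make_element_id(src, form, i, field_name, table_name, phase)
        if eid in seen:
            raise DuplicateElementError(f"duplicate element_id {eid!r} at data row {i}")
        seen.add(eid)
        elements.append(
            DataElement(
                element_id=eid,
                source=src,
                form_name=form,
                descriptor=desc,
                field_name=field_name,
                table_name=table_name,
                phase=phase,
                value_type=vtype,
                unit=cell(row, "unit") or None,
                value_codes=cell(row, "value_codes") or None,
            )
        )
    return ReadResult(elements, rejects)


def read_dictionary(
    path: str | Path,
    profile: SchemaProfile,
    source: Optional[Source] = None,
    delimiter: str = ",",
) -> ReadResult:
    """Read a CSV data dictionary under the given schema profile."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    return read_dictionary_frame(df, profile, source=source)


# ---------------------------------------------------------------------------
# Mapping and audit files

_MAPPING_COLUMNS = [
    "source_id",
    "target_id",
    "method",
    "score",
    "valid_flag",
    "type_verdict",
    "unit_verdict",
    "value_list_verdict",
]


def write_mappings(mappings: list, path: str | Path, delimiter: str = ",") -> None:
    """Write mapping candidates (optionally audited) as CSV.

    Round-trips losslessly through :func:`read_mappings`; scores are written
    with full float precision.
    """
    rows = []
    for m in mappings:
        audit = getattr(m, "audit", None)
        rows.append(
            {
                "source_id": m.source_id,
                "target_id": m.target_id,
                "method": m.method,
                "score": repr(float(m.score)),
                "valid_flag": m.valid_flag.value,
                "type_verdict": audit.type_verdict.value if audit else "",
                "unit_verdict": (audit.unit_verdict.value if audit and audit.unit_verdict else "")
                if audit
                else "",
                "value_list_verdict": (
                    audit.value_list_verdict.value if audit and audit.value_list_verdict else ""
                )
                if audit
                else "",
            }
        )
    df = pd.DataFrame(rows, columns=_MAPPING_COLUMNS)
    df.to_csv(path, index=False, sep=delimiter)


def read_mappings(path: str | Path, delimiter: str = ",") -> list:
    """Read a mapping CSV written by :func:`write_mappings`."""
    from .mapping import MappingCandidate, ReviewStatus
    from .value_consistency import TypeVerdict, UnitVerdict, ValueAudit, ValueListVerdict

    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    missing = [c for c in _MAPPING_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SchemaError(f"mapping file lacks column(s): {missing}")
    out = []
    for row in df.to_dict("records"):
        audit = None
        if row.get("type_verdict"):
            audit = ValueAudit(
                type_verdict=TypeVerdict(row["type_verdict"]),
                unit_verdict=UnitVerdict(row["unit_verdict"]) if row.get("unit_verdict") else None,
                value_list_verdict=ValueListVerdict(row["value_list_verdict"])
                if row.get("value_list_verdict")
                else None,
            )
        out.append(
            MappingCandidate(
                source_id=row["source_id"],
                target_id=row["target_id"],
                method=row["method"],
                score=float(row["score"]),
                valid_flag=ReviewStatus(row["valid_flag"]),
                audit=audit,
            )
        )
    return out


def write_rejects(rejects: list[RejectedRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"row_index": r.row_index, "reason": r.reason} for r in rejects],
        columns=["row_index", "reason"],
    )
    df.to_csv(path, index=False)


def load_form_name_lookup(path: str | Path) -> dict[str, str]:
    """Load a 2-column (short,full) form-name table; keys are lowercased."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError("form-name lookup needs two columns: short,full")
    short_col, full_col = df.columns[:2]
    return {
        str(s).strip().lower(): str(f).strip()
        for s, f in zip(df[short_col], df[full_col])
        if str(s).strip()
    }
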