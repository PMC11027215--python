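"""Value-domain auditing of valid mappings.

Two elements that denote the same variable may still disagree on how the
value is recorded.  For each valid mapping the audit reports: whether the
two inferred value types (numerical / categorical / date / text) are
identical or disparate; for numerical pairs, whether the units agree
(identical / disparate / not available when either side lacks a unit);
and for categorical pairs, whether the permissible-value lists agree
(identical / partially identical / disparate).

Comparisons are deliberately conservative and literal: "cc" vs "mm3" is
disparate even though the quantities are convertible, and value labels are
matched case-insensitively with no synonym expansion.  Codes ("1=Yes") are
ignored when comparing value lists — only the labels carry meaning across
resources, since one resource may code its responses and another may not.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .dictionary_io import DataElement, ValueType

logger = logging.getLogger(__name__)

__all__ = [
    "PermissibleValue",
    "TypeVerdict",
    "UnitVerdict",
    "ValueListVerdict",
    "ValueAudit",
    "infer_value_type",
    "parse_value_list",
    "compare_value_types",
    "compare_units",
    "compare_value_lists",
    "audit_pair",
]


class TypeVerdict(str, Enum):
    IDENTICAL = "identical"
    DISPARATE = "disparate"


class UnitVerdict(str, Enum):
    IDENTICAL = "identical"
    DISPARATE = "disparate"
    NOT_AVAILABLE = "not_available"


class ValueListVerdict(str, Enum):
    IDENTICAL = "identical"
    PARTIALLY_IDENTICAL = "partially_identical"
    DISPARATE = "disparate"


@dataclass(frozen=True)
class PermissibleValue:
    """One allowable response: an optional code plus a label ("1=Yes")."""

    label: str
    code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.label.strip():
            raise ValueError("permissible value label must be non-empty")


@dataclass(frozen=True)
class ValueAudit:
    """Consistency verdicts for one valid mapping.

    ``unit_verdict`` is present iff both elements are numerical (and types
    agree); ``value_list_verdict`` iff both are categorical.  Date and text
    pairs carry the type verdict only.
    """

    type_verdict: TypeVerdict
    unit_verdict: Optional[UnitVerdict] = None
    value_list_verdict: Optional[ValueListVerdict] = None


_DATE_HINT_RE = re.compile(r"\b(date|mm/dd|dd/mm|yyyy)\b", re.IGNORECASE)


def infer_value_type(e: DataElement) -> ValueType:
    """Infer the value type of an element.

    A profile-supplied type code wins, with one refinement: a nominally
    numerical element whose code string enumerates responses ("1=Present -
    1 point; 0=Absent") is categorical — the number is a code, not a
    measurement.  Without a type code: a code list means categorical,
    date-format hints mean date, a unit means numerical, and any other
    described element is free text.
    """
    has_codes = bool(e.value_codes and parse_value_list(e.value_codes))
    if e.value_type is not ValueType.UNKNOWN:
        if e.value_type is ValueType.NUMERICAL and has_codes:
            return ValueType.CATEGORICAL
        return e.value_type
    if has_codes:
        return ValueType.CATEGORICAL
    if _DATE_HINT_RE.search(e.descriptor):
        return ValueType.DATE
    if e.unit:
        return ValueType.NUMERICAL
    if e.descriptor or e.form_name:
        return ValueType.TEXT
    return ValueType.UNKNOWN


def parse_value_list(raw: str) -> list[PermissibleValue]:
    """Parse a "1=Yes; 0=No" style code string.

    Parts are split on ";", each on its *first* "=" (labels may contain
    further "="); parts without "=" are label-only values.
    """
    values: list[PermissibleValue] = []
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            code, label = part.split("=", 1)
            code, label = code.strip(), label.strip()
            if label:
                values.append(PermissibleValue(label=label, code=code or None))
            elif code:
                values.append(PermissibleValue(label=code))
        else:
            values.append(PermissibleValue(label=part))
    return values


def compare_value_types(a: DataElement, b: DataElement) -> TypeVerdict:
    """Identical iff the inferred types are equal; unknown never matches."""
    ta, tb = infer_value_type(a), infer_value_type(b)
    if ta is ValueType.UNKNOWN or tb is ValueType.UNKNOWN:
        return TypeVerdict.DISPARATE
    return TypeVerdict.IDENTICAL if ta is tb else TypeVerdict.DISPARATE


def compare_units(a: DataElement, b: DataElement) -> UnitVerdict:
    """Unit agreement for a numerical pair.

    Missing unit on either side → not available; otherwise case-insensitive,
    whitespace-stripped string equality (no unit conversion: "cc" and "mm3"
    are disparate even though convertible).
    """
    ua = (a.unit or "").strip()
    ub = (b.unit or "").strip()
    if not ua or not ub:
        return UnitVerdict.NOT_AVAILABLE
    return UnitVerdict.IDENTICAL if ua.lower() == ub.lower() else UnitVerdict.DISPARATE


def compare_value_lists(
    a: list[PermissibleValue],
    b: list[PermissibleValue],
) -> ValueListVerdict:
    """Label-set agreement for a categorical pair.

    Codes are ignored; labels are compared case-insensitively as sets.
    Equal sets → identical; overlapping but unequal → partially identical;
    disjoint → disparate.  An empty list on either side is disparate (with
    a warning): nothing can be matched.
    """
    la = {v.label.strip().lower() for v in a}
    lb = {v.label.strip().lower() for v in b}
    if not la or not lb:
        logger.warning("empty permissible-value list in comparison")
        return ValueListVerdict.DISPARATE
    if la == lb:
        return ValueListVerdict.IDENTICAL
    if la & lb:
        return ValueListVerdict.PARTIALLY_IDENTICAL
    return ValueListVerdict.DISPARATE


def audit_pair(a: DataElement, b: DataElement) -> ValueAudit:
    """Full value-consistency audit of one mapped pair."""
    type_verdict = compare_value_types(a, b)
    if type_verdict is not TypeVerdict.IDENTICAL:
        return ValueAudit(type_verdict=type_verdict)
    vtype = infer_value_type(a)
    if vtype is ValueType.NUMERICAL:
        return ValueAudit(type_verdict=type_verdict, unit_verdict=compare_units(a, b))
    if vtype is ValueType.CATEGORICAL:
        verdict = compare_value_lists(
            parse_value_list(a.value_codes or ""),
            parse_value_list(b.value_codes or ""),
        )
        return ValueAudit(type_verdict=type_verdict, value_list_verdict=verdict)
    return ValueAudit(type_verdict=type_verdict)
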