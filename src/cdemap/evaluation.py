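"""Evaluation of adjudicated mapping runs.

Computes per-method valid/invalid contingency tables, precision and recall
against the aggregated valid set, mapping rates (the fraction of a
resource's preprocessed elements that acquired at least one valid mapping),
and the seven-region decomposition behind a three-method Venn diagram.

Recall is measured against the union of valid mappings found by any
method — there is no independent gold standard — so reported recall is an
upper bound: mappings missed by every method are invisible to it.
Percentages are rounded half-up to two decimals, matching how such tables
are conventionally printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .mapping import MappingCandidate, ReviewStatus

logger = logging.getLogger(__name__)

__all__ = [
    "MethodTable",
    "round_half_up",
    "method_table",
    "precision_recall",
    "mapping_rate",
    "overlap_counts",
    "compare_to_truth",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (so 2.255 → 2.26, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MethodTable:
    """Valid/invalid counts and percentages for one adjudicated run."""

    total: int
    valid: int
    invalid: int
    valid_pct: Optional[float]
    invalid_pct: Optional[float]

    def render(self) -> str:
        if self.total == 0:
            return "0 mappings (percentages undefined: —)"
        return (
            f"{self.valid} ({self.valid_pct:.2f}%) valid, "
            f"{self.invalid} ({self.invalid_pct:.2f}%) invalid, "
            f"{self.total} total"
        )


def method_table(candidates: list[MappingCandidate]) -> MethodTable:
    """Count valid/invalid mappings of one fully adjudicated run.

    An unreviewed candidate is a hard error: the table is only meaningful
    after expert review.
    """
    for c in candidates:
        if c.valid_flag is ReviewStatus.UNREVIEWED:
            raise ValueError(
                f"candidate ({c.source_id} -> {c.target_id}) is unreviewed"
            )
    total = len(candidates)
    valid = sum(1 for c in candidates if c.valid_flag is ReviewStatus.VALID)
    invalid = total - valid
    if total == 0:
        logger.warning("empty mapping run: percentages are undefined")
        return MethodTable(0, 0, 0, None, None)
    return MethodTable(
        total=total,
        valid=valid,
        invalid=invalid,
        valid_pct=round_half_up(100.0 * valid / total),
        invalid_pct=round_half_up(100.0 * invalid / total),
    )


def precision_recall(
    method_valid: int,
    method_total: int,
    aggregated_valid: int,
) -> tuple[Optional[float], Optional[float]]:
    """Precision = valid/total of the method; recall = valid/union-valid."""
    if method_valid > method_total:
        raise ValueError("method_valid cannot exceed method_total")
    if method_valid > aggregated_valid:
        raise ValueError("method_valid cannot exceed aggregated_valid")
    precision = method_valid / method_total if method_total else None
    recall = method_valid / aggregated_valid if aggregated_valid else None
    if precision is None or recall is None:
        logger.warning("zero denominator: precision/recall undefined")
    return precision, recall


def mapping_rate(mapped_sources: int, total_sources: int) -> float:
    """Percentage of source elements mapped, half-up to two decimals."""
    if total_sources <= 0:
        raise ValueError("total_sources must be positive")
    if mapped_sources > total_sources:
        raise ValueError("mapped_sources cannot exceed total_sources")
    return round_half_up(100.0 * mapped_sources / total_sources)


def overlap_counts(
    run_a: Iterable[tuple[str, str]],
    run_b: Iterable[tuple[str, str]],
    run_c: Iterable[tuple[str, str]],
) -> dict[str, int]:
    """Exclusive sizes of the seven regions of a three-set Venn diagram.

    Inputs are sets of (source_id, target_id) keys; the region sizes sum to
    the size of the three-way union.
    """
    a, b, c = set(run_a), set(run_b), set(run_c)
    return {
        "only_a": len(a - b - c),
        "only_b": len(b - a - c),
        "only_c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def compare_to_truth(
    mappings: list[MappingCandidate],
    truth_pairs: Iterable[tuple[str, str]],
) -> dict[str, float | int]:
    """Precision/recall of a mapping run against planted ground truth.

    Used with the synthetic-data generator, whose correspondence table gives
    the gold pairs that a real study would obtain from expert review.
    """
    truth = set(truth_pairs)
    found = {m.key for m in mappings}
    hits = len(found & truth)
    return {
        "n_truth": len(truth),
        "n_mapped": len(found),
        "n_recovered": hits,
        "precision": hits / len(found) if found else 0.0,
        "recall": hits / len(truth) if truth else 0.0,
    }
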