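"""Cross-dictionary element mapping.

Every source element is scored against every target on the normalized
combined form-name + descriptor text; pairs scoring strictly above the
threshold (default 0.6) are retained, and of those each source keeps only
its highest-scoring target.  Results from several methods are aggregated by
union on the (source, target) pair.  Candidate mappings are emitted
unreviewed; an external adjudication file flips them to valid/invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Protocol

from .dictionary_io import DataElement
from .preprocess import DEFAULT_CONFIG, NormalizationConfig, prepare_element_text
from .similarity import (
    EmbeddingStore,
    SimilarityScore,
    TokenBag,
    cosine_similarity,
    to_token_bag,
    wmd_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReviewStatus",
    "MappingCandidate",
    "Scorer",
    "BowScorer",
    "WmdScorer",
    "map_elements",
    "aggregate_mappings",
    "merge_adjudications",
]


class ReviewStatus(str, Enum):
    UNREVIEWED = "unreviewed"
    VALID = "valid"
    INVALID = "invalid"


@dataclass(frozen=True)
class MappingCandidate:
    """A scored source→target pair with method provenance and review status."""

    source_id: str
    target_id: str
    method: str
    score: float
    valid_flag: ReviewStatus = ReviewStatus.UNREVIEWED
    audit: Optional[object] = None  # ValueAudit once audited

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_id, self.target_id)


class Scorer(Protocol):
    method: str

    def score(self, a: TokenBag, b: TokenBag) -> SimilarityScore: ...


class BowScorer:
    """Term-frequency bag-of-words cosine backend."""

    method = "bow_cosine"

    def score(self, a: TokenBag, b: TokenBag) -> SimilarityScore:
        return cosine_similarity(a, b)


class WmdScorer:
    """Word Mover's Distance backend over a given embedding store.

    ``method`` labels the provenance of the embeddings (e.g. "wmd_word2vec",
    "wmd_biowordvec") in the mapping output.
    """

    def __init__(self, store: EmbeddingStore, method: str = "wmd") -> None:
        self.store = store
        self.method = method

    def score(self, a: TokenBag, b: TokenBag) -> SimilarityScore:
        return wmd_similarity(a, b, self.store, method=self.method)


def map_elements(
    sources: list[DataElement],
    targets: list[DataElement],
    scorer: Scorer,
    threshold: float = 0.6,
    config: NormalizationConfig = DEFAULT_CONFIG,
    split_concatenated: bool = True,
) -> list[MappingCandidate]:
    """Thresholded best-match mapping from sources into targets.

    Only pairs scoring strictly above ``threshold`` survive, and each source
    keeps a single best target (ties break to the lexicographically smallest
    target_id, with a warning).  A scorer failure on one pair skips that
    pair; it never aborts the run.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    if not targets:
        return []
    target_bags = [
        (t, to_token_bag(prepare_element_text(t, config, split_concatenated)))
        for t in targets
    ]
    out: list[MappingCandidate] = []
    for s in sources:
        bag_s = to_token_bag(prepare_element_text(s, config, split_concatenated))
        best: Optional[tuple[float, str]] = None
        tied = False
        for t, bag_t in target_bags:
            try:
                score = scorer.score(bag_s, bag_t)
            except Exception:
                logger.exception(
                    "scorer failed on pair (%s, %s); pair skipped",
                    s.element_id,
                    t.element_id,
                )
                continue
            if score.value <= threshold:
                continue
            cand = (score.value, t.element_id)
            if best is None or cand[0] > best[0]:
                best, tied = cand, False
            elif cand[0] == best[0]:
                tied = True
                if cand[1] < best[1]:
                    best = cand
        if best is not None:
            if tied:
                logger.warning(
                    "score tie for source %s resolved to smallest target_id %s",
                    s.element_id,
                    best[1],
                )
            out.append(
                MappingCandidate(
                    source_id=s.element_id,
                    target_id=best[1],
                    method=scorer.method,
                    score=best[0],
                )
            )
    return out


def _merge_methods(*methods: str) -> str:
    parts = sorted({p for m in methods for p in m.split("+") if p})
    return "+".join(parts)


def _merge_flags(a: ReviewStatus, b: ReviewStatus) -> ReviewStatus:
    for status in (ReviewStatus.VALID, ReviewStatus.INVALID):
        if status in (a, b):
            return status
    return ReviewStatus.UNREVIEWED


def aggregate_mappings(runs: list[list[MappingCandidate]]) -> list[MappingCandidate]:
    """Union of several method runs, keyed on (source_id, target_id).

    Method provenance is concatenated ("bow_cosine+wmd_biowordvec"), the
    best score is kept, and any non-unreviewed flag survives.  Aggregation
    is idempotent and independent of run order.
    """
    merged: dict[tuple[str, str], MappingCandidate] = {}
    for run in runs:
        for cand in run:
            prev = merged.get(cand.key)
            if prev is None:
                merged[cand.key] = cand
            else:
                merged[cand.key] = replace(
                    prev,
                    method=_merge_methods(prev.method, cand.method),
                    score=max(prev.score, cand.score),
                    valid_flag=_merge_flags(prev.valid_flag, cand.valid_flag),
                )
    return [merged[k] for k in sorted(merged)]


def merge_adjudications(
    candidates: list[MappingCandidate],
    reviews: dict[tuple[str, str], ReviewStatus],
) -> list[MappingCandidate]:
    """Apply an external expert-review table to candidate mappings.

    ``reviews`` maps (source_id, target_id) to valid/invalid.  Reviews for
    unknown pairs are reported with a warning; candidates without a review
    stay unreviewed.
    """
    known = {c.key for c in candidates}
    stray = sorted(set(reviews) - known)
    if stray:
        logger.warning("%d review(s) reference unknown pairs: %s", len(stray), stray[:5])
    return [
        replace(c, valid_flag=reviews[c.key]) if c.key in reviews else c
        for c in candidates
    ]
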