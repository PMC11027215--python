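"""Similarity backends: term-frequency cosine and Word Mover's Distance.

Two ways of scoring a pair of normalized element texts:

* **Bag-of-words cosine** — each text is a term-frequency vector over the
  union vocabulary; similarity is the cosine of the two vectors.  Counts
  matter: a word repeated on one side only ("Participant ... Participant")
  genuinely lowers the score.

* **Word Mover's Distance (WMD)** — each text is a normalized bag-of-words
  mass distribution (nBOW) over its in-vocabulary tokens; the distance is
  the minimum cost of transporting one distribution onto the other, where
  moving mass from word x to word y costs the Euclidean distance between
  their unit-length embedding vectors.  The transport problem is solved
  exactly as a linear program (HiGHS), never greedily.  WMD is turned into
  a bounded similarity via 1/(1 + distance).

Out-of-vocabulary tokens are dropped from the bags before WMD; a pair that
loses all its tokens on either side is incomparable and scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

__all__ = [
    "TokenBag",
    "EmbeddingStore",
    "SimilarityScore",
    "OOVError",
    "to_token_bag",
    "cosine_similarity",
    "wmd_distance",
    "wmd_similarity",
    "token_similarity",
]


class OOVError(KeyError):
    """A token (or a whole bag) has no vector in the embedding store."""


@dataclass(frozen=True)
class TokenBag:
    """Term-frequency representation of an already-normalized text."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.counts.items() if c < 1}
        if bad:
            raise ValueError(f"token counts must be >= 1, got {bad}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)


def to_token_bag(normalized_text: str) -> TokenBag:
    """Count whitespace-split tokens with multiplicity."""
    counts: dict[str, int] = {}
    for tok in normalized_text.split():
        counts[tok] = counts.get(tok, 0) + 1
    return TokenBag(counts)


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    method: str
    oov_dropped: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"similarity must lie in [0, 1], got {self.value}")


class EmbeddingStore:
    """Keyed word vectors of one fixed dimension.

    Lookup of a missing token raises :class:`OOVError` rather than returning
    a default vector.  ``unit_vector`` returns the L2-normalized vector used
    as the WMD ground space.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray], name: str = "") -> None:
        if not vectors:
            raise ValueError("embedding store must contain at least one vector")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"all vectors must share one 1-D shape, got {dims}")
        self._vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        self.dimension = next(iter(dims))[0]
        self.name = name

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self._vectors)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self._vectors[token]
        except KeyError:
            raise OOVError(f"token {token!r} is out of vocabulary") from None

    def unit_vector(self, token: str) -> np.ndarray:
        v = self.vector(token)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"token {token!r} has a zero vector")
        return v / norm

    @classmethod
    def load_text(cls, path: str | Path, name: str | None = None) -> "EmbeddingStore":
        """Load word-per-line text vectors ("token v1 ... vD").

        A leading word2vec-style header line with two integers (vocabulary
        size, dimension) is detected and skipped.
        """
        path = Path(path)
        vectors: dict[str, np.ndarray] = {}
        with path.open() as fh:
            lines = fh.read().splitlines()
        start = 0
        if lines:
            first = lines[0].split()
            if len(first) == 2 and all(p.lstrip("-").isdigit() for p in first):
                start = 1
        for line in lines[start:]:
            parts = line.split()
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors, name=name or path.name)

    def save_text(self, path: str | Path, header: bool = False) -> None:
        with Path(path).open("w") as fh:
            if header:
                fh.write(f"{len(self._vectors)} {self.dimension}\n")
            for token in sorted(self._vectors):
                coords = " ".join(repr(float(x)) for x in self._vectors[token])
                fh.write(f"{token} {coords}\n")


def cosine_similarity(a: TokenBag, b: TokenBag) -> SimilarityScore:
    """Cosine of the two term-frequency vectors on the union vocabulary."""
    if not a or not b:
        return SimilarityScore(0.0, "bow_cosine")
    vocab = sorted(set(a) | set(b))
    va = np.array([a.counts.get(t, 0) for t in vocab], dtype=float)
    vb = np.array([b.counts.get(t, 0) for t in vocab], dtype=float)
    value = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return SimilarityScore(min(value, 1.0), "bow_cosine")


def _nbow(bag: TokenBag, emb: EmbeddingStore) -> tuple[list[str], np.ndarray, int]:
    tokens = sorted(t for t in bag if t in emb)
    dropped = bag.total - sum(bag.counts[t] for t in tokens)
    if not tokens:
        return [], np.array([]), dropped
    w = np.array([bag.counts[t] for t in tokens], dtype=float)
    return tokens, w / w.sum(), dropped


def wmd_distance(a: TokenBag, b: TokenBag, emb: EmbeddingStore) -> float:
    """Exact optimal-transport cost between the two nBOW distributions.

    Ground cost is the Euclidean distance between unit-length word vectors,
    so single-token distances lie in [0, 2].  Raises :class:`OOVError` when
    either bag is empty after out-of-vocabulary removal.
    """
    toks_a, wa, _ = _nbow(a, emb)
    toks_b, wb, _ = _nbow(b, emb)
    if not toks_a or not toks_b:
        raise OOVError("a bag lost all tokens to out-of-vocabulary removal")
    xa = np.stack([emb.unit_vector(t) for t in toks_a])
    xb = np.stack([emb.unit_vector(t) for t in toks_b])
    cost = cdist(xa, xb, metric="euclidean")
    n, m = cost.shape
    # transport polytope: row sums wa, column sums wb
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    res = linprog(
        cost.ravel(),
        A_eq=a_eq,
        b_eq=np.concatenate([wa, wb]),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - degenerate only on bad input
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(float(res.fun), 0.0)


def wmd_similarity(
    a: TokenBag,
    b: TokenBag,
    emb: EmbeddingStore,
    method: str = "wmd",
) -> SimilarityScore:
    """Bounded WMD similarity 1/(1 + distance); fully-OOV pairs score 0."""
    _, _, dropped_a = _nbow(a, emb)
    _, _, dropped_b = _nbow(b, emb)
    dropped = dropped_a + dropped_b
    try:
        dist = wmd_distance(a, b, emb)
    except OOVError:
        return SimilarityScore(0.0, method, oov_dropped=dropped)
    return SimilarityScore(1.0 / (1.0 + dist), method, oov_dropped=dropped)


def token_similarity(x: str, y: str, emb: EmbeddingStore) -> float:
    """Cosine similarity of two word vectors; OOV tokens raise OOVError."""
    vx, vy = emb.vector(x), emb.vector(y)
    return float(vx @ vy / (np.linalg.norm(vx) * np.linalg.norm(vy)))
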