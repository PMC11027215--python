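"""Element-level cleanup and text normalization.

Four cleanup steps precede mapping: (1) phase deduplication — the same
variable collected in several study phases/visits is kept once; (2) removal
of ambiguous "other"/"specify" elements, which are always satellites of a
different question and would otherwise generate spurious matches; (3)
expansion of short form names ("b6") to full names through a lookup table;
(4) insertion of spaces into camel-case concatenations ("RightTemporalPole")
found in imaging variable texts.

Text normalization then lowercases, strips punctuation, drops enumerator
tokens (question numbers such as "1." or "16a"), removes stopwords and
lemmatizes with a noun-default rule table.  The stopword list and lemmatizer
tables are pinned data files shipped with the package so results are
reproducible offline.  Normalization is idempotent: applying it to its own
output changes nothing, which the test suite checks by property.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .dictionary_io import DataElement

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationConfig",
    "DEFAULT_CONFIG",
    "load_stopwords",
    "load_lemma_exceptions",
    "lemmatize_token",
    "dedup_elements",
    "filter_ambiguous",
    "expand_form_names",
    "split_concatenated_words",
    "normalize_text",
    "prepare_element_text",
]


@lru_cache(maxsize=1)
def load_stopwords() -> frozenset[str]:
    """The pinned English stopword list (one lowercase token per line)."""
    text = resources.files("cdemap.data").joinpath("stopwords_en.txt").read_text()
    return frozenset(tok for tok in text.split() if tok)


@lru_cache(maxsize=1)
def load_lemma_exceptions() -> dict[str, str]:
    """Irregular plural → singular table.

    Every value is also inserted as a key mapping to itself so that
    lemmatization is a projection (its output is a fixed point).
    """
    text = resources.files("cdemap.data").joinpath("lemma_exceptions.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        plural, singular = line.split("\t")
        table[plural.strip()] = singular.strip()
    for singular in list(table.values()):
        table.setdefault(singular, singular)
    return table


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the text normalizer.

    drop_enumerators removes pure question-number tokens (digits, optionally
    with a single trailing letter: "1", "16a").  It is on by default —
    CRF question texts are number-laden ("8. Do you often feel helpless?")
    while the corresponding descriptors in other resources are not, and
    leaving the numbers in systematically depresses similarity scores.
    """

    stopword_list: frozenset[str] = field(default_factory=load_stopwords)
    drop_enumerators: bool = True
    lemmatize: bool = True
    punctuation_set: str = string.punctuation

    def __post_init__(self) -> None:
        if not self.stopword_list:
            raise ValueError("stopword_list must be non-empty")


DEFAULT_CONFIG = NormalizationConfig()

_VOWELS = set("aeiou")
_ENUMERATOR_RE = re.compile(r"^\d+[a-z]?$")


def lemmatize_token(token: str, exceptions: dict[str, str] | None = None) -> str:
    """Noun-default lemmatization by exceptions table plus suffix rules.

    A compact rule-based singularizer: irregular forms come from the pinned
    exceptions table; regular forms are handled by ordered suffix rules with
    small guards (never touch -ss/-us/-is endings, vowel-before-suffix
    disambiguation for -ches).  The step is iterated until stable, so the
    output is always a fixed point (lemmatization is a projection).
    """
    exc = exceptions if exceptions is not None else load_lemma_exceptions()
    while True:
        out = _lemma_step(token, exc)
        if out == token:
            return out
        token = out


def _lemma_step(token: str, exc: dict[str, str]) -> str:
    if token in exc:
        return exc[token]
    n = len(token)
    if n < 3 or not token.endswith("s"):
        return token
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith("ies") and n >= 5:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("ches"):
        # watch+es, church+es vs ache+s, headache+s: consonant before the
        # suffix signals an -es plural of a -ch noun
        before = token[-5] if n >= 5 else ""
        if before and before not in _VOWELS:
            return token[:-2]
        return token[:-1]
    if token.endswith(("shes", "xes", "zzes", "oes")) and n >= 5:
        return token[:-2]
    if n >= 4:
        return token[:-1]
    return token


def _tokenize(text: str, config: NormalizationConfig) -> list[str]:
    table = str.maketrans({c: " " for c in config.punctuation_set})
    tokens = text.lower().translate(table).split()
    if config.drop_enumerators:
        tokens = [t for t in tokens if not _ENUMERATOR_RE.match(t)]
    tokens = [t for t in tokens if t not in config.stopword_list]
    if config.lemmatize:
        tokens = [lemmatize_token(t) for t in tokens]
        # a lemma may itself be a stopword ("dids" -> "did"); filter again so
        # normalization is a projection
        tokens = [t for t in tokens if t not in config.stopword_list]
    return tokens


def normalize_text(text: str, config: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """Lowercase, de-punctuate, drop enumerators and stopwords, lemmatize."""
    return " ".join(_tokenize(text, config))


_CAMEL_RE = re.compile(r"(?<=[a-z])(?=[A-Z])")


def split_concatenated_words(text: str) -> str:
    """Insert a space before an uppercase letter that follows a lowercase one.

    "RightTemporalPole" → "Right Temporal Pole"; all-uppercase acronyms
    ("MMSE") are left intact.
    """
    return _CAMEL_RE.sub(" ", text)


def prepare_element_text(
    element: DataElement,
    config: NormalizationConfig = DEFAULT_CONFIG,
    split_concatenated: bool = True,
) -> str:
    """The fully normalized combined form-name + descriptor text of an element."""
    text = element.combined_text
    if split_concatenated:
        text = split_concatenated_words(text)
    return normalize_text(text, config)


# ---------------------------------------------------------------------------
# Element-level steps


def dedup_elements(elements: list[DataElement]) -> list[DataElement]:
    """Collapse phase/visit duplicates of the same variable.

    The dedup key is (field_name, table_name, form_name, descriptor), all
    case-insensitive.  Phase, type/length metadata and the permissible-value
    string are deliberately excluded: re-releases of a form may reorder the
    code list without making the element a different variable.  The first
    occurrence (first in phase order for phase-sorted dictionaries) wins.
    """
    seen: set[tuple] = set()
    kept: list[DataElement] = []
    for e in elements:
        key = (
            (e.field_name or "").lower(),
            (e.table_name or "").lower(),
            e.form_name.lower(),
            e.descriptor.lower(),
        )
        if key in seen:
            continue
        seen.add(key)
        kept.append(e)
    return kept


_AMBIGUOUS_WORDS = ("other", "specify")


def filter_ambiguous(
    elements: list[DataElement],
    require_both: bool = False,
) -> tuple[list[DataElement], list[DataElement]]:
    """Split off ambiguous "other"/"specify" elements.

    Matching is whole-word and case-insensitive on the descriptor only, so
    "Mother's age" is kept.  By default either word triggers removal;
    ``require_both`` demands both.
    """
    patterns = [re.compile(rf"\b{w}\b", re.IGNORECASE) for w in _AMBIGUOUS_WORDS]
    kept: list[DataElement] = []
    removed: list[DataElement] = []
    for e in elements:
        hits = [bool(p.search(e.descriptor)) for p in patterns]
        ambiguous = all(hits) if require_both else any(hits)
        (removed if ambiguous else kept).append(e)
    return kept, removed


def expand_form_names(
    elements: list[DataElement],
    lookup: dict[str, str],
) -> list[DataElement]:
    """Replace short form names ("b6") by their full names via a lookup table.

    Form names missing from the table are left unchanged with a warning;
    expansion is idempotent because full names are not keys of the table.
    """
    out: list[DataElement] = []
    missing: set[str] = set()
    for e in elements:
        full = lookup.get(e.form_name.lower())
        if full is not None:
            out.append(e.with_form_name(full))
        else:
            if lookup and e.form_name:
                missing.add(e.form_name)
            out.append(e)
    if missing:
        logger.warning(
            "no full name found for %d form name(s), left unchanged: %s",
            len(missing),
            sorted(missing)[:10],
        )
    return out
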