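"""Synthetic paired dictionaries with planted correspondences.

Real dictionary downloads are large, license-bound and unversioned, so the
test bed is generated: dictionary A is written in the NACC-style layout and
dictionary B in the ADNI-style layout, with a known 1:1 correspondence
between a subset of their elements.  B's texts are perturbed copies of
their A counterparts, emulating the phenomena observed in real resources:

* enumerator prefixes — CRF question texts carry nested section/question
  numbering ("12. 3a."); two to five numbering tokens are inserted so the
  perturbation measurably depresses bag-of-words scores on short texts;
* stopword insertion — filler words that normalization should absorb;
* synonym substitution — a shipped table ("mean" ↔ "average", "subject" ↔
  "participant", ...) models cross-resource vocabulary drift;
* word concatenation — camel-case fusing of adjacent words, as in imaging
  variable names ("RightTemporalPole");
* phase duplication — B rows are replicated across study phases, with the
  permissible-value string optionally reordered in later phases;
* "Other, specify" distractors — ambiguous satellite elements with no
  counterpart.

Element templates are assembled from a vocabulary of clinical-assessment
phrases (depression-scale items, imaging volumetrics, neuropathology
findings, motor-exam items) so the synthetic dictionaries resemble the real
domains without copying any real resource.  One integer seed governs every
random draw; identical seeds give byte-identical output files.

A deterministic toy embedding store accompanies the dictionaries: tokens in
one synonym group receive nearly parallel unit vectors (pairwise cosine
>= 0.95 by construction) while tokens of different groups are nearly
orthogonal (cosine <= 0.3), standing in for a pre-trained store at test
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dictionary_io import Source, make_element_id
from .similarity import EmbeddingStore

__all__ = [
    "PerturbationConfig",
    "SyntheticTruth",
    "load_synonym_table",
    "template_pool",
    "generate_paired_dictionaries",
    "write_paired_dictionaries",
    "toy_embeddings",
    "corpus_vocabulary",
]

YESNO = "1=Yes; 0=No"
SEVERITY = "0=Normal; 1=Slight; 2=Mild; 3=Moderate; 4=Severe"

# (form, descriptor, type_code, value codes, unit)
_GDS_FORM = "Behavioral Assessment - Geriatric Depression Scale"
_GDS_ITEMS = [
    "Are you basically satisfied with your life?",
    "Do you feel that your life is empty?",
    "Do you often get bored?",
    "Are you in good spirits most of the time?",
    "Are you afraid that something bad is going to happen to you?",
    "Do you feel happy most of the time?",
    "Do you often feel helpless?",
    "Do you prefer to stay at home rather than going out?",
    "Do you feel you have more problems with memory than most?",
    "Do you feel it is wonderful to be alive now?",
    "Do you feel pretty worthless the way you are now?",
    "Do you feel full of energy?",
]
_IMG_REGIONS = [
    "Left hippocampus",
    "Right hippocampus",
    "Left fusiform",
    "Right fusiform",
    "Left temporal pole",
    "Right temporal pole",
    "Left insula",
    "Right entorhinal cortex",
]
_IMG_MEASURES = [
    ("gray matter volume", "cc"),
    ("mean cortical thickness", "mm"),
    ("white matter volume", "cc"),
    ("surface area", "mm2"),
]
_NP_FORM = "Neuropathology"
_NP_ITEMS = [
    "Paraffin-embedded blocks of brain regions",
    "Medial temporal lobe sclerosis present",
    "Lewy body disease present",
    "Hippocampal sclerosis present",
    "Frozen tissue available",
    "Prion associated disease primary",
    "Cerebral amyloid angiopathy present",
    "Arteriolosclerosis present",
]
_UPDRS_FORM = "Unified Parkinson's Disease Rating Scale (UPDRS)"
_UPDRS_ITEMS = [
    "Finger taps - right hand",
    "Finger taps - left hand",
    "Hand movements - right hand",
    "Hand movements - left hand",
    "Leg agility - right leg",
    "Leg agility - left leg",
    "Body bradykinesia and hypokinesia",
    "Tremor at rest - face",
    "Speech problems",
    "Facial expression",
]
_HH_FORM = "Subject Health History"
_HH_ITEMS = [
    "Pacemaker",
    "Stroke",
    "Seizures",
    "Diabetes",
    "Hypertension",
    "Hypercholesterolemia",
    "Thyroid disease",
    "Congestive heart failure",
    "Cardiac bypass procedure",
    "Atrial fibrillation",
]
# MoCA sub-items are mostly single words on a dedicated form, so their
# combined texts are very short — the similarity-fragile regime where
# question-number noise can push a true pair below threshold
_MOCA_FORM = "MOCA"
_MOCA_ITEMS = [
    "Place",
    "City",
    "Month",
    "Year",
    "Day",
    "Date",
    "Season",
    "Cube",
    "Clock",
    "Lion",
    "Rhinoceros",
    "Camel",
    "Digits",
    "Letters",
    "Repetition",
    "Fluency",
    "Abstraction",
    "Recall",
]
_SYN_FORM = "Overall Assessment"
_SYN_ITEMS = [
    "Memory total mean score",
    "Language overall evaluation rating",
    "Attention subject mean rating",
    "Orientation total exam score",
    "Recall overall test rating",
    "Gait subject mean score",
    "Balance total overall rating",
    "Fluency mean exam rating",
    "Naming subject overall score",
    "Abstraction total mean rating",
]
_LAB_FORM = "Laboratory and Vitals"
_LAB_ITEMS = [
    ("Systolic blood pressure", "mmHg"),
    ("Diastolic blood pressure", "mmHg"),
    ("Pulse rate", "bpm"),
    ("Body weight", "kg"),
    ("Body height", "cm"),
    ("PR interval", "ms"),
    ("QRS duration", "ms"),
    ("Serum glucose level", "mg/dL"),
    ("White blood cell count", "10^3/uL"),
    ("Hemoglobin concentration", "g/dL"),
    ("Respiratory rate", "breaths/min"),
    ("Body temperature", "C"),
]
_DEMO_FORM = "Subject Demographics"
_DEMO_ITEMS = [
    ("Marital status", "T", "1=Married; 2=Widowed; 3=Divorced; 4=Never married", ""),
    ("Years of education", "N", "", "years"),
    ("Month of birth", "D", "", ""),
    ("Handedness", "T", "1=Left; 2=Right; 3=Ambidextrous", ""),
    ("Primary language", "T", "1=English; 2=Spanish; 3=Mandarin", ""),
    ("Living situation", "T", "1=Lives alone; 2=Lives with spouse; 3=Lives with relative", ""),
]


def template_pool() -> list[tuple[str, str, str, str, str]]:
    """The fixed, ordered pool of (form, descriptor, type, codes, unit) templates."""
    pool: list[tuple[str, str, str, str, str]] = []
    pool += [(_GDS_FORM, q, "N", YESNO, "") for q in _GDS_ITEMS]
    pool += [
        ("Imaging", f"{region} {measure}", "N", "", unit)
        for region in _IMG_REGIONS
        for measure, unit in _IMG_MEASURES
    ]
    pool += [(_NP_FORM, q, "N", YESNO, "") for q in _NP_ITEMS]
    pool += [(_UPDRS_FORM, q, "N", SEVERITY, "") for q in _UPDRS_ITEMS]
    pool += [(_HH_FORM, q, "N", YESNO, "") for q in _HH_ITEMS]
    pool += [(_MOCA_FORM, q, "N", "1=Correct; 0=Incorrect", "") for q in _MOCA_ITEMS]
    pool += [(_SYN_FORM, q, "N", "", "") for q in _SYN_ITEMS]
    pool += [(_LAB_FORM, q, "N", "", unit) for q, unit in _LAB_ITEMS]
    pool += [(_DEMO_FORM, q, t, codes, unit) for q, t, codes, unit in _DEMO_ITEMS]
    return pool


def load_synonym_table() -> list[list[str]]:
    """The shipped synonym groups (tab-separated, one group per line)."""
    text = resources.files("cdemap.data").joinpath("synonyms.tsv").read_text()
    return [line.split("\t") for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class PerturbationConfig:
    """Rates of the perturbations applied to dictionary B texts.

    All rates are per-element probabilities in [0, 1], except
    ``synonym_rate`` which applies per synonym-eligible word and
    ``phase_dup_factor`` which is the number of study phases each B row is
    replicated into (1 = no duplication).
    """

    enumerator_rate: float = 0.0
    stopword_rate: float = 0.0
    synonym_rate: float = 0.0
    concat_rate: float = 0.0
    phase_dup_factor: int = 1
    distractor_other_rate: float = 0.0
    code_reorder_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "enumerator_rate",
            "stopword_rate",
            "synonym_rate",
            "concat_rate",
            "distractor_other_rate",
            "code_reorder_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.phase_dup_factor < 1:
            raise ValueError("phase_dup_factor must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted 1:1 correspondences and distractors for one generated pair."""

    pairs: list[tuple[str, str, tuple[str, ...]]]
    distractor_ids: list[str]
    seed: int

    @property
    def pair_keys(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source_id": a, "target_id": b, "tags": "|".join(tags)}
                for a, b, tags in self.pairs
            ],
            columns=["source_id", "target_id", "tags"],
        )


_FILLER_STOPWORDS = ["the", "of", "a", "is", "on", "for", "to"]


def _perturb_text(
    text: str,
    rng: np.random.Generator,
    config: PerturbationConfig,
    synonym_of: dict[str, list[str]],
) -> tuple[str, tuple[str, ...]]:
    tags: list[str] = []
    words = text.split()
    if config.synonym_rate > 0:
        swapped = False
        out = []
        for w in words:
            key = w.strip(".,?!:;()'-").lower()
            if key in synonym_of and rng.random() < config.synonym_rate:
                others = [s for s in synonym_of[key] if s != key]
                out.append(str(rng.choice(others)))
                swapped = True
            else:
                out.append(w)
        words = out
        if swapped:
            tags.append("synonym")
    if config.concat_rate > 0 and len(words) >= 2 and rng.random() < config.concat_rate:
        i = int(rng.integers(0, len(words) - 1))
        a, b = words[i], words[i + 1]
        if a.isalpha() and b.isalpha():
            words[i : i + 2] = [a.capitalize() + b.capitalize()]
            tags.append("concat")
    if config.stopword_rate > 0 and rng.random() < config.stopword_rate:
        i = int(rng.integers(0, len(words) + 1))
        words.insert(i, str(rng.choice(_FILLER_STOPWORDS)))
        tags.append("stopword")
    if config.enumerator_rate > 0 and rng.random() < config.enumerator_rate:
        # nested section/question/sub-item numbering, e.g. "12. 3a."
        m = int(rng.integers(2, 6))
        prefix = []
        for _ in range(m):
            num = int(rng.integers(1, 20))
            sub = str(rng.choice(["", "a", "b"]))
            prefix.append(f"{num}{sub}.")
        words = prefix + words
        tags.append("enum")
    return " ".join(words), tuple(tags)


def _table_name(form: str) -> str:
    return "".join(w[0] for w in form.split() if w[:1].isalnum()).upper() or "TBL"


def generate_paired_dictionaries(
    n_pairs: int,
    n_distractors: int,
    config: PerturbationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate dictionary A (NACC layout), dictionary B (ADNI layout), truth.

    Element ids in the truth table are exactly the ids that
    :func:`cdemap.dictionary_io.read_dictionary` assigns when reading the
    generated tables; B's ids refer to the first study phase, the instance
    that phase deduplication retains.
    """
    if n_pairs < 0 or n_distractors < 0:
        raise ValueError("n_pairs and n_distractors must be >= 0")
    pool = template_pool()
    if n_pairs + n_distractors > len(pool):
        raise ValueError(
            f"template pool has {len(pool)} entries; cannot draw "
            f"{n_pairs + n_distractors} distinct elements"
        )
    synonym_groups = load_synonym_table()
    if config.synonym_rate > 0 and not synonym_groups:
        raise ValueError("synonym_rate > 0 but the synonym table is empty")
    synonym_of = {w: group for group in synonym_groups for w in group}

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_pairs + n_distractors, replace=False)
    pair_templates = [pool[i] for i in chosen[:n_pairs]]
    distractor_templates = [pool[i] for i in chosen[n_pairs:]]

    rows_a = []
    for form, desc, _type, codes, unit in pair_templates:
        rows_a.append(
            {"Form": form, "Short descriptor": desc, "Value codes": codes, "Unit": unit}
        )
    df_a = pd.DataFrame(rows_a, columns=["Form", "Short descriptor", "Value codes", "Unit"])

    phases = [f"PH{k + 1}" for k in range(config.phase_dup_factor)]
    rows_b = []
    pairs: list[tuple[str, str, tuple[str, ...]]] = []
    distractor_ids: list[str] = []
    fld_counter = 0

    def add_b_element(
        form: str, desc: str, type_code: str, codes: str, unit: str
    ) -> str:
        """Append one B element (replicated over phases); return its first-phase id."""
        nonlocal fld_counter
        fld_counter += 1
        fld = f"F{fld_counter:04d}"
        tbl = _table_name(form)
        first_id = make_element_id(
            Source.SYNTH, form, 0, field_name=fld, table_name=tbl, phase=phases[0]
        )
        for k, phase in enumerate(phases):
            phase_codes = codes
            if k > 0 and codes and rng.random() < config.code_reorder_rate:
                phase_codes = ";".join(
                    p.strip() for p in reversed(codes.split(";")) if p.strip()
                )
            rows_b.append(
                {
                    "Phase": phase,
                    "FLDNAME": fld,
                    "TBLNAME": tbl,
                    "CRFNAME": form,
                    "TEXT": desc,
                    "TYPE": type_code,
                    "LENGTH": "",
                    "CODE": phase_codes,
                    "UNITS": unit,
                }
            )
        return first_id

    for i, (form, desc, type_code, codes, unit) in enumerate(pair_templates, start=1):
        a_id = make_element_id(Source.SYNTH, form, i)
        perturbed, tags = _perturb_text(desc, rng, config, synonym_of)
        b_id = add_b_element(form, perturbed, type_code, codes, unit)
        pairs.append((a_id, b_id, tags))

    for form, desc, type_code, codes, unit in distractor_templates:
        if rng.random() < config.distractor_other_rate:
            desc, codes, unit = "Other, specify", "", ""
        else:
            desc, _ = _perturb_text(desc, rng, config, synonym_of)
        distractor_ids.append(add_b_element(form, desc, type_code, codes, unit))

    df_b = pd.DataFrame(
        rows_b,
        columns=[
            "Phase",
            "FLDNAME",
            "TBLNAME",
            "CRFNAME",
            "TEXT",
            "TYPE",
            "LENGTH",
            "CODE",
            "UNITS",
        ],
    )
    truth = SyntheticTruth(pairs=pairs, distractor_ids=distractor_ids, seed=seed)
    return df_a, df_b, truth


def write_paired_dictionaries(
    out_dir: str | Path,
    df_a: pd.DataFrame,
    df_b: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write dict_a.csv, dict_b.csv and truth.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dict_a": out / "dict_a.csv",
        "dict_b": out / "dict_b.csv",
        "truth": out / "truth.csv",
    }
    df_a.to_csv(paths["dict_a"], index=False)
    df_b.to_csv(paths["dict_b"], index=False)
    truth.to_frame().to_csv(paths["truth"], index=False)
    return paths


def corpus_vocabulary(texts: Sequence[str]) -> list[str]:
    """Sorted vocabulary of already-normalized texts."""
    vocab: set[str] = set()
    for t in texts:
        vocab.update(t.split())
    return sorted(vocab)


def toy_embeddings(
    vocabulary: Sequence[str],
    synonym_groups: Optional[list[list[str]]] = None,
    dimension: Optional[int] = None,
    seed: int = 0,
) -> EmbeddingStore:
    """Deterministic unit vectors with controlled synonym geometry.

    Each synonym group (and each remaining token as a singleton group) gets
    an orthonormal anchor direction; members are the anchor plus a small
    jitter confined to extra dimensions, so within-group cosines are
    >= 0.95 and cross-group cosines <= 0.3 by construction, for any seed.
    """
    groups = [list(g) for g in (synonym_groups or [])]
    vocab = list(dict.fromkeys(vocabulary))
    grouped = {w for g in groups for w in g}
    missing = sorted(grouped - set(vocab))
    if missing:
        raise ValueError(f"synonym-group tokens missing from vocabulary: {missing}")
    for w in vocab:
        if w not in grouped:
            groups.append([w])
    n_groups = len(groups)
    jitter_dims = 4
    if dimension is None:
        dimension = n_groups + jitter_dims
    if dimension < max(2, n_groups + 1):
        raise ValueError(
            f"dimension must be at least {n_groups + 1} for {n_groups} groups"
        )
    rng = np.random.default_rng(seed)
    eps = 0.15
    vectors: dict[str, np.ndarray] = {}
    for g, members in enumerate(groups):
        for w in members:
            v = np.zeros(dimension)
            v[g] = 1.0
            jitter = rng.standard_normal(dimension - n_groups)
            norm = np.linalg.norm(jitter)
            if norm > 0:
                v[n_groups:] = eps * jitter / norm
            vectors[w] = v / np.linalg.norm(v)
    return EmbeddingStore(vectors, name=f"toy(seed={seed})")
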