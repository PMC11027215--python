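"""Shared fixtures: worked-example elements, dictionaries and toy embeddings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cdemap import (
    BowScorer,
    DataElement,
    PerturbationConfig,
    Source,
    generate_paired_dictionaries,
)
from cdemap.dictionary_io import get_profile, read_dictionary_frame
from cdemap.preprocess import dedup_elements, filter_ambiguous
from cdemap.similarity import EmbeddingStore

# The duplicated-across-phases ADNI entry used throughout: the same modified
# Hachinski item collected in four study phases, with the code list reordered
# in the last release.
TABLE1_ROWS = [
    {
        "Phase": phase,
        "FLDNAME": "HMSTEPWS",
        "TBLNAME": "MODHACH",
        "CRFNAME": "Modified Hachinski",
        "TEXT": "2. Stepwise Deterioration of Dementia",
        "TYPE": "N",
        "LENGTH": "1",
        "CODE": code,
        "UNITS": "",
    }
    for phase, code in [
        ("ADNI1", "1=Present - 1 point; 0=Absent"),
        ("ADNIGO", "1=Present - 1 point; 0=Absent"),
        ("ADNI2", "1=Present - 1 point; 0=Absent"),
        ("ADNI3", "0=Absent;1=Present - 1 point"),
    ]
]


@pytest.fixture
def table1_frame() -> pd.DataFrame:
    return pd.DataFrame(TABLE1_ROWS)


@pytest.fixture
def table1_elements(table1_frame) -> list[DataElement]:
    return read_dictionary_frame(table1_frame, get_profile("adni")).elements


def make_element(
    element_id: str = "X:test:r0001",
    descriptor: str = "",
    form_name: str = "",
    **kwargs,
) -> DataElement:
    kwargs.setdefault("source", Source.SYNTH)
    return DataElement(
        element_id=element_id, form_name=form_name, descriptor=descriptor, **kwargs
    )


@pytest.fixture
def gds_pair() -> tuple[DataElement, DataElement]:
    """The depression-scale life-satisfaction item as it appears in two resources."""
    nacc = make_element(
        "NACC:b6:r0001",
        source=Source.NACC,
        form_name="Behavioral Assessment - Geriatric Depression Scale",
        descriptor="Are you basically satisfied with your life?",
    )
    adni = make_element(
        "ADNI:GDS:GDSATIS",
        source=Source.ADNI,
        form_name="Geriatric Depression Scale",
        descriptor="1. Are you basically satisfied with your life?",
    )
    return nacc, adni


def preprocess_pipeline(df: pd.DataFrame, profile_name: str) -> list[DataElement]:
    """Read → dedup → ambiguous-filter, as the CLI does."""
    result = read_dictionary_frame(df, get_profile(profile_name))
    kept, _ = filter_ambiguous(dedup_elements(result.elements))
    return kept


@pytest.fixture
def zero_noise_pair():
    """50 planted pairs + 20 distractors with no perturbation at all."""
    df_a, df_b, truth = generate_paired_dictionaries(
        50, 20, PerturbationConfig(), seed=1
    )
    return (
        preprocess_pipeline(df_a, "synth-nacc"),
        preprocess_pipeline(df_b, "synth-adni"),
        truth,
    )


@pytest.fixture
def small_store() -> EmbeddingStore:
    """A tiny hand-built embedding store with known geometry."""
    rng = np.random.default_rng(12345)
    vectors = {t: rng.standard_normal(5) for t in "abcdefgh"}
    vectors["zero_like"] = rng.standard_normal(5) * 1e-3
    return EmbeddingStore(vectors, name="fixture")


@pytest.fixture
def bow() -> BowScorer:
    return BowScorer()
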