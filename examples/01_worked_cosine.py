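"""Bag-of-words cosine between one item recorded in two dictionaries.

The geriatric-depression-scale question "Are you basically satisfied with
your life?" exists in both resources, under different form context and with
a question number on one side.  Normalization strips the differences that
do not carry meaning; the cosine of the remaining term-frequency bags is
the mapping score.
"""

from cdemap import DataElement, Source, cosine_similarity, prepare_element_text, to_token_bag

nacc = DataElement(
    element_id="NACC:b6:r0001",
    source=Source.NACC,
    form_name="Behavioral Assessment - Geriatric Depression Scale",
    descriptor="Are you basically satisfied with your life?",
)
adni = DataElement(
    element_id="ADNI:GDS:GDSATIS",
    source=Source.ADNI,
    form_name="Geriatric Depression Scale",
    descriptor="1. Are you basically satisfied with your life?",
)

text_a, text_b = prepare_element_text(nacc), prepare_element_text(adni)
print("normalized A:", text_a)
print("normalized B:", text_b)
score = cosine_similarity(to_token_bag(text_a), to_token_bag(text_b))
print(f"cosine similarity: {score.value:.4f} (rounded to one decimal: {round(score.value, 1)})")
print("-> well above the 0.6 mapping threshold: the pair is proposed as a mapping")
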