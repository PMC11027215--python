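"""End-to-end mapping on generated dictionaries with planted truth.

Generates a NACC-layout dictionary A and an ADNI-layout dictionary B with
50 planted correspondences (B's texts carry question-number noise and are
phase-duplicated) plus 20 distractors, runs the full preprocessing and
bag-of-words mapping pipeline, and scores the result against the planted
truth.
"""

from cdemap import (
    BowScorer,
    PerturbationConfig,
    compare_to_truth,
    generate_paired_dictionaries,
    map_elements,
)
from cdemap.dictionary_io import get_profile, read_dictionary_frame
from cdemap.preprocess import dedup_elements, filter_ambiguous

config = PerturbationConfig(enumerator_rate=0.5, phase_dup_factor=3, distractor_other_rate=0.3)
df_a, df_b, truth = generate_paired_dictionaries(50, 20, config, seed=1)
print(f"dictionary A: {len(df_a)} rows; dictionary B: {len(df_b)} rows (phase-duplicated)")

elements = {}
for name, df, profile in [("A", df_a, "synth-nacc"), ("B", df_b, "synth-adni")]:
    result = read_dictionary_frame(df, get_profile(profile))
    deduped = dedup_elements(result.elements)
    kept, removed = filter_ambiguous(deduped)
    print(
        f"{name}: {len(result.elements)} read -> {len(deduped)} after dedup "
        f"-> {len(kept)} after dropping {len(removed)} ambiguous"
    )
    elements[name] = kept

mappings = map_elements(elements["A"], elements["B"], BowScorer(), threshold=0.6)
res = compare_to_truth(mappings, truth.pair_keys)
print(
    f"mapped {res['n_mapped']} sources; {res['n_recovered']} of {res['n_truth']} "
    f"planted pairs recovered (precision {res['precision']:.2f}, recall {res['recall']:.2f})"
)
print("-> question-number noise is absorbed by enumerator dropping, so recovery is high")
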