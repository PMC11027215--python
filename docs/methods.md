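# Methods

## Problem and data model

A data dictionary is read into a flat list of elements, each carrying a
form/CRF context (`form_name`), a descriptor or question text, optional
variable/table names, an optional study-phase label, a value type, a unit
and a raw permissible-value string. Three built-in schema profiles cover
the common layouts (NACC-style `Form`/`Short descriptor`, ADNI-style
`Phase`/`FLDNAME`/`TBLNAME`/`CRFNAME`/`TEXT`/`TYPE`/`CODE`/`UNITS`,
NIH-CDE-style `Name`/`Question Texts`); because published CSV exports vary,
profiles are user-overridable from a JSON file. Element identifiers are
deterministic — `<source>:<table or form slug>:<field name or row index>`,
with an `@<phase>` suffix when a phase label is present so that the same
variable collected in several phases remains addressable before
deduplication. Rows are never silently dropped: a row whose form name and
descriptor are both empty goes to a rejects list with a reason, and
`len(elements) + len(rejects)` always equals the number of data rows.

## Preprocessing

Four element-level steps precede scoring, in this order:

1. **Phase deduplication.** The dedup key is (field name, table name, form
   name, descriptor), case-insensitive. Phase, type/length metadata and
   the permissible-value string are excluded from the key because a later
   form release may reorder a code list without making the element a new
   variable; the first occurrence wins.
2. **Ambiguous-element filtering.** Elements whose descriptor contains
   "other" or "specify" as a whole word (case-insensitive) are satellites
   of some other question and are removed; both kept and removed lists are
   returned for audit. OR semantics is the default — either word alone
   already marks a satellite item — with AND available as an option.
3. **Form-name expansion.** Short form codes ("b6") are replaced by full
   names through a two-column lookup table; missing keys warn and pass
   through unchanged, so expansion is idempotent.
4. **Concatenated-word splitting.** Imaging variable texts fuse words in
   camel case ("RightTemporalPole"); a space is inserted before each
   uppercase letter that follows a lowercase letter, leaving all-caps
   acronyms ("MMSE") intact.

Text normalization then lowercases, replaces ASCII punctuation by spaces,
drops enumerator tokens, removes stopwords, lemmatizes, and re-filters
stopwords (a lemma can itself be a stopword). Normalization is a
projection — applying it to its own output changes nothing — which the
suite checks by property test on arbitrary text.

**Enumerator dropping** removes tokens that are pure digits or digits with
one trailing letter ("1", "16a"). CRF question texts are number-laden
while counterpart descriptors in other resources are not, so leaving the
numbers in systematically depresses similarity; the toggle defaults to on
and is exposed because the removal of numeric tokens is a modeling choice,
not a certainty, for any given resource pair.

**Stopwords and lemmatizer.** The stopword list is a pinned standard
English list shipped as a data file, so results do not depend on network
access or on another package's version drift. The lemmatizer is a compact
rule-based noun-default singularizer: an irregular-plural exceptions table
(also shipped) plus ordered suffix rules with small guards (-ss/-us/-is
endings untouched; vowel-before-suffix disambiguation separates
"watches"→"watch" from "aches"→"ache"). The rule step is iterated to a
fixed point so lemmatization is also a projection. It deliberately
over-stems rare forms ("quizzes"→"quizz"); both sides of every comparison
receive the same treatment, which is what matters for matching.

## Similarity backends

**Bag-of-words cosine.** Texts are term-frequency bags (counts, not
binary): a word repeated on only one side genuinely lowers the score,
which is the observed failure mode for texts like "Participant …
Participant …" against a singly-worded counterpart.

**Word Mover's Distance.** Bags are converted to nBOW mass distributions
over their in-vocabulary tokens; out-of-vocabulary tokens are dropped and
counted, and a pair that loses *all* tokens on either side is incomparable
and scores 0 (this mirrors the real failure mode of general-domain
embeddings on anatomical vocabulary). Word vectors are L2-normalized
before the ground cost `‖x_i − x_j‖` is computed, which bounds
single-token distances to [0, 2]. The transport problem is solved exactly
with the HiGHS linear-programming solver; no greedy or relaxed lower-bound
shortcut is used. Bags in this domain are short (≈ 3–15 tokens), so the
LP is tiny and an all-pairs run over ~10³ × 10⁴ elements remains
practical. WMD is reported as the bounded similarity `1/(1 + distance)`,
the transform used by the similarity wrappers of common embedding
libraries, so both backends share one `[0, 1]` scale and one threshold.
The suite verifies the solver against an independent brute-force oracle
that enumerates greedy-saturation transport plans in exact integer
arithmetic (every vertex of the transport polytope arises from some
saturation order, and the LP optimum is attained at a vertex), to
1 × 10⁻⁹ on 200 random instances with vocabularies ≤ 4.

## Mapping rules

Scoring text is `form_name + " " + descriptor`, normalized once per
element and cached. Pairs must score **strictly above** the threshold
(default 0.6); each source then keeps only its highest-scoring target.
Ties break to the lexicographically smallest target id with a logged
warning. Thresholding before or after best-match selection is equivalent
for positive thresholds; the suite asserts this. Aggregation across
backends is a union keyed on (source id, target id), keeping the best
score, concatenating method provenance and preserving any review verdict;
it is idempotent and order-independent. The tool emits *unreviewed*
candidates; expert review arrives as an external CSV of
(source id, target id, valid|invalid) verdicts merged back in — the
adjudication itself is out of scope by design.

## Value-domain auditing

Value types are inferred as numerical / categorical / date / text /
unknown. A profile-supplied type code wins, with one refinement: a
nominally numeric element whose code string enumerates responses
("1=Present - 1 point; 0=Absent") is categorical, because the digit is a
code, not a measurement. Unknown never matches anything, including
another unknown. For type-identical numerical pairs, units compare by
literal case-insensitive string equality with missing-on-either-side
reported as *not available*; there is deliberately no unit-conversion
ontology ("cc" vs "mm3" is *disparate* even though convertible — the
audit reports recording differences, it does not resolve them). For
type-identical categorical pairs, permissible-value strings are parsed by
splitting on ";" and on the *first* "=" (labels may contain "="), and
label sets are compared case-insensitively with codes ignored, since one
resource may code its responses ("1=Yes") while another lists bare labels
("Yes"); equal sets are *identical*, overlapping sets *partially
identical*, disjoint sets *disparate*. No synonym matching is applied to
labels ("None" vs "Absent" stays disparate). Date and text pairs carry
the type verdict only.

## Evaluation

Per-run contingency tables require every candidate to be adjudicated and
report valid/invalid counts with percentages rounded half-up to two
decimals. Precision is valid/total per run; recall is valid over the
*aggregated* valid set — with no independent gold standard, mappings
missed by every backend are invisible, so reported recall is an upper
bound and the report says so. Mapping rate is the percentage of one
resource's preprocessed elements that acquired at least one valid mapping.
For three runs the seven exclusive Venn regions of the valid sets are
reported; they always sum to the size of the three-way union.

## Synthetic data generator

The generator is the package's study bed: a template pool of 118 clinical
assessment items (depression-scale questions, regional imaging
volumetrics with realistic units, neuropathology findings, motor-exam
items, single-word MoCA sub-items, health-history indicators, labs and
demographics) assembled from domain vocabulary without copying any real
resource. Dictionary A takes the NACC layout; dictionary B the ADNI
layout, with B's texts perturbed:

* *enumerator prefixes* — two to five numbering tokens ("12. 3a.")
  emulating nested section/question numbering; a single number can never
  push a true pair below the 0.6 threshold (k shared tokens against k+1
  give cosine √(k/(k+1)) ≥ 0.707), so heavier numbering on short texts is
  what makes the drop-enumerators toggle observable;
* *stopword insertion*, absorbed entirely by normalization;
* *synonym substitution* from the shipped table (mean↔average,
  subject↔participant, …) — the synonym-dense "Overall Assessment"
  templates are constructed so that at substitution rate 1 a true pair's
  cosine falls below threshold deterministically while WMD over the toy
  store keeps it high, reproducing the qualitative bag-of-words vs
  embeddings contrast;
* *camel-case fusion* of adjacent words, undone by the splitting step;
* *phase duplication* with optional code-list reordering in later phases,
  collapsed by dedup;
* *"Other, specify" distractors*, removed by the ambiguous filter.

One seed drives every draw; the same seed yields byte-identical output
files, and the resolved configuration is written next to them. The toy
embedding store assigns each synonym group an orthonormal anchor
direction plus a small jitter (ε = 0.15) confined to extra dimensions, so
within-group cosines are ≥ (1−ε²)/(1+ε²) ≈ 0.956 and cross-group cosines
≤ ε²/(1+ε²) ≈ 0.022 *for any seed* — the geometry is guaranteed, not
sampled.

What the generator does **not** model: real lexical diversity and length
distributions, acronym/abbreviation drift ("APOE genotype" vs
"Apolipoprotein-E"), elements whose counterpart has a much longer
paraphrase, and cross-form reorganization. Passing recovery tests
therefore demonstrates that the pipeline implements its rules correctly
under the planted perturbations, not that those precision/recall figures
transfer to real resources, where candidate mappings additionally require
expert review.

## Problem sizes and numerical choices

The default test bed uses 50 planted pairs plus 20 distractors, a scale at
which all-pairs WMD (50 × ~65 LPs) completes in seconds while leaving all
perturbation regimes populated. Solver-vs-oracle agreement is asserted at
1 × 10⁻⁹ absolute; metric properties (symmetry, triangle inequality) at
the same tolerance. Scores are compared to the threshold with plain
floating-point `>` — the strictness of "above" is part of the contract.
Degenerate inputs: empty bags score 0 under cosine; fully-OOV bags score
0 under WMD similarity (the distance function raises instead, so callers
cannot mistake incomparability for closeness); empty mapping runs render
percentages as undefined rather than 0.

## Known limitations

* No acronym expansion or terminology-based synonym substitution; these
  are the dominant cause of missed real-world mappings.
* Unit comparison is string equality; convertible units count as
  disparate by design.
* Best-match keeps exactly one target per source; genuinely one-to-many
  correspondences are reduced to their best representative.
* The lemmatizer is intentionally small; it is consistent across both
  sides of a comparison but not a full morphological analyzer.
* Reading the binary keyed-vector embedding format is not supported; use
  the word-per-line text format (a header line with vocabulary size and
  dimension is accepted and skipped).
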