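# Methods

This note documents the quantities `girasol` computes, the conventions and
numerical choices behind them, what the synthetic data emulate, and the
limits of what the test suite demonstrates.

## Units and normalization

The scoring unit is the Unicode code point. This makes orthographic and
broad-IPA scoring uniform, at the price of treating an affricate written
as two code points (`d` + `ʒ`) as two "phonemes" — which is the convention
the shared-phoneme worked examples require (e.g. the
development/intelligence transcriptions give 63.64% only when `dʒ` counts
twice). Combining diacritics are not folded away; instead all table input
is NFC-normalized on read (`read_table`), so precomposed and decomposed
spellings compare equal. Stress (ˈ ˌ) and syllable (.) marks are removed
only by an explicit call to `strip_phonemic_marks`; scoring functions
never strip them silently, because mark-stripping changes string lengths
and hence every length-normalized index. Comparisons are case-sensitive;
wordlist and embedding lookups case-fold, since those resources are
conventionally lowercase.

## The formal index battery

For target *t* (length `NLt`) and response *r* (length `NLr`):

- `p_shared_char` = `2·SL/(NLt+NLr)·100`, with `SL` the multiset
  intersection of the character bags. Symmetric, order-independent,
  in [0, 100]. Undefined (NaN) when the response is blank.
- `strict_match_pos` / `adj_strict_match_pos`: positionwise identity
  strings over `max(NLt, NLr)` and exactly `NLt` positions;
  `p_shared_char_in_pos` is the percentage of 1s in the adjusted string.
  The target length is the denominator throughout — it is the reference
  unit of the positional analysis, and it reproduces the 50% worked
  example for *mangrove*/*mango*.
- `Ld`: Levenshtein distance. `DLd`: **unrestricted** Damerau–Levenshtein
  (Lowrance–Wagner), i.e. adjacent transposition is a first-class edit
  with no restriction against editing a transposed pair again
  (`DLd("ca","abc") = 2`, where the optimal-string-alignment variant gives
  3). The unrestricted variant was chosen because transposition is
  described as an ordinary edit operation, without the adjacency-reuse
  caveat that defines OSA.
- `JWd`: 1 − Jaro–Winkler similarity, standard parameters (prefix scaling
  0.1, prefix cap 4, no boost threshold).
- `pcc` = `1 − DLd/NLt`, floored at 0. The source description says only
  "the total number of phonemes"; the target length was chosen as the
  denominator because the target is the reference unit everywhere else,
  and the floor keeps the index in [0, 1] for grossly long or unrelated
  responses. If the forthcoming definition of pcc normalizes differently
  (e.g. by `max(NLt, NLr)`), only this constant needs changing.
- `lcs` **column** vs `lcs_string` **function**: the longest common
  *subsequence* of *mangrove* and *mango* is "mango" (m-a-n-g plus the
  trailing o), but reference implementations of this battery report
  "mang" — the longest common *substring*. Both are provided:
  `lcs_string` computes the subsequence under a deterministic leftmost
  tie-break (earliest target indices win) and is validated against
  brute-force enumeration; `lcs_substring` computes the contiguous run
  (earliest start in the target on ties), and is what the `lcs` output
  column reports so that the battery matches the reference outputs.
- `similarity_str`: a minimal Levenshtein edit script over {M, D, S, I},
  tie-broken M > S > D > I at equal cost so the trace is deterministic.
  Counts satisfy `#M+#S+#D = NLt`, `#M+#S+#I = NLr`, `#S+#D+#I = Ld`.
- `approach_diff`: Δpcc between consecutive attempts, computed within each
  `group_cols` × item partition ordered by attempt and missing for the
  first attempt. Partitioning by every identifying column matters:
  without it, attempt 2 of one assessment could be compared against
  attempt 1 of another. Duplicate (group, attempt) keys are a
  data-integrity error, not silently averaged. The increments telescope:
  their sum over a sequence equals pcc(last) − pcc(first) exactly.

Blank responses in a table are scored rather than fatal (`p_shared_char`
NaN, match strings all zero, `Ld = DLd = NLt`, `pcc = 0`, empty `lcs`,
all-deletion trace), while the scalar functions with a length in a
denominator raise on empty input. `comment_warning` flags responses
containing a space or comma, the usual sign of an unsplit multi-attempt
cell.

## Wrangling conventions

The attempt delimiter is a literal string (default ", "), not a pattern —
IPA text makes regular-expression delimiters hazardous. Attempts are
whitespace-trimmed; interior spaces are preserved and surface later as
`comment_warning`. With `drop_blank`, blank attempts are removed before
numbering, so attempt indices count retained attempts only, and a fully
blank cell disappears. Without it, interior blanks survive as rows and a
fully blank cell yields one empty-response row (RA = 0, attempt = 1); use
this mode when no-response items must reach the classifier. RA = 1 iff
the source cell held at least two non-blank attempts. Attempt order is
assumed left-to-right as transcribed.

## Lexicality

The dictionary criterion is plain wordlist membership and is independent
of the target. The database criterion follows the published rule: the
response must be listed *and* strictly more frequent (log10 frequency)
than the target item. This makes lexicality target-relative — the same
response can be "lexical" for a rare target and "non-lexical" for a
frequent one — which is surprising but implemented as stated. Two edge
decisions: frequency ties are non-lexical (the rule says "higher"), and a
target absent from the lexicon is treated as having frequency −∞ (any
listed response counts as lexical) with a note in `lexicality_note`,
because the target's absence from a resource should not silently discard
real-word responses.

## Semantic similarity

`load_embeddings` reads word2vec text (and binary) tables; cosines are
computed on the raw vectors, so load-time normalization is optional and
irrelevant to the scores. Out-of-vocabulary or blank words produce NaN —
missingness is a value here, not an error. The classifier treats a
missing cosine as "not semantically related" and records it in
`classifier_note` rather than flagging the row for manual review; this is
conservative (a formal real-word response stays formal rather than
becoming mixed) and auditable. The default decision threshold is 0.46,
appropriate for models whose cosines live in [0, 1]; stricter work has
used ≈ 0.55, and models with cosines in [−1, 1] need a rescaled threshold.
No accent-stripping or subword fallback is applied at lookup beyond
case-folding and NFC.

## Classification

`accessed` (the examiner's correctness annotation) dominates: a row
marked correct never receives an error category, and when the annotation
is absent, string equality of item and response is used. Mixed is
evaluated before formal/semantic so a doubly related word cannot fire two
categories; threshold ties count as related (criteria read "at least").
The ≥ 50% formal criterion is applied to `p_shared_char` — the quantity
the worked formal-error example computes — on whichever representation
(orthographic or phonemic) the caller passes as the item/response
columns. `check_comment` is "required" when zero or multiple categories
fire (with this tree, only possible when upstream evidence is missing),
and "is only considered as RA" when RA rows are excluded from
classification. `classify_errors_regular` is the RA-free variant and
agrees with the RA-aware function on single-response rows.

## Synthetic data

`make_toy_embeddings` places words so that same-cluster pairs have cosine
`within_cos` and cross-cluster pairs `between_cos`, exactly: each vector
is `√w·h_c + √(1−w)·e_i` with cluster axes at pairwise dot `between/within`
and orthonormal per-word residuals, followed by a seeded random rotation.
This brackets the 0.46 threshold from both sides by construction
(defaults 0.8 / 0.1).

`make_fixture_world` engineers, for every target item (6 letters from one
half of the alphabet), four real-word companions: semantic (same cluster,
disjoint letters), mixed (same cluster, one substitution), formal
(different cluster, same first letter) and unrelated (different cluster,
disjoint letters). `simulate_responses` then draws a category per
presentation from `error_mix`, builds a response satisfying that
category's defining inequalities (searching the lexicon for real-word
categories, mutating or resampling for nonwords, with a 1000-retry cap),
and prepends approach attempts — nonword distortions of the target whose
edit count decreases toward the final attempt, giving monotone-increasing
*expected* pcc (disable with `monotone_cda=False`). Every attempt's
category and pcc are recorded as ground truth; generation is fully
deterministic given the seed.

Default simulation conditions: a geometric attempt count (p = 0.6,
capped at 6; most presentations are single attempts, long conduites
d'approche are rare) and an error mix spanning all seven categories with
nonword and semantic errors most common — the typical profile of
phonologically impaired samples. What the simulation does *not* emulate:
Spanish phonotactics, perseverations or circumlocutions, annotation noise
in `accessed`, and real embedding geometry (real cosines are not
two-valued). Passing the round-trip test therefore shows the classifier
applies its defining inequalities exactly — not that those inequalities
capture clinical judgement on real data, where the cosine threshold and
the supervision of flagged rows remain the user's responsibility.

## Problem sizes and verification

The test suite verifies the edit-distance kernels against independent
oracles: Levenshtein against both a memoized recursion and the `edlib`
alignment library, LCS length against brute-force subsequence
enumeration, and unrestricted Damerau–Levenshtein against breadth-first
shortest paths in the edit graph (insert/delete/substitute/adjacent-
transpose as unit-cost moves) — exhaustively over the {a,b,c} universe at
short lengths (≤ 5 for Ld/LCS, ≤ 3 for DLd) plus a seeded 1,000-pair
sample at length ≤ 5 for DLd. The simulation round-trip runs ~340
presentations (≈ 520 attempts), chosen as comfortably large enough that
all seven categories and multi-attempt sequences occur many times while
the whole suite stays fast.

## Known limitations

- Automatic phonemic transcription is out of scope; phonemic scoring
  expects transcriptions supplied in parallel columns.
- The real Spanish resources (RAE wordlist, BPal frequencies, a
  billion-word word2vec model) are interfaces here, not contents; all
  shipped resources are synthetic stand-ins.
- `pcc`'s denominator convention (target length) is one defensible
  reading of an under-specified definition; see above.
- Plotting is out of scope: `positional_summary` produces the table
  behind serial-position plots, not the figure.
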