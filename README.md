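# girasol

Analysis of single-word production attempts and errors in aphasia and
related disorders (apraxia of speech, stuttering, developmental speech
sound disorders). `girasol` takes transcribed picture-naming / repetition /
reading responses — including multi-attempt cells such as conduites
d'approche ("*talablo, talabro, talabro, taladro, taladro*" for
*taladro*) — and automates three tasks that are slow and error-prone by
hand:

1. **Wrangling** multi-attempt response cells into a long table with a
   repeated-attempt (RA) flag and attempt index.
2. **Formal-similarity scoring** of each target–response pair, at the
   letter or the broad-IPA-phoneme level.
3. **Error classification** into the standard paraphasia taxonomy
   (no response, nonword/phonemic, neologism, formal, unrelated, semantic,
   mixed) from lexicality, formal and embedding-based semantic evidence.

It is written for researchers and clinicians (speech therapists,
neuropsychologists) who work with tabular transcription data in Python or
from the shell.

## The indexes and the classification rule

For a target with `NLt` characters and a response with `NLr`, the
shared-character proportion is

```
psl = 2·SL / (NLt + NLr) · 100
```

where `SL` is the size of the multiset intersection of their characters
(`psp` when computed on broad phonemic transcriptions after removing
stress ˈ ˌ and syllable . marks). The battery also includes positional
match strings (raw and adjusted to the target length), Levenshtein (`Ld`),
unrestricted Damerau–Levenshtein (`DLd`), and Jaro–Winkler (`JWd`)
distances, the longest common subsequence and substring, an alignment
trace over {M, D, S, I}, the proportion of correct characters
`pcc = 1 − DLd/NLt` (floored at 0), and `approach_diff`, the change in pcc
between consecutive attempts of one repeated-attempt sequence.

An erroneous attempt is classified as:

- **no response** — blank;
- **nonword (phonemic)** vs **neologism** — not a real word, with
  `psl ≥ 50%` vs `< 50%`;
- real words: *formally related* iff `psl ≥ 50%` or same first character;
  *semantically related* iff the word2vec cosine of target and response
  is ≥ 0.46 (configurable). Both → **mixed**, only formal → **formal**,
  only semantic → **semantic**, neither → **unrelated**.

Lexicality comes from a dictionary wordlist or from a frequency database
(response listed *and* more frequent than the target). Rows the tree
cannot place are flagged `required` for manual review.

## Worked example

```python
from girasol import *
import pandas as pd

wordlist = Wordlist.from_words(
    ["table", "truck", "chair", "sneaker", "furniture", "furnace"])
store = make_toy_embeddings(
    [["table", "chair"], ["furniture", "furnace"], ["truck"], ["sneaker"]],
    within_cos=0.8, between_cos=0.1, seed=5)

rows = pd.DataFrame({
    "ID": ["P01"]*6, "item_ID": range(1, 7),
    "item": ["Table"]*5 + ["Furniture"],
    "response": ["Tagle", "Timos", "Sneaker", "Truck", "Chair", "Furnace"],
    "accessed": [0]*6, "RA": [0]*6, "attempt": [1]*6})

scored  = compute_formal_indexes(rows, attempt_col="attempt",
                                 group_cols=["ID", "item_ID"])
checked = check_lexicality(scored, criterion="dictionary", resource=wordlist)
out     = classify_errors(get_semantic_similarity(checked, store=store))
```

which prints (selected columns):

```
     item response  lexicality  p_shared_char  w2v_cos  category
    Table    Tagle           0          80.00      NaN   nonword
    Table    Timos           0          20.00      NaN neologism
    Table  Sneaker           1          33.33      0.1 unrelated
    Table    Truck           1          20.00      0.1    formal
    Table    Chair           1          20.00      0.8  semantic
Furniture  Furnace           1          62.50      0.8     mixed
```

*Tagle* shares 80% of its letters with *Table* but is no word → nonword
error; *Truck* is a word sharing the initial letter with a low cosine →
formal error; *Furnace* is both formally (62.5% ≥ 50%) and semantically
(0.8 ≥ 0.46) related to *Furniture* → mixed error.

The `examples/` directory has one short script per capability (wrangling,
formal indexes, positional accuracy, classification, simulation
round-trip); each prints its output with a comment on what the numbers
mean. The same stages are available from the shell via the `girasol`
command (`wrangle`, `formal`, `positions`, `classify`, `simulate`, `run`).

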