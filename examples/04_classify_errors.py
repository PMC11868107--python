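"""Classify production errors into the standard paraphasia taxonomy.

Builds a toy lexicon and an embedding store with controlled cosines
(chair/table and furnace/furniture semantically close, truck and sneaker
far), then runs the scoring + lexicality + semantics + classification
chain on the classic exemplar responses for the target "Table".
"""

import pandas as pd

from girasol import (
    CATEGORY_COLUMNS,
    Wordlist,
    check_lexicality,
    classify_errors,
    compute_formal_indexes,
    get_semantic_similarity,
    make_toy_embeddings,
)

wordlist = Wordlist.from_words(
    ["table", "truck", "chair", "sneaker", "furniture", "furnace"]
)
store = make_toy_embeddings(
    [["table", "chair"], ["furniture", "furnace"], ["truck"], ["sneaker"]],
    within_cos=0.8,
    between_cos=0.1,
    seed=5,
)

rows = pd.DataFrame(
    {
        "ID": ["P01"] * 6,
        "item_ID": range(1, 7),
        "item": ["Table"] * 5 + ["Furniture"],
        "response": ["Tagle", "Timos", "Sneaker", "Truck", "Chair", "Furnace"],
        "accessed": [0] * 6,
        "RA": [0] * 6,
        "attempt": [1] * 6,
    }
)
scored = compute_formal_indexes(rows, attempt_col="attempt", group_cols=["ID", "item_ID"])
checked = check_lexicality(scored, criterion="dictionary", resource=wordlist)
with_cos = get_semantic_similarity(checked, store=store)
out = classify_errors(with_cos, cosine_limit_value=0.46)

out["category"] = out[CATEGORY_COLUMNS].idxmax(axis=1)
print(out[["item", "response", "lexicality", "p_shared_char", "w2v_cos",
           "category"]].round(2).to_string(index=False))
# Tagle -> nonword (not a word, 80% shared), Timos -> neologism (20%),
# Sneaker -> unrelated, Truck -> formal (same first letter, low cosine),
# Chair -> semantic (cosine 0.8 >= 0.46), Furnace -> mixed (both criteria).
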