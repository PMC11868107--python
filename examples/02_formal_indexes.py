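"""Score target-response formal similarity, including across attempts.

Prints the full index battery for a small conduite d'approche and shows
how approach_diff tracks the change in the proportion of correct
characters (pcc) from one attempt to the next.
"""

import pandas as pd

from girasol import compute_formal_indexes, shared_char_proportion, strip_phonemic_marks

# The classic formal-error check: are these two words >= 50% formally similar?
psl = shared_char_proportion("development", "intelligence")
print(f"shared-letter proportion development/intelligence: {psl:.2f}%")
# 52.17% -> above the 50% criterion, despite looking unrelated at a glance.

psp = shared_char_proportion(
    strip_phonemic_marks("dɪˈvɛl.əp.mənt"), strip_phonemic_marks("ɪnˈtɛl.ɪ.dʒəns")
)
print(f"shared-phoneme proportion on broad transcriptions: {psp:.2f}%")
# 63.64% -- the phonemic comparison makes the overlap clearer.

cda = pd.DataFrame(
    {
        "ID": ["P01"] * 3,
        "item_ID": [1] * 3,
        "item": ["taladro"] * 3,
        "response": ["talablo", "talabro", "taladro"],
        "attempt": [1, 2, 3],
    }
)
scored = compute_formal_indexes(
    cda, attempt_col="attempt", group_cols=["ID", "item_ID"]
)
cols = ["response", "p_shared_char", "DLd", "pcc", "lcs", "similarity_str", "approach_diff"]
print(scored[cols].to_string(index=False))
# pcc climbs toward 1.0 as the attempts converge on the target;
# approach_diff is the per-step improvement (missing for the first attempt).
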