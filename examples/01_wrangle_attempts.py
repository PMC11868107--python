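"""Split a multi-attempt response cell into one row per attempt.

A conduite d'approche — successive self-corrections toward a target word —
arrives as a single transcription cell.  Wrangling turns it into a long
table with an RA (repeated attempt) flag and an attempt index, the shape
every later analysis expects.
"""

import pandas as pd

from girasol import get_attempts, separate_responses

raw = pd.DataFrame(
    {
        "ID": ["P01", "P01"],
        "item_ID": [1, 2],
        "item": ["taladro", "peine"],
        "response": ["talablo, talabro, talabro, taladro, taladro", "peine"],
    }
)

long = get_attempts(separate_responses(raw, "response", ", "), drop_blank=True)
print(long[["item_ID", "item", "response", "RA", "attempt"]].to_string(index=False))
# The taladro cell yields 5 rows (RA=1, attempts 1..5 in produced order);
# the single-response peine row keeps RA=0, attempt=1.
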