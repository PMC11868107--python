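"""Where in the word do errors land?

Explodes the positional match string of each attempt into one row per
target position, then summarizes the proportion correct per position —
the table behind serial-position accuracy plots.
"""

import pandas as pd

from girasol import compute_formal_indexes, positional_accuracy, positional_summary

scored = compute_formal_indexes(
    pd.DataFrame(
        {
            "item": ["mangrove", "mangrove"],
            "response": ["mango", "mangrove"],
        }
    )
)
positions = positional_accuracy(scored)
print(positions[["item", "response", "position", "element_in_item",
                 "element_in_response", "correct_pos"]].to_string(index=False))

summary = positional_summary(positions, by=["position"])
print(summary.to_string(index=False))
# Positions 1-4 ("mang") are produced correctly in both attempts
# (proportion 1.0); positions 5-8 are correct only in the full production
# (proportion 0.5).
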