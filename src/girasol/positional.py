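"""Per-position accuracy records derived from positional match strings.

Explodes each scored attempt into one row per target position so that the
distribution of errors over word positions (onset vs. coda effects,
serial-position curves in apraxia of speech or conduction aphasia) can be
tabulated and plotted.  Positions are 1-based and always refer to the
target string, not the response.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

__all__ = ["positional_accuracy", "positional_summary"]


def positional_accuracy(
    records: pd.DataFrame,
    item_col: str = "item",
    response_col: str = "response",
    match_col: str = "adj_strict_match_pos",
) -> pd.DataFrame:
    """One output row per target position per input attempt.

    Adds four columns: ``position`` (1-based index into the target),
    ``element_in_item``, ``element_in_response`` (empty string where the
    response is shorter than the target) and ``correct_pos`` (the binary
    digit of the adjusted match string).  All input columns are retained as
    identifiers.
    """
    for col, name in (
        (item_col, "item_col"),
        (response_col, "response_col"),
        (match_col, "match_col"),
    ):
        if col not in records.columns:
            raise ConfigurationError(f"{name} {col!r} not found in table")

    rows: list[dict[str, object]] = []
    for idx, source in records.iterrows():
        item = str(source[item_col]).strip()
        response = "" if pd.isna(source[response_col]) else str(source[response_col]).strip()
        match = str(source[match_col])
        if len(match) != len(item):
            raise DataIntegrityError(
                f"row {idx}: match string length {len(match)} does not equal "
                f"item length {len(item)}"
            )
        for pos in range(len(item)):
            row = dict(source)
            row["position"] = pos + 1
            row["element_in_item"] = item[pos]
            row["element_in_response"] = response[pos] if pos < len(response) else ""
            row["correct_pos"] = int(match[pos])
            rows.append(row)
    columns = [*records.columns, "position", "element_in_item", "element_in_response", "correct_pos"]
    return pd.DataFrame(rows, columns=columns)


def positional_summary(
    positions: pd.DataFrame, by: Sequence[str] = ("position",)
) -> pd.DataFrame:
    """Proportion of correctly produced elements per group.

    ``by`` lists the grouping columns (typically including ``position``).
    Returns one row per observed group with ``n``, ``n_correct`` and
    ``proportion = n_correct / n``; groups that are empty after upstream
    filtering simply do not appear.
    """
    if positions.empty:
        raise ConfigurationError("positional_summary requires a non-empty table")
    missing = [c for c in by if c not in positions.columns]
    if missing:
        raise ConfigurationError(f"unknown grouping columns: {missing}")
    grouped = positions.groupby(list(by), sort=True)["correct_pos"]
    out = grouped.agg(n="size", n_correct="sum").reset_index()
    out["proportion"] = out["n_correct"] / out["n"]
    return out
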