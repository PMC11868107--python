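"""Reshaping raw assessment tables into one row per production attempt.

Clinical transcriptions often pack several successive attempts at one
stimulus into a single response cell ("talablo, talabro, talabro, taladro,
taladro" for *taladro*), as happens with conduites d'approche in conduction
aphasia.  :func:`separate_responses` splits such cells into attempt columns
and :func:`get_attempts` pivots them to long format, annotating each row
with an RA flag (was the source cell a repeated attempt?) and a 1-based
attempt index.
"""

from __future__ import annotations

import re

import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

__all__ = ["separate_responses", "get_attempts"]

_ATTEMPT_COL = re.compile(r"^attempt_(\d+)$")


def _is_blank(s: str) -> bool:
    return not s.strip()


def separate_responses(
    records: pd.DataFrame,
    response_col: str = "response",
    delimiter: str = ", ",
) -> pd.DataFrame:
    """Split multi-attempt response cells into ``attempt_1..attempt_K`` columns.

    The delimiter is a literal string (default ``", "``), not a pattern;
    attempts are trimmed of leading/trailing whitespace.  K is the maximum
    attempt count in the table; shorter cells leave their trailing attempt
    columns empty.  All other columns are preserved and the original
    response column is replaced by the attempt columns.
    """
    if not delimiter:
        raise ConfigurationError("delimiter must be a non-empty string")
    if response_col not in records.columns:
        raise ConfigurationError(f"response column {response_col!r} not found in table")

    cells = records[response_col].fillna("").astype(str)
    split = [[part.strip() for part in cell.split(delimiter)] for cell in cells]
    k = max((len(parts) for parts in split), default=1)
    out = records.drop(columns=[response_col]).copy()
    for idx in range(k):
        out[f"attempt_{idx + 1}"] = [
            parts[idx] if idx < len(parts) else "" for parts in split
        ]
    return out


def get_attempts(wide: pd.DataFrame, drop_blank: bool = True) -> pd.DataFrame:
    """Pivot ``attempt_*`` columns to long format, one row per attempt.

    Adds three columns: ``response`` (the single attempt), ``RA`` (1 when
    the source cell held two or more non-blank attempts, 0 otherwise) and
    ``attempt`` (1..k in original left-to-right order).

    With ``drop_blank`` (the recommended setting), blank attempts are
    removed before numbering, so attempt indices count only retained
    attempts; a cell with no non-blank attempt disappears entirely.
    Without it, interior blanks are kept as rows and a fully blank cell
    yields a single empty-response row (RA = 0, attempt = 1), which is how
    no-response items survive into error classification.
    """
    numbered = sorted(
        (
            (int(m.group(1)), col)
            for col in wide.columns
            if (m := _ATTEMPT_COL.match(col))
        ),
    )
    if not numbered:
        raise DataIntegrityError(
            "no attempt_N columns found; run separate_responses first"
        )
    attempt_cols = [col for _, col in numbered]
    id_cols = [c for c in wide.columns if c not in attempt_cols]

    rows: list[dict[str, object]] = []
    for _, source in wide.iterrows():
        values = [str(source[c]) if pd.notna(source[c]) else "" for c in attempt_cols]
        values = [v.strip() for v in values]
        nonblank = [v for v in values if v]
        ra = 1 if len(nonblank) >= 2 else 0
        if drop_blank:
            retained = nonblank
        else:
            # Trailing blanks are padding from separate_responses, not
            # attempts; interior blanks are genuine.
            last = max((i for i, v in enumerate(values) if v), default=-1)
            retained = values[: last + 1] if last >= 0 else [""]
        for number, attempt in enumerate(retained, start=1):
            row = {c: source[c] for c in id_cols}
            row["response"] = attempt
            row["RA"] = ra
            row["attempt"] = number
            rows.append(row)

    out = pd.DataFrame(rows, columns=[*id_cols, "response", "RA", "attempt"])
    return out.reset_index(drop=True)
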