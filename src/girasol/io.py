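"""Table reading and writing.

Tables are UTF-8 CSV or TSV with a header row; the delimiter is detected
from the file extension (``.tsv``/``.tab`` → tab) and can be overridden.
All cells are read as text — numeric typing is applied downstream where a
stage needs it — and every string cell and header is NFC-normalized so
that IPA transcriptions compare by code point regardless of how the file
was composed.
"""

from __future__ import annotations

import csv
import unicodedata
from pathlib import Path

import pandas as pd

from .errors import FormatError

__all__ = ["read_table", "write_table"]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise FormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a delimited text table with all values as NFC-normalized text."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header:
        raise FormatError(f"{path}: empty file or missing header row")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicated header columns {dupes}")

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    df.columns = [unicodedata.normalize("NFC", c) for c in df.columns]
    for col in df.columns:
        df[col] = df[col].map(lambda s: unicodedata.normalize("NFC", s))
    return df


def write_table(df: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a table as UTF-8 CSV/TSV (delimiter from extension or dialect)."""
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path, dialect), index=False, encoding="utf-8")
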