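"""Lexicality checking: is a produced string a real word?

Two criteria are supported, mirroring common practice with Spanish
resources (a dictionary wordlist such as the RAE list, or a frequency
database such as BPal):

* ``"dictionary"`` — the response is lexical iff it is in the wordlist.
* ``"database"`` — the response is lexical iff it is in the frequency
  lexicon AND its log10 frequency is strictly higher than the target
  item's.  This makes lexicality depend on the target: the same response
  can be lexical for a rare item and non-lexical for a frequent one.  The
  rule is implemented as stated by its users; the asymmetry is deliberate.

Lookups are case-folded and NFC-normalized.  When the *item* itself is
absent from the frequency lexicon its frequency is treated as −∞ (any
listed response counts as lexical) and a note is recorded, so a real-word
response is never silently excluded because the target is missing from the
resource.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = ["Wordlist", "FrequencyLexicon", "check_lexicality"]


def _norm(word: str) -> str:
    return unicodedata.normalize("NFC", word.strip().casefold())


@dataclass(frozen=True)
class Wordlist:
    """A set of real-word forms, stored case-folded and NFC-normalized."""

    entries: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("wordlist is empty")
        bad = [w for w in self.entries if any(ch.isspace() for ch in w)]
        if bad:
            raise ConfigurationError(f"wordlist entries contain whitespace: {bad[:5]}")

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "Wordlist":
        return cls(frozenset(_norm(w) for w in words if w.strip()))

    @classmethod
    def from_file(cls, path: str | Path) -> "Wordlist":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_words(text.splitlines())

    def __contains__(self, word: str) -> bool:
        return _norm(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class FrequencyLexicon:
    """Word → log10 frequency mapping (e.g. the LOG10_FRQ of BPal)."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ConfigurationError("frequency lexicon is empty")
        bad = {w: f for w, f in self.frequencies.items() if not math.isfinite(f)}
        if bad:
            raise ConfigurationError(f"non-finite frequencies: {bad}")

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, float] | Iterable[tuple[str, float]]) -> "FrequencyLexicon":
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        out: dict[str, float] = {}
        for word, freq in items:
            key = _norm(word)
            if key in out:
                raise ConfigurationError(f"duplicate lexicon word: {word!r}")
            out[key] = float(freq)
        return cls(out)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyLexicon":
        df = pd.read_csv(path, dtype={"word": str})
        if not {"word", "log10_frq"}.issubset(df.columns):
            raise FormatError(
                f"{path}: frequency lexicon needs columns 'word' and 'log10_frq'"
            )
        return cls.from_pairs(zip(df["word"], df["log10_frq"].astype(float)))

    def get(self, word: str) -> float | None:
        return self.frequencies.get(_norm(word))

    def __contains__(self, word: str) -> bool:
        return _norm(word) in self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)


def check_lexicality(
    records: pd.DataFrame,
    item_col: str = "item",
    response_col: str = "response",
    criterion: str = "dictionary",
    resource: Wordlist | FrequencyLexicon | None = None,
) -> pd.DataFrame:
    """Add a binary ``lexicality`` column (plus ``lexicality_note``).

    See the module docstring for the two criteria.  Empty/missing
    responses are non-lexical with a "no response" note.
    """
    if criterion not in ("dictionary", "database"):
        raise ConfigurationError(
            f"unknown lexicality criterion {criterion!r}; use 'dictionary' or 'database'"
        )
    expected = Wordlist if criterion == "dictionary" else FrequencyLexicon
    if not isinstance(resource, expected):
        raise ConfigurationError(
            f"criterion {criterion!r} requires a {expected.__name__} resource, "
            f"got {type(resource).__name__}"
        )
    for col, name in ((item_col, "item_col"), (response_col, "response_col")):
        if col not in records.columns:
            raise ConfigurationError(f"{name} {col!r} not found in table")

    flags: list[int] = []
    notes: list[str] = []
    items = records[item_col].fillna("").astype(str)
    responses = records[response_col].fillna("").astype(str)
    for item, response in zip(items, responses):
        response = response.strip()
        if not response:
            flags.append(0)
            notes.append("no response")
            continue
        note = ""
        if criterion == "dictionary":
            lexical = int(response in resource)
        else:
            freq_response = resource.get(response)
            if freq_response is None:
                lexical = 0
            else:
                freq_item = resource.get(item)
                if freq_item is None:
                    freq_item = -math.inf
                    note = "item not in frequency lexicon"
                lexical = int(freq_response > freq_item)
        flags.append(lexical)
        notes.append(note)

    out = records.copy()
    out["lexicality"] = flags
    out["lexicality_note"] = notes
    return out
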