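"""Formal-similarity indexes between target and response strings.

The scoring unit is the Unicode code point: an IPA affricate written as two
code points (``d`` + ``ʒ``) counts as two characters, and combining
diacritics are not folded away (tables should be NFC-normalized on read,
which :func:`girasol.io.read_table` does).  Stress and syllable marks in
broad phonemic transcriptions are removed explicitly with
:func:`strip_phonemic_marks`; no scoring function strips them silently.

The index battery mirrors standard practice in single-word production
research: a shared-character proportion (the psl/psp statistic), positional
match strings, Levenshtein / Damerau–Levenshtein / Jaro–Winkler distances,
the longest common subsequence, an alignment trace, and the proportion of
correct characters (pcc) together with its across-attempt change
(approach_diff) for repeated-attempt sequences such as conduites d'approche.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError, UndefinedInputError

__all__ = [
    "strip_phonemic_marks",
    "shared_char_proportion",
    "positional_match",
    "levenshtein",
    "damerau_levenshtein",
    "jaro_winkler_distance",
    "edit_distances",
    "lcs_string",
    "lcs_substring",
    "similarity_trace",
    "pcc",
    "compute_formal_indexes",
    "FORMAL_INDEX_COLUMNS",
]

#: Marks removed from broad phonemic transcriptions before scoring:
#: primary stress, secondary stress, syllable separator.
PHONEMIC_MARKS = "ˈˌ."

#: Output columns added by :func:`compute_formal_indexes`, in order.
FORMAL_INDEX_COLUMNS = [
    "targetL",
    "responseL",
    "p_shared_char",
    "p_shared_char_in_pos",
    "diff_char_num",
    "Ld",
    "DLd",
    "JWd",
    "pcc",
    "lcs",
    "similarity_str",
    "shared1char",
    "strict_match_pos",
    "adj_strict_match_pos",
    "comment_warning",
    "approach_diff",
]

RA_WARNING = "response contains spaces or commas; could indicate repeated attempts (RA)"


def strip_phonemic_marks(s: str, marks: str = PHONEMIC_MARKS) -> str:
    """Remove stress and syllable-separation marks from a transcription."""
    return "".join(ch for ch in s if ch not in marks)


def shared_char_proportion(target: str, response: str) -> float:
    """Percent of characters shared between two strings (psl / psp).

    Computed as ``2·SL / (NLt + NLr) · 100`` where SL is the size of the
    multiset intersection of the two character bags and NLt, NLr are the
    string lengths.  Order-independent and symmetric.

    >>> round(shared_char_proportion("development", "intelligence"), 2)
    52.17
    """
    if not target or not response:
        raise UndefinedInputError(
            "shared_char_proportion is undefined for empty strings"
        )
    shared = sum((Counter(target) & Counter(response)).values())
    return 2.0 * shared / (len(target) + len(response)) * 100.0


def positional_match(target: str, response: str) -> tuple[str, str, float]:
    """Position-by-position match strings and the positional-accuracy percent.

    Returns ``(strict_match_pos, adj_strict_match_pos, p_shared_char_in_pos)``.
    The strict string spans ``max(len(target), len(response))`` positions
    (1 where both strings have that position and the characters agree); the
    adjusted string is cut or padded to exactly the target's length, which
    is the reference unit for positional accuracy.  The percent is the
    share of 1s in the adjusted string.
    """
    if not target:
        raise UndefinedInputError("positional_match requires a non-empty target")
    span = max(len(target), len(response))
    strict = "".join(
        "1" if i < len(target) and i < len(response) and target[i] == response[i] else "0"
        for i in range(span)
    )
    adj = strict[: len(target)].ljust(len(target), "0")
    pct = 100.0 * adj.count("1") / len(target)
    return strict, adj, pct


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b``."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def damerau_levenshtein(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein distance.

    Adds adjacent transposition to the Levenshtein edit set.  This is the
    full (Lowrance–Wagner) variant: a transposed pair may be edited again
    later, unlike the optimal-string-alignment restriction, so e.g.
    ``damerau_levenshtein("ca", "abc") == 2``.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    inf = la + lb
    # d is (la+2) x (lb+2) with a sentinel row/column of `inf`.
    d = [[inf] * (lb + 2) for _ in range(la + 2)]
    for i in range(la + 1):
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[1][j + 1] = j
    last_row: dict[str, int] = {}
    for i in range(1, la + 1):
        last_col = 0
        for j in range(1, lb + 1):
            k = last_row.get(b[j - 1], 0)
            l = last_col
            if a[i - 1] == b[j - 1]:
                cost = 0
                last_col = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,  # substitution / match
                d[i + 1][j] + 1,  # insertion
                d[i][j + 1] + 1,  # deletion
                d[k][l] + (i - k - 1) + 1 + (j - l - 1),  # transposition
            )
        last_row[a[i - 1]] = i
    return d[la + 1][lb + 1]


def jaro_winkler_distance(a: str, b: str) -> float:
    """Jaro–Winkler distance: 0 for identical strings, 1 for no similarity.

    Standard parameters: prefix scaling 0.1, prefix length capped at 4,
    no boost threshold.
    """
    return 1.0 - _jaro_winkler_similarity(a, b)


def _jaro_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    matched_a = [False] * la
    matched_b = [False] * lb
    matches = 0
    for i in range(la):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not matched_b[j] and a[i] == b[j]:
                matched_a[i] = matched_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    b_matches = [b[j] for j in range(lb) if matched_b[j]]
    transpositions = sum(
        1 for ai, bj in zip((a[i] for i in range(la) if matched_a[i]), b_matches) if ai != bj
    )
    t = transpositions // 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3.0


def _jaro_winkler_similarity(a: str, b: str, p: float = 0.1, max_prefix: int = 4) -> float:
    jaro = _jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == max_prefix:
            break
        prefix += 1
    return jaro + prefix * p * (1.0 - jaro)


def edit_distances(target: str, response: str) -> tuple[int, int, float]:
    """``(Ld, DLd, JWd)`` for one target/response pair.

    Empty strings are allowed: the distance to an empty string is the other
    string's length (JWd = 1 unless both are empty).
    """
    return (
        levenshtein(target, response),
        damerau_levenshtein(target, response),
        jaro_winkler_distance(target, response),
    )


def _lcs_table(target: str, response: str) -> list[list[int]]:
    # L[i][j] = LCS length of target[i:] and response[j:]
    n, m = len(target), len(response)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if target[i] == response[j]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    return L


def lcs_string(target: str, response: str) -> str:
    """One longest common subsequence of the two strings.

    Among equal-length candidates the tie-break is deterministic: the
    subsequence whose matched target indices are lexicographically smallest
    (leftmost backtrace).  Achieved by consuming response characters first
    whenever doing so preserves the optimal length, so target characters
    are matched as early as possible.
    """
    L = _lcs_table(target, response)
    i = j = 0
    out: list[str] = []
    n, m = len(target), len(response)
    while i < n and j < m:
        if target[i] == response[j]:
            out.append(target[i])
            i += 1
            j += 1
        elif L[i][j + 1] == L[i][j]:
            j += 1
        else:
            i += 1
    return "".join(out)


def lcs_substring(target: str, response: str) -> str:
    """Longest common contiguous substring of the two strings.

    This is the quantity reported in the ``lcs`` column of the index
    battery: for *mangrove*/*mango* it is ``"mang"`` — the run breaks at
    the fifth character — whereas the longest common subsequence
    (:func:`lcs_string`) is ``"mango"``.  Ties go to the earliest start
    position in the target.
    """
    n, m = len(target), len(response)
    best_len, best_start = 0, 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if target[i - 1] == response[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len = cur[j]
                    best_start = i - cur[j]
        prev = cur
    return target[best_start : best_start + best_len]


def similarity_trace(target: str, response: str) -> str:
    """Alignment trace over {M, D, S, I} from a minimal Levenshtein script.

    One symbol per edit-script step reading the target left to right:
    M match, S substitution, D deletion (target character absent from the
    response), I insertion (response character absent from the target).
    At equal cost the priority is M > S > D > I, which fixes the trace.
    The counts satisfy #M+#S+#D = len(target) and #M+#S+#I = len(response),
    and #S+#D+#I equals the Levenshtein distance.
    """
    n, m = len(target), len(response)
    # D[i][j] = Levenshtein distance between target[i:] and response[j:]
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][m] = n - i
    for j in range(m + 1):
        D[n][j] = m - j
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            D[i][j] = min(
                D[i + 1][j + 1] + (target[i] != response[j]),
                D[i + 1][j] + 1,
                D[i][j + 1] + 1,
            )
    i = j = 0
    out: list[str] = []
    while i < n or j < m:
        here = D[i][j]
        if i < n and j < m and target[i] == response[j] and here == D[i + 1][j + 1]:
            out.append("M")
            i += 1
            j += 1
        elif i < n and j < m and here == D[i + 1][j + 1] + 1:
            out.append("S")
            i += 1
            j += 1
        elif i < n and here == D[i + 1][j] + 1:
            out.append("D")
            i += 1
        else:
            out.append("I")
            j += 1
    return "".join(out)


def pcc(target: str, response: str) -> float:
    """Proportion of correct characters: ``1 − DLd/len(target)``, floored at 0.

    The target length is the reference unit (as in the adjusted match
    string); flooring keeps the index in [0, 1] when the response is much
    longer or entirely different.
    """
    if not target:
        raise UndefinedInputError("pcc requires a non-empty target")
    return max(0.0, 1.0 - damerau_levenshtein(target, response) / len(target))


def _row_indexes(target: str, response: str) -> dict[str, object]:
    """All per-row formal indexes for one (target, response) pair."""
    target = target.strip()
    response = "" if response is None else str(response).strip()
    if not target:
        raise UndefinedInputError("item string is empty")
    strict, adj, in_pos = positional_match(target, response)
    ld, dld, jwd = edit_distances(target, response)
    return {
        "targetL": len(target),
        "responseL": len(response),
        "p_shared_char": (
            shared_char_proportion(target, response) if response else np.nan
        ),
        "p_shared_char_in_pos": in_pos,
        "diff_char_num": len(target) - len(response),
        "Ld": ld,
        "DLd": dld,
        "JWd": jwd,
        "pcc": max(0.0, 1.0 - dld / len(target)),
        "lcs": lcs_substring(target, response),
        "similarity_str": similarity_trace(target, response),
        "shared1char": bool(response) and target[0] == response[0],
        "strict_match_pos": strict,
        "adj_strict_match_pos": adj,
        "comment_warning": RA_WARNING if (" " in response or "," in response) else "",
    }


def compute_formal_indexes(
    records: pd.DataFrame,
    item_col: str = "item",
    response_col: str = "response",
    attempt_col: str | None = None,
    group_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Augment a long-format attempt table with the formal index battery.

    Every row gains the Table-of-indexes columns (targetL … comment_warning).
    When ``attempt_col`` is given, ``group_cols`` must identify one
    repeated-attempt sequence together with the item (participant and item
    identifiers at minimum): ``approach_diff`` is then the change in pcc
    between consecutive attempts within each ``group_cols`` × item
    partition, ordered by attempt and missing for the first attempt.  When
    ``attempt_col`` is omitted the approach_diff column is omitted too.
    """
    for col, name in ((item_col, "item_col"), (response_col, "response_col")):
        if col not in records.columns:
            raise ConfigurationError(f"{name} {col!r} not found in table")
    if attempt_col is not None:
        if not group_cols:
            raise ConfigurationError(
                "attempt_col requires group_cols identifying each attempt sequence"
            )
        missing = [c for c in (attempt_col, *group_cols) if c not in records.columns]
        if missing:
            raise ConfigurationError(f"columns not found in table: {missing}")

    out = records.copy()
    responses = out[response_col].fillna("").astype(str)
    computed = [
        _row_indexes(item, resp)
        for item, resp in zip(out[item_col].astype(str), responses)
    ]
    block = pd.DataFrame(computed, index=out.index)
    for col in FORMAL_INDEX_COLUMNS:
        if col in block.columns:
            out[col] = block[col]

    if attempt_col is not None:
        keys = [*group_cols, item_col]
        dup = out.duplicated(subset=[*keys, attempt_col], keep=False)
        if dup.any():
            offending = (
                out.loc[dup, [*keys, attempt_col]]
                .drop_duplicates()
                .to_dict("records")
            )
            raise DataIntegrityError(
                f"duplicate (group, attempt) keys: {offending[:5]}"
            )
        attempts = pd.to_numeric(out[attempt_col])
        ordered = out.assign(_attempt=attempts).sort_values("_attempt", kind="stable")
        out["approach_diff"] = (
            ordered.groupby(keys, sort=False, dropna=False)["pcc"]
            .diff()
            .reindex(out.index)
        )
    return out
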