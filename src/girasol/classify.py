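"""Seven-way classification of single-word production errors.

Each attempt is sorted into one of: no response, nonword (phonemic),
neologism, formal, unrelated, semantic, mixed — the standard paraphasia
taxonomy — from three pieces of evidence computed upstream:

* lexicality (is the response a real word?),
* formal similarity (the shared-character proportion ``p_shared_char`` and
  the shared-first-character flag), and
* semantic similarity (the embedding cosine ``w2v_cos``).

Decision tree, applied only to erroneous attempts (``accessed`` = 0 and a
non-identical response):

1. blank response → **no response**;
2. nonword: shared proportion ≥ threshold (default 50%) → **nonword
   (phonemic)**, otherwise → **neologism**;
3. real word: formally related := shared proportion ≥ threshold OR same
   first character; semantically related := cosine present AND ≥ the
   cosine threshold (default 0.46).  Both → **mixed**; only formal →
   **formal**; only semantic → **semantic**; neither → **unrelated**.

Threshold ties count as related (the criteria read "at least").  A row the
tree cannot place (e.g. missing lexicality or shared proportion) receives
no category and ``check_comment = "required"`` so it can be resolved by
hand; a missing cosine alone does not trigger "required" — it is treated
as "not semantically related" and recorded in ``classifier_note``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, PipelineOrderError

__all__ = [
    "ClassifierConfig",
    "CATEGORY_COLUMNS",
    "classify_single",
    "classify_errors",
    "classify_errors_regular",
]

#: Category columns, in output order.
CATEGORY_COLUMNS = [
    "no_response",
    "nonword",
    "neologism",
    "formal",
    "unrelated",
    "semantic",
    "mixed",
]

RA_ONLY_COMMENT = "is only considered as RA"
REQUIRED_COMMENT = "required"


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the error taxonomy.

    cosine_limit_value: minimum embedding cosine for "semantically
        related", in the model's cosine range (default 0.46, appropriate
        for models whose cosines live in [0, 1]; raise toward ~0.55 for a
        stricter criterion, adjust if the model's range is [−1, 1]).
    formal_threshold: minimum shared-character percentage for "formally
        related" (default 50).
    also_classify_RAs: whether attempts inside repeated-attempt sequences
        are classified like any other attempt (default) or left with the
        comment "is only considered as RA".
    """

    cosine_limit_value: float = 0.46
    formal_threshold: float = 50.0
    also_classify_RAs: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.formal_threshold <= 100.0):
            raise ConfigurationError("formal_threshold must be in (0, 100]")
        if not (-1.0 <= self.cosine_limit_value <= 1.0):
            raise ConfigurationError("cosine_limit_value must be within [-1, 1]")


@dataclass
class ErrorClassification:
    """Outcome for one attempt: binary category indicators plus audit flags."""

    categories: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORY_COLUMNS}
    )
    check_comment: str = ""
    note: str = ""

    @property
    def category(self) -> str | None:
        fired = [c for c, v in self.categories.items() if v]
        return fired[0] if len(fired) == 1 else None


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_single(
    item: str,
    response: str,
    accessed: int | None,
    lexicality: int | None,
    p_shared_char: float | None,
    shared1char: bool | None,
    w2v_cos: float | None,
    config: ClassifierConfig | None = None,
) -> ErrorClassification:
    """Classify one attempt; see the module docstring for the tree.

    ``accessed`` marks a correct production (1); when missing it falls
    back to string equality of item and response.  Correct productions
    receive no category.
    """
    config = config or ClassifierConfig()
    out = ErrorClassification()
    response = "" if response is None else str(response).strip()
    item = "" if item is None else str(item).strip()

    if not response:
        out.categories["no_response"] = 1
        return out
    correct = (accessed == 1) if not _missing(accessed) else (item == response)
    if correct or item == response:
        return out

    if _missing(lexicality):
        out.check_comment = REQUIRED_COMMENT
        out.note = "lexicality missing"
        return out
    if _missing(p_shared_char):
        out.check_comment = REQUIRED_COMMENT
        out.note = "p_shared_char missing"
        return out

    if not lexicality:
        if p_shared_char >= config.formal_threshold:
            out.categories["nonword"] = 1
        else:
            out.categories["neologism"] = 1
        return out

    formally = p_shared_char >= config.formal_threshold or bool(shared1char)
    if _missing(w2v_cos):
        semantically = False
        out.note = "cosine similarity missing (out of vocabulary)"
    else:
        semantically = w2v_cos >= config.cosine_limit_value
    if formally and semantically:
        out.categories["mixed"] = 1
    elif formally:
        out.categories["formal"] = 1
    elif semantically:
        out.categories["semantic"] = 1
    else:
        out.categories["unrelated"] = 1
    return out


_PREREQUISITES = {
    "p_shared_char": "compute_formal_indexes",
    "shared1char": "compute_formal_indexes",
    "lexicality": "check_lexicality",
    "w2v_cos": "get_semantic_similarity",
}


def _check_pipeline_order(records: pd.DataFrame) -> None:
    missing = {
        col: stage for col, stage in _PREREQUISITES.items() if col not in records.columns
    }
    if missing:
        steps = ", ".join(sorted(set(missing.values())))
        raise PipelineOrderError(
            f"columns {sorted(missing)} are missing; run {steps} before classification"
        )


def _classify_table(
    records: pd.DataFrame,
    access_col: str | None,
    RA_col: str | None,
    item_col: str,
    response_col: str,
    also_classify_RAs: bool,
    config: ClassifierConfig,
) -> pd.DataFrame:
    _check_pipeline_order(records)
    for col, name in ((item_col, "item_col"), (response_col, "response_col")):
        if col not in records.columns:
            raise ConfigurationError(f"{name} {col!r} not found in table")
    if access_col is not None and access_col not in records.columns:
        raise ConfigurationError(f"access_col {access_col!r} not found in table")
    if RA_col is not None and RA_col not in records.columns:
        raise ConfigurationError(f"RA_col {RA_col!r} not found in table")

    out = records.copy()
    results: list[ErrorClassification] = []
    for _, row in out.iterrows():
        if RA_col is not None and not also_classify_RAs and row[RA_col] == 1:
            skipped = ErrorClassification()
            skipped.check_comment = RA_ONLY_COMMENT
            results.append(skipped)
            continue
        accessed = row[access_col] if access_col is not None else None
        if not _missing(accessed):
            accessed = int(accessed)
        results.append(
            classify_single(
                item=row[item_col],
                response=row[response_col],
                accessed=accessed,
                lexicality=None if _missing(row["lexicality"]) else int(row["lexicality"]),
                p_shared_char=row["p_shared_char"],
                shared1char=row["shared1char"],
                w2v_cos=row["w2v_cos"],
                config=config,
            )
        )
    for col in CATEGORY_COLUMNS:
        out[col] = [r.categories[col] for r in results]
    out["check_comment"] = [r.check_comment for r in results]
    out["classifier_note"] = [r.note for r in results]

    # Safety net: an erroneous attempt must land in exactly one category.
    fired = out[CATEGORY_COLUMNS].sum(axis=1)
    ambiguous = (fired > 1) | (
        (fired == 0)
        & (out["check_comment"] == "")
        & ~_correct_mask(out, access_col, item_col, response_col)
    )
    out.loc[ambiguous, "check_comment"] = REQUIRED_COMMENT
    return out


def _correct_mask(
    records: pd.DataFrame, access_col: str | None, item_col: str, response_col: str
) -> pd.Series:
    items = records[item_col].fillna("").astype(str).str.strip()
    responses = records[response_col].fillna("").astype(str).str.strip()
    equal = items == responses
    if access_col is None:
        return equal
    accessed = pd.to_numeric(records[access_col], errors="coerce")
    return equal | (accessed == 1)


def classify_errors(
    records: pd.DataFrame,
    access_col: str = "accessed",
    RA_col: str = "RA",
    item_col: str = "item",
    response_col: str = "response",
    also_classify_RAs: bool = True,
    cosine_limit_value: float | None = None,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify every attempt of a long-format table, RA-aware.

    Requires the upstream columns ``p_shared_char``/``shared1char``
    (formal indexes), ``lexicality`` and ``w2v_cos``; a missing column
    raises a pipeline-order error naming the stage to run.  With
    ``also_classify_RAs=False``, rows inside repeated-attempt sequences
    (``RA`` = 1) are left unclassified with the comment
    "is only considered as RA".
    """
    config = config or ClassifierConfig()
    if cosine_limit_value is not None:
        config = ClassifierConfig(
            cosine_limit_value=cosine_limit_value,
            formal_threshold=config.formal_threshold,
            also_classify_RAs=also_classify_RAs,
        )
    return _classify_table(
        records, access_col, RA_col, item_col, response_col, also_classify_RAs, config
    )


def classify_errors_regular(
    records: pd.DataFrame,
    access_col: str | None = None,
    item_col: str = "item",
    response_col: str = "response",
    cosine_limit_value: float | None = None,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify a table of single responses, ignoring RA structure.

    When ``access_col`` is omitted, correctness is derived from string
    equality of item and response.  On RA = 0 rows this is equivalent to
    :func:`classify_errors` with ``also_classify_RAs=True``.
    """
    config = config or ClassifierConfig()
    if cosine_limit_value is not None:
        config = ClassifierConfig(
            cosine_limit_value=cosine_limit_value,
            formal_threshold=config.formal_threshold,
        )
    if records.empty:
        out = records.copy()
        for col in CATEGORY_COLUMNS:
            out[col] = pd.Series(dtype=int)
        out["check_comment"] = pd.Series(dtype=str)
        out["classifier_note"] = pd.Series(dtype=str)
        return out
    return _classify_table(
        records, access_col, None, item_col, response_col, True, config
    )
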