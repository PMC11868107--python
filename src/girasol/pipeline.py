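"""End-to-end pipeline: wrangle → score → lexicality → semantics → classify.

Running the stages through :func:`run_pipeline` is exactly equivalent to
calling them one by one — each stage is a pure function of its input table
and the configuration, with no hidden state — so stacked and stepwise
executions produce identical tables.  Per-stage row counts and audit-flag
tallies are logged for review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import ClassifierConfig, classify_errors
from .errors import ConfigurationError
from .formal import compute_formal_indexes
from .io import read_table
from .lexicality import FrequencyLexicon, Wordlist, check_lexicality
from .semantics import EmbeddingStore, get_semantic_similarity, load_embeddings
from .wrangle import get_attempts, separate_responses

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("girasol")

STAGES = ("wrangle", "formal", "lexicality", "semantics", "classify")


@dataclass
class PipelineConfig:
    """Column bindings, thresholds and resources for a full run.

    ``stop_after`` truncates the pipeline ("wrangle" yields the long
    format only, "formal" adds the index battery, "classify" runs
    everything).  Resources may be given as loaded objects or as file
    paths (wordlist: one word per line; frequency lexicon: CSV with
    ``word, log10_frq``; embeddings: word2vec text format).
    """

    response_col: str = "response"
    item_col: str = "item"
    delimiter: str = ", "
    drop_blank: bool = True
    attempt_col: str = "attempt"
    group_cols: tuple[str, ...] = ("ID", "item_ID")
    access_col: str = "accessed"
    RA_col: str = "RA"
    lexicality_criterion: str = "dictionary"
    wordlist: Wordlist | str | Path | None = None
    freq_lexicon: FrequencyLexicon | str | Path | None = None
    embeddings: EmbeddingStore | str | Path | None = None
    cosine_limit_value: float = 0.46
    formal_threshold: float = 50.0
    also_classify_RAs: bool = True
    stop_after: str = "classify"

    def __post_init__(self) -> None:
        if self.stop_after not in STAGES:
            raise ConfigurationError(
                f"stop_after must be one of {STAGES}, got {self.stop_after!r}"
            )
        bound = [self.response_col, self.item_col, self.attempt_col, *self.group_cols]
        if len(set(bound)) != len(bound):
            raise ConfigurationError(f"bound column names must be distinct: {bound}")

    def lexical_resource(self) -> Wordlist | FrequencyLexicon:
        if self.lexicality_criterion == "dictionary":
            if self.wordlist is None:
                raise ConfigurationError(
                    "lexicality stage: dictionary criterion requires a wordlist"
                )
            if isinstance(self.wordlist, Wordlist):
                return self.wordlist
            return Wordlist.from_file(self.wordlist)
        if self.lexicality_criterion == "database":
            if self.freq_lexicon is None:
                raise ConfigurationError(
                    "lexicality stage: database criterion requires a frequency lexicon"
                )
            if isinstance(self.freq_lexicon, FrequencyLexicon):
                return self.freq_lexicon
            return FrequencyLexicon.from_csv(self.freq_lexicon)
        raise ConfigurationError(
            f"unknown lexicality criterion {self.lexicality_criterion!r}"
        )

    def embedding_store(self) -> EmbeddingStore:
        if self.embeddings is None:
            raise ConfigurationError(
                "semantics stage: classification requires an embedding table"
            )
        if isinstance(self.embeddings, EmbeddingStore):
            return self.embeddings
        return load_embeddings(self.embeddings, format="word2vec-text")


def run_pipeline(
    data: pd.DataFrame | str | Path, config: PipelineConfig
) -> pd.DataFrame:
    """Run the pipeline on a raw table (or a path to one).

    Stage order is fixed: separate_responses → get_attempts →
    compute_formal_indexes → check_lexicality → get_semantic_similarity →
    classify_errors.  The result equals running the stages individually
    with the same parameters.
    """
    df = read_table(data) if isinstance(data, (str, Path)) else data

    wide = separate_responses(df, config.response_col, config.delimiter)
    long = get_attempts(wide, drop_blank=config.drop_blank)
    log.info("wrangle: %d source rows -> %d attempts", len(df), len(long))
    if config.stop_after == "wrangle":
        return long

    scored = compute_formal_indexes(
        long,
        item_col=config.item_col,
        response_col="response",
        attempt_col=config.attempt_col,
        group_cols=list(config.group_cols),
    )
    n_warn = int((scored["comment_warning"] != "").sum())
    log.info("formal: %d rows scored, %d comment warnings", len(scored), n_warn)
    if config.stop_after == "formal":
        return scored

    checked = check_lexicality(
        scored,
        item_col=config.item_col,
        response_col="response",
        criterion=config.lexicality_criterion,
        resource=config.lexical_resource(),
    )
    log.info("lexicality: %d lexical responses", int(checked["lexicality"].sum()))
    if config.stop_after == "lexicality":
        return checked

    with_cos = get_semantic_similarity(
        checked,
        item_col=config.item_col,
        response_col="response",
        store=config.embedding_store(),
    )
    if config.stop_after == "semantics":
        return with_cos

    classified = classify_errors(
        with_cos,
        access_col=config.access_col,
        RA_col=config.RA_col,
        item_col=config.item_col,
        response_col="response",
        also_classify_RAs=config.also_classify_RAs,
        config=ClassifierConfig(
            cosine_limit_value=config.cosine_limit_value,
            formal_threshold=config.formal_threshold,
            also_classify_RAs=config.also_classify_RAs,
        ),
    )
    n_required = int((classified["check_comment"] == "required").sum())
    log.info("classify: %d rows, %d flagged 'required'", len(classified), n_required)
    return classified
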