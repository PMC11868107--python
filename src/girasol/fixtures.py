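"""Synthetic resources: toy lexicons, engineered embeddings, simulated data.

Everything a full pipeline run needs can be generated here without any
download: a wordlist and frequency lexicon, an embedding store whose
pairwise cosines are controlled exactly (so the semantic threshold can be
tested on both sides), and multi-attempt response tables whose per-attempt
error category is known by construction.

Responses are generated constructively with rejection sampling: a drawn
category's defining inequalities (lexicality, shared-character proportion,
first-character match, embedding cosine against the classifier thresholds)
are enforced at generation time by re-scoring each candidate, so the
ground-truth label is exact rather than assigned post hoc.  Strings do not
emulate Spanish phonotactics — they only need to satisfy the scoring
definitions.

Repeated-attempt cells emulate conduites d'approche: earlier attempts are
nonword distortions of the target whose expected distortion decreases
toward the final attempt (monotone-increasing expected pcc); a flag
disables the monotone schedule for negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .formal import damerau_levenshtein, shared_char_proportion
from .lexicality import FrequencyLexicon, Wordlist
from .semantics import EmbeddingStore

__all__ = [
    "SimulationSpec",
    "FixtureWorld",
    "make_toy_lexicon",
    "make_toy_embeddings",
    "make_fixture_world",
    "simulate_responses",
]

ERROR_CATEGORIES = [
    "no_response",
    "nonword",
    "neologism",
    "formal",
    "unrelated",
    "semantic",
    "mixed",
]

# Disjoint letter pools: items draw on the first, their semantically
# related / unrelated real-word companions on the second, which pins the
# shared-character proportion between pools at 0.
_POOL_A = "abcdefghijklm"
_POOL_B = "nopqrstuvwxyz"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the response simulator.

    attempts_per_item: a fixed int, or ``("geometric", p)`` for a
        geometric number of attempts (capped at 6).
    error_mix: proportions over the seven error categories; must sum to 1.
    edit_rates: relative weights of substitute/delete/insert/transpose
        when distorting strings.
    """

    n_items: int = 25
    attempts_per_item: int | tuple[str, float] = ("geometric", 0.6)
    error_mix: dict[str, float] = field(
        default_factory=lambda: {
            "no_response": 0.08,
            "nonword": 0.22,
            "neologism": 0.14,
            "formal": 0.16,
            "unrelated": 0.12,
            "semantic": 0.18,
            "mixed": 0.10,
        }
    )
    edit_rates: dict[str, float] = field(
        default_factory=lambda: {
            "substitute": 0.5,
            "delete": 0.2,
            "insert": 0.2,
            "transpose": 0.1,
        }
    )
    seed: int = 0
    cosine_limit_value: float = 0.46
    formal_threshold: float = 50.0
    monotone_cda: bool = True
    retry_cap: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.error_mix) - set(ERROR_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown error categories: {sorted(unknown)}")
        if any(not (0.0 <= p <= 1.0) for p in self.error_mix.values()):
            raise ConfigurationError("error_mix proportions must be in [0, 1]")
        if abs(sum(self.error_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("error_mix must sum to 1")
        if any(not (0.0 <= p <= 1.0) for p in self.edit_rates.values()):
            raise ConfigurationError("edit_rates must be in [0, 1]")


@dataclass(frozen=True)
class FixtureWorld:
    """A self-consistent synthetic language for end-to-end tests."""

    items: tuple[str, ...]
    wordlist: Wordlist
    lexicon: FrequencyLexicon
    embeddings: EmbeddingStore


def make_toy_lexicon(
    words: list[str],
    frequencies: list[float] | None = None,
    seed: int = 0,
) -> tuple[Wordlist, FrequencyLexicon]:
    """Build a wordlist and frequency lexicon from an explicit word list.

    Default log10 frequencies are drawn uniformly on [0, 3] (log-uniform
    in raw frequency) from a seeded generator, so resources are
    deterministic.  Duplicate words (after case folding) are rejected.
    """
    if not words:
        raise ConfigurationError("make_toy_lexicon requires at least one word")
    folded = [w.strip().casefold() for w in words]
    if len(set(folded)) != len(folded):
        dupes = sorted({w for w in folded if folded.count(w) > 1})
        raise ConfigurationError(f"duplicate words in lexicon: {dupes}")
    if frequencies is None:
        rng = np.random.default_rng(seed)
        frequencies = [float(x) for x in rng.uniform(0.0, 3.0, size=len(words))]
    elif len(frequencies) != len(words):
        raise ConfigurationError("frequencies must align with words")
    return (
        Wordlist.from_words(words),
        FrequencyLexicon.from_pairs(zip(words, frequencies)),
    )


def make_toy_embeddings(
    clusters: list[list[str]],
    within_cos: float = 0.8,
    between_cos: float = 0.1,
    seed: int = 0,
) -> EmbeddingStore:
    """Embedding store with exactly prescribed pairwise cosines.

    Words in the same cluster have pairwise cosine ``within_cos``; words
    in different clusters ``between_cos`` (requires
    ``0 ≤ between_cos < within_cos ≤ 1``, or a single cluster).  The
    construction is geometric, not sampled: each word vector is
    ``√w·h_c + √(1−w)·e_i`` with cluster axes ``h_c`` at pairwise dot
    ``between/within`` and per-word orthonormal residuals ``e_i``, then a
    seeded random rotation.  Cosines are exact up to float round-off
    (≪ 1e−6).
    """
    words = [w for cluster in clusters for w in cluster]
    if not words:
        raise ConfigurationError("clusters must contain at least one word")
    if len(set(words)) != len(words):
        raise ConfigurationError("duplicate words across clusters")
    if not (0.0 <= between_cos <= 1.0 and 0.0 < within_cos <= 1.0):
        raise ConfigurationError("cosines must lie in [0, 1]")
    if len(clusters) > 1 and between_cos >= within_cos:
        raise ConfigurationError(
            "infeasible cosine combination: need between_cos < within_cos"
        )

    n_clusters, n_words = len(clusters), len(words)
    dim = 1 + n_clusters + n_words
    gamma = between_cos / within_cos
    alpha = np.sqrt(within_cos)
    beta = np.sqrt(1.0 - within_cos)

    basis = np.eye(dim)
    vectors: dict[str, np.ndarray] = {}
    word_index = 0
    for c, cluster in enumerate(clusters):
        axis = np.sqrt(gamma) * basis[0] + np.sqrt(1.0 - gamma) * basis[1 + c]
        for w in cluster:
            residual = basis[1 + n_clusters + word_index]
            vectors[w] = alpha * axis + beta * residual
            word_index += 1

    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    q *= np.sign(np.diag(r))  # fix the sign ambiguity of QR
    return EmbeddingStore({w: v @ q.T for w, v in vectors.items()})


def _unique_word(make, taken: set[str], cap: int = 1000) -> str:
    for _ in range(cap):
        w = make()
        if w not in taken:
            taken.add(w)
            return w
    raise SimulationError("could not generate a unique word; widen the letter pools")


def make_fixture_world(
    n_items: int = 25,
    seed: int = 0,
    within_cos: float = 0.8,
    between_cos: float = 0.1,
    word_length: int = 6,
) -> FixtureWorld:
    """An engineered lexicon in which every error category is realizable.

    For each target item (letters from one pool) the lexicon also holds:
    a semantic companion (same embedding cluster, disjoint letters), a
    mixed companion (same cluster, one substitution away), a formal
    companion (different cluster, same first letter) and an unrelated
    companion (different cluster, disjoint letters).
    """
    if n_items < 1:
        raise ConfigurationError("n_items must be positive")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()

    def draw(pool: str, length: int, first: str | None = None) -> str:
        letters = rng.choice(list(pool), size=length)
        word = "".join(letters)
        return (first + word[1:]) if first is not None else word

    items, clusters = [], []
    distractors: list[str] = []
    for _ in range(n_items):
        item = _unique_word(lambda: draw(_POOL_A, word_length), taken)

        def mutate_one() -> str:
            pos = int(rng.integers(1, word_length))
            alternatives = [c for c in _POOL_A if c != item[pos]]
            ch = alternatives[int(rng.integers(len(alternatives)))]
            return item[:pos] + ch + item[pos + 1 :]

        mixed = _unique_word(mutate_one, taken)
        semantic = _unique_word(lambda: draw(_POOL_B, word_length), taken)
        formal = _unique_word(lambda: draw(_POOL_B, word_length, first=item[0]), taken)
        unrelated = _unique_word(lambda: draw(_POOL_B, word_length), taken)
        items.append(item)
        clusters.append([item, semantic, mixed])
        distractors.extend([formal, unrelated])

    clusters.append(distractors)
    words = [w for cluster in clusters for w in cluster]
    wordlist, lexicon = make_toy_lexicon(words, seed=seed)
    embeddings = make_toy_embeddings(
        clusters, within_cos=within_cos, between_cos=between_cos, seed=seed
    )
    return FixtureWorld(tuple(items), wordlist, lexicon, embeddings)


_ALPHABET = _POOL_A + _POOL_B


def _apply_edit(word: str, rng: np.random.Generator, edit_rates: dict[str, float]) -> str:
    ops = list(edit_rates)
    weights = np.array([edit_rates[o] for o in ops], dtype=float)
    if weights.sum() <= 0:
        raise ConfigurationError("edit_rates must have positive total weight")
    op = ops[int(rng.choice(len(ops), p=weights / weights.sum()))]
    if len(word) == 0:
        op = "insert"
    if op == "substitute":
        pos = int(rng.integers(len(word)))
        ch = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
        return word[:pos] + ch + word[pos + 1 :]
    if op == "delete":
        pos = int(rng.integers(len(word)))
        return word[:pos] + word[pos + 1 :]
    if op == "insert":
        pos = int(rng.integers(len(word) + 1))
        ch = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
        return word[:pos] + ch + word[pos:]
    if len(word) < 2:
        return word
    pos = int(rng.integers(len(word) - 1))
    return word[:pos] + word[pos + 1] + word[pos] + word[pos + 2 :]


def _distort(
    item: str,
    n_edits: int,
    rng: np.random.Generator,
    spec: SimulationSpec,
    wordlist: Wordlist,
) -> str:
    """A nonword obtained from `item` by n_edits random edits."""
    for _ in range(spec.retry_cap):
        word = item
        for _ in range(n_edits):
            word = _apply_edit(word, rng, spec.edit_rates)
        if word and word != item and word not in wordlist:
            return word
    raise SimulationError(
        f"could not distort {item!r} into a nonword in {spec.retry_cap} tries"
    )


def _nonword_response(item, rng, spec, wordlist):
    for _ in range(spec.retry_cap):
        word = _distort(item, 1, rng, spec, wordlist)
        if shared_char_proportion(item, word) >= spec.formal_threshold:
            return word
    raise SimulationError(f"no nonword response for {item!r}; lower edit rates")


def _neologism_response(item, rng, spec, wordlist):
    pool = [c for c in _ALPHABET if c not in set(item)]
    for _ in range(spec.retry_cap):
        length = int(rng.integers(max(2, len(item) - 1), len(item) + 2))
        word = "".join(pool[int(rng.integers(len(pool)))] for _ in range(length))
        if word not in wordlist and shared_char_proportion(item, word) < spec.formal_threshold:
            return word
    raise SimulationError(f"no neologism response for {item!r}")


def _real_word_response(item, category, rng, spec, wordlist, embeddings):
    candidates = sorted(wordlist.entries)
    order = rng.permutation(len(candidates))
    tried = 0
    for idx in order:
        word = candidates[idx]
        if word == item:
            continue
        tried += 1
        if tried > spec.retry_cap:
            break
        ps = shared_char_proportion(item, word)
        formally = ps >= spec.formal_threshold or word[0] == item[0]
        cos = embeddings.cosine(item, word)
        has_cos = not np.isnan(cos)
        semantically = has_cos and cos >= spec.cosine_limit_value
        if category == "formal" and formally and not semantically:
            return word
        if category == "semantic" and semantically and not formally:
            return word
        if category == "mixed" and formally and semantically:
            return word
        if category == "unrelated" and has_cos and not formally and not semantically:
            return word
    raise SimulationError(
        f"no lexicon word realizes category {category!r} for item {item!r}"
    )


def _draw_attempt_count(spec: SimulationSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.attempts_per_item, int):
        return max(1, spec.attempts_per_item)
    kind, p = spec.attempts_per_item
    if kind != "geometric" or not (0.0 < p <= 1.0):
        raise ConfigurationError(
            "attempts_per_item must be an int or ('geometric', p) with 0 < p <= 1"
        )
    return min(int(rng.geometric(p)), 6)


def simulate_responses(
    spec: SimulationSpec,
    items: list[str],
    wordlist: Wordlist,
    embeddings: EmbeddingStore,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a raw assessment table plus its exact ground truth.

    Items are presented in order, cycling through ``items`` until
    ``spec.n_items`` presentations are reached.  For each presentation a
    final-attempt category is drawn from ``error_mix``; repeated-attempt
    cells prepend nonword approach attempts (labelled nonword/neologism by
    their actual shared-character proportion).  Returns
    ``(responses, truth)``: the raw wide table (attempts joined with
    ", ") and a long-format table with one row per attempt holding the
    generating category and the attempt's pcc.  Fully reproducible from
    ``spec.seed``.
    """
    if not items:
        raise ConfigurationError("simulate_responses requires at least one item")
    rng = np.random.default_rng(spec.seed)
    categories = sorted(spec.error_mix)
    probs = np.array([spec.error_mix[c] for c in categories])

    raw_rows, truth_rows = [], []
    for n in range(spec.n_items):
        item = items[n % len(items)]
        category = categories[int(rng.choice(len(categories), p=probs))]

        if category == "no_response":
            attempts, labels = [""], ["no_response"]
        else:
            if category == "nonword":
                final = _nonword_response(item, rng, spec, wordlist)
            elif category == "neologism":
                final = _neologism_response(item, rng, spec, wordlist)
            else:
                final = _real_word_response(
                    item, category, rng, spec, wordlist, embeddings
                )
            k = _draw_attempt_count(spec, rng)
            attempts, labels = [], []
            for j in range(1, k):
                n_edits = (k - j + 1) if spec.monotone_cda else int(rng.integers(1, 4))
                approach = _distort(item, n_edits, rng, spec, wordlist)
                attempts.append(approach)
                ps = shared_char_proportion(item, approach)
                labels.append(
                    "nonword" if ps >= spec.formal_threshold else "neologism"
                )
            attempts.append(final)
            labels.append(category)

        ra = 1 if len([a for a in attempts if a]) >= 2 else 0
        accessed = int(any(a == item for a in attempts))
        raw_rows.append(
            {
                "ID": "P01",
                "task": "simulated_naming",
                "item_ID": n + 1,
                "item": item,
                "response": ", ".join(attempts),
                "accessed": accessed,
            }
        )
        for j, (attempt, label) in enumerate(zip(attempts, labels), start=1):
            truth_rows.append(
                {
                    "ID": "P01",
                    "item_ID": n + 1,
                    "item": item,
                    "attempt": j,
                    "response": attempt,
                    "RA": ra,
                    "category": label,
                    "pcc": (
                        max(0.0, 1.0 - damerau_levenshtein(item, attempt) / len(item))
                    ),
                }
            )
    return pd.DataFrame(raw_rows), pd.DataFrame(truth_rows)
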