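"""Formal-similarity indexes: worked examples, invariants, oracles."""

import math

import edlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import girasol as g
from girasol.errors import ConfigurationError, DataIntegrityError, UndefinedInputError

words = st.text(alphabet="abc", min_size=0, max_size=6)


class TestSharedCharProportion:
    @pytest.mark.parametrize(
        "target, response, expected",
        [
            ("development", "intelligence", 52.17),
            ("rhino", "hippo", 60.0),
            ("dɪvɛləpmənt", "ɪntɛlɪdʒəns", 63.64),
            ("ab", "ab", 100.0),
            ("ab", "cd", 0.0),
        ],
    )
    def test_worked_examples(self, target, response, expected):
        assert round(g.shared_char_proportion(target, response), 2) == expected

    def test_phonemic_transcriptions_after_mark_removal(self):
        target = g.strip_phonemic_marks("dɪˈvɛl.əp.mənt")
        response = g.strip_phonemic_marks("ɪnˈtɛl.ɪ.dʒəns")
        assert (len(target), len(response)) == (11, 11)
        assert round(g.shared_char_proportion(target, response), 2) == 63.64

    def test_empty_string_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            g.shared_char_proportion("", "abc")
        with pytest.raises(UndefinedInputError):
            g.shared_char_proportion("abc", "")

    @settings(derandomize=True, max_examples=100)
    @given(a=words.filter(bool), b=words.filter(bool))
    def test_symmetric_and_bounded(self, a, b):
        p = g.shared_char_proportion(a, b)
        assert p == pytest.approx(g.shared_char_proportion(b, a))
        assert 0.0 <= p <= 100.0


class TestPositionalMatch:
    @pytest.mark.parametrize(
        "target, response, strict, adj, pct",
        [
            ("mangrove", "mango", "11110000", "11110000", 50.0),
            ("abc", "abc", "111", "111", 100.0),
            ("ab", "abcd", "1100", "11", 100.0),
            ("abc", "", "000", "000", 0.0),
        ],
    )
    def test_match_strings(self, target, response, strict, adj, pct):
        assert g.positional_match(target, response) == (strict, adj, pct)

    def test_empty_target_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            g.positional_match("", "abc")

    @settings(derandomize=True, max_examples=100)
    @given(a=words.filter(bool), b=words)
    def test_adjusted_string_consistency(self, a, b):
        strict, adj, pct = g.positional_match(a, b)
        assert len(adj) == len(a)
        assert len(strict) == max(len(a), len(b))
        assert pct == pytest.approx(100.0 * adj.count("1") / len(a))


class TestEditDistances:
    @pytest.mark.parametrize(
        "a, b, ld, dld",
        [
            ("mangrove", "mango", 3, 3),
            ("ab", "ba", 2, 1),
            ("abc", "", 3, 3),
            ("", "", 0, 0),
            ("ca", "abc", 3, 2),  # unrestricted DL beats optimal string alignment
            ("taladro", "talabro", 1, 1),
        ],
    )
    def test_distance_examples(self, a, b, ld, dld):
        got_ld, got_dld, _ = g.edit_distances(a, b)
        assert (got_ld, got_dld) == (ld, dld)

    def test_jaro_winkler_examples(self):
        assert g.jaro_winkler_distance("martha", "marhta") == pytest.approx(
            0.0389, abs=5e-5
        )
        assert g.edit_distances("abc", "")[2] == 1.0
        assert g.jaro_winkler_distance("same", "same") == 0.0

    @settings(derandomize=True, max_examples=150)
    @given(a=words, b=words)
    def test_symmetry_and_dl_bound(self, a, b):
        ld, dld, jwd = g.edit_distances(a, b)
        assert (ld, dld) == (g.levenshtein(b, a), g.damerau_levenshtein(b, a))
        assert jwd == pytest.approx(g.jaro_winkler_distance(b, a))
        assert 0 <= dld <= ld
        assert 0.0 <= jwd <= 1.0

    @settings(derandomize=True, max_examples=150)
    @given(a=words, b=words)
    def test_levenshtein_matches_edlib(self, a, b):
        """Cross-check against an independent alignment library."""
        if a and b:
            assert g.levenshtein(a, b) == edlib.align(a, b)["editDistance"]


def _brute_lcs_set(a, b):
    """All common subsequences, by enumeration (tiny strings only)."""

    def subseqs(s):
        out = {""}
        for ch in s:
            out |= {x + ch for x in out}
        return out

    return subseqs(a) & subseqs(b)


class TestLcs:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("mangrove", "mango", "mango"),  # subsequence: mang + trailing o
            ("abc", "abc", "abc"),
            ("abcd", "acbd", "abd"),  # leftmost tie-break among abd/acd
            ("abc", "xyz", ""),
        ],
    )
    def test_subsequence_examples(self, a, b, expected):
        assert g.lcs_string(a, b) == expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("mangrove", "mango", "mang"),  # contiguous run breaks at r/o
            ("abc", "abc", "abc"),
            ("xabx", "ab", "ab"),
            ("abc", "xyz", ""),
        ],
    )
    def test_substring_examples(self, a, b, expected):
        assert g.lcs_substring(a, b) == expected

    @settings(derandomize=True, max_examples=80)
    @given(a=words, b=words)
    def test_substring_is_contiguous_in_both(self, a, b):
        sub = g.lcs_substring(a, b)
        assert sub in a and sub in b

    @settings(derandomize=True, max_examples=100)
    @given(a=words, b=words)
    def test_is_maximal_common_subsequence(self, a, b):
        got = g.lcs_string(a, b)
        common = _brute_lcs_set(a, b)
        assert got in common
        assert len(got) == max(len(s) for s in common)


class TestSimilarityTrace:
    @pytest.mark.parametrize(
        "a, b, expected", [("abc", "abc", "MMM"), ("a", "b", "S"), ("ab", "", "DD")]
    )
    def test_trivial_traces(self, a, b, expected):
        assert g.similarity_trace(a, b) == expected

    @settings(derandomize=True, max_examples=150)
    @given(a=words, b=words)
    def test_trace_counts_account_for_both_strings_and_cost(self, a, b):
        trace = g.similarity_trace(a, b)
        counts = {op: trace.count(op) for op in "MDSI"}
        assert counts["M"] + counts["S"] + counts["D"] == len(a)
        assert counts["M"] + counts["S"] + counts["I"] == len(b)
        assert counts["S"] + counts["D"] + counts["I"] == g.levenshtein(a, b)

    def test_mangrove_trace_is_minimal(self):
        trace = g.similarity_trace("mangrove", "mango")
        assert trace.count("M") == 5
        assert sum(trace.count(op) for op in "SDI") == 3


class TestPcc:
    @pytest.mark.parametrize(
        "target, response, expected",
        [("mangrove", "mango", 0.625), ("abc", "abc", 1.0), ("ab", "wxyz", 0.0)],
    )
    def test_examples(self, target, response, expected):
        assert g.pcc(target, response) == pytest.approx(expected)

    def test_empty_target_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            g.pcc("", "abc")

    @settings(derandomize=True, max_examples=80)
    @given(target=st.text(alphabet="abcd", min_size=2, max_size=6), cut=st.integers(1, 5))
    def test_completing_a_prefix_never_decreases_pcc(self, target, cut):
        """Appending the correct next target character to a strict-prefix
        response cannot lower the proportion of correct characters."""
        cut = min(cut, len(target) - 1)
        shorter, longer = target[:cut], target[: cut + 1]
        assert g.pcc(target, longer) >= g.pcc(target, shorter)


class TestComputeFormalIndexes:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_identical_pair_scores_perfectly(self):
        out = g.compute_formal_indexes(
            self._frame([{"item": "mesa", "response": "mesa"}])
        )
        row = out.iloc[0]
        assert row["p_shared_char"] == 100.0
        assert row["Ld"] == 0 and row["DLd"] == 0 and row["JWd"] == 0.0
        assert row["pcc"] == 1.0
        assert row["adj_strict_match_pos"] == "1111"
        assert row["shared1char"]
        assert row["similarity_str"] == "MMMM"
        assert "approach_diff" not in out.columns

    def test_comment_warning_on_space_or_comma(self):
        out = g.compute_formal_indexes(
            self._frame(
                [
                    {"item": "taladro", "response": "taladro, taladro"},
                    {"item": "taladro", "response": "taladro"},
                ]
            )
        )
        assert out["comment_warning"].iloc[0] != ""
        assert out["comment_warning"].iloc[1] == ""

    def test_approach_diff_is_pcc_delta_within_group(self):
        df = self._frame(
            [
                {"ID": 1, "item_ID": 1, "item": "aaaaa", "response": r, "attempt": i}
                for i, r in enumerate(["bbbbb", "aabbb", "aaaab"], start=1)
            ]
        )
        out = g.compute_formal_indexes(
            df, attempt_col="attempt", group_cols=["ID", "item_ID"]
        )
        assert out["pcc"].tolist() == pytest.approx([0.0, 0.4, 0.8])
        diffs = out["approach_diff"].tolist()
        assert math.isnan(diffs[0])
        assert diffs[1:] == pytest.approx([0.4, 0.4])

    def test_approach_diff_respects_group_boundaries(self):
        df = self._frame(
            [
                {"ID": pid, "item_ID": 1, "item": "abc", "response": r, "attempt": a}
                for pid, r, a in [(1, "xbc", 1), (1, "abc", 2), (2, "abc", 1)]
            ]
        )
        out = g.compute_formal_indexes(
            df, attempt_col="attempt", group_cols=["ID", "item_ID"]
        )
        assert math.isnan(out["approach_diff"].iloc[2])

    def test_attempt_without_group_cols_is_configuration_error(self):
        df = self._frame([{"item": "a", "response": "a", "attempt": 1}])
        with pytest.raises(ConfigurationError):
            g.compute_formal_indexes(df, attempt_col="attempt")

    def test_duplicate_group_attempt_keys_are_reported(self):
        df = self._frame(
            [
                {"ID": 1, "item_ID": 1, "item": "abc", "response": "abc", "attempt": 1},
                {"ID": 1, "item_ID": 1, "item": "abc", "response": "abd", "attempt": 1},
            ]
        )
        with pytest.raises(DataIntegrityError, match="duplicate"):
            g.compute_formal_indexes(
                df, attempt_col="attempt", group_cols=["ID", "item_ID"]
            )

    def test_empty_response_row_is_scored_not_fatal(self):
        out = g.compute_formal_indexes(self._frame([{"item": "abc", "response": ""}]))
        row = out.iloc[0]
        assert np.isnan(row["p_shared_char"])
        assert row["DLd"] == 3 and row["pcc"] == 0.0
        assert row["adj_strict_match_pos"] == "000"

    @settings(derandomize=True, max_examples=50)
    @given(a=words.filter(bool), b=words)
    def test_positional_percent_consistent_with_adjusted_string(self, a, b):
        out = g.compute_formal_indexes(self._frame([{"item": a, "response": b}]))
        row = out.iloc[0]
        ones = row["adj_strict_match_pos"].count("1")
        assert round(row["p_shared_char_in_pos"] / 100 * row["targetL"]) == ones
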