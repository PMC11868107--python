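"""Error taxonomy: the classifier's decision tree and its table variants."""

import numpy as np
import pandas as pd
import pytest

import girasol as g
from girasol.classify import RA_ONLY_COMMENT, REQUIRED_COMMENT
from girasol.errors import ConfigurationError, PipelineOrderError


def _single(item, response, lexicality, cos, accessed=0, config=None):
    ps = g.shared_char_proportion(item, response) if response else None
    shared1 = bool(response) and item[0] == response[0]
    return g.classify_single(
        item=item,
        response=response,
        accessed=accessed,
        lexicality=lexicality,
        p_shared_char=ps,
        shared1char=shared1,
        w2v_cos=cos,
        config=config,
    )


class TestDecisionTree:
    @pytest.mark.parametrize(
        "item, response, lexicality, cos, expected",
        [
            ("Table", "Tagle", 0, None, "nonword"),
            ("Table", "Timos", 0, None, "neologism"),
            ("Table", "Truck", 1, 0.1, "formal"),
            ("Table", "Chair", 1, 0.8, "semantic"),
            ("Furniture", "Furnace", 1, 0.8, "mixed"),
            ("Table", "Sneaker", 1, 0.1, "unrelated"),
            ("Table", "", None, None, "no_response"),
        ],
    )
    def test_taxonomy_exemplars(self, item, response, lexicality, cos, expected):
        out = _single(item, response, lexicality, cos)
        assert out.category == expected
        assert out.check_comment == ""

    def test_accessed_dominates(self):
        out = _single("mesa", "msea", 0, None, accessed=1)
        assert sum(out.categories.values()) == 0

    def test_identical_response_is_never_an_error(self):
        out = _single("mesa", "mesa", 1, 1.0, accessed=0)
        assert sum(out.categories.values()) == 0

    def test_threshold_ties_count_as_related(self):
        # shared proportion exactly 50 -> nonword; cosine exactly at limit -> semantic
        assert _single("abcd", "abxy", 0, None).category == "nonword"
        assert _single("abcd", "wxyz", 1, 0.46).category == "semantic"

    def test_missing_lexicality_flags_required(self):
        out = _single("mesa", "mnop", None, None)
        assert sum(out.categories.values()) == 0
        assert out.check_comment == REQUIRED_COMMENT

    def test_missing_cosine_is_noted_not_required(self):
        out = _single("mesa", "nopq", 1, float("nan"))
        assert out.category == "unrelated"
        assert out.check_comment == ""
        assert "missing" in out.note

    def test_cosine_threshold_monotonicity(self):
        """Raising the cosine threshold can only demote mixed->formal and
        semantic->unrelated, never the reverse."""
        demotions = {"mixed": "formal", "semantic": "unrelated"}
        for response, lex, cos in [("melon", 1, 0.5), ("nopqr", 1, 0.5)]:
            lo = _single("mesal", response, lex, cos,
                         config=g.ClassifierConfig(cosine_limit_value=0.3)).category
            hi = _single("mesal", response, lex, cos,
                         config=g.ClassifierConfig(cosine_limit_value=0.7)).category
            assert hi == demotions.get(lo, lo)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            g.ClassifierConfig(formal_threshold=0)
        with pytest.raises(ConfigurationError):
            g.ClassifierConfig(cosine_limit_value=2.0)


def _prepared(world, raw, drop_blank=False):
    long = g.get_attempts(g.separate_responses(raw), drop_blank=drop_blank)
    scored = g.compute_formal_indexes(
        long, attempt_col="attempt", group_cols=["ID", "item_ID"]
    )
    checked = g.check_lexicality(
        scored, criterion="dictionary", resource=world.wordlist
    )
    return g.get_semantic_similarity(checked, store=world.embeddings)


@pytest.fixture()
def prepared_table(world):
    item = world.items[0]
    raw = pd.DataFrame(
        {
            "ID": ["P01"] * 3,
            "item_ID": [1, 2, 3],
            "item": [item] * 3,
            "response": [f"{item}x, {item}", item, ""],
            "accessed": [1, 1, 0],
        }
    )
    return _prepared(world, raw)


class TestClassifyErrors:
    def test_ra_rows_skipped_when_not_classifying_ras(self, prepared_table):
        out = g.classify_errors(prepared_table, also_classify_RAs=False)
        ra_rows = out[out["RA"] == 1]
        assert (ra_rows[g.CATEGORY_COLUMNS].sum(axis=1) == 0).all()
        assert (ra_rows["check_comment"] == RA_ONLY_COMMENT).all()

    def test_fully_correct_rows_have_no_categories(self, prepared_table):
        out = g.classify_errors(prepared_table)
        correct = out[out["accessed"] == 1]
        assert (correct[g.CATEGORY_COLUMNS].sum(axis=1) == 0).all()
        assert (correct["check_comment"] == "").all()

    def test_empty_cell_is_no_response(self, prepared_table):
        out = g.classify_errors(prepared_table)
        assert out[out["response"] == ""]["no_response"].tolist() == [1]

    def test_missing_prerequisite_names_stage(self, world):
        df = pd.DataFrame({"item": ["a"], "response": ["b"], "accessed": [0], "RA": [0]})
        with pytest.raises(PipelineOrderError, match="check_lexicality"):
            g.classify_errors(df)

    def test_unclassifiable_row_flagged_required(self, prepared_table):
        broken = prepared_table.copy()
        broken["lexicality"] = np.nan
        broken["accessed"] = 0
        out = g.classify_errors(broken)
        erroneous = out[(out["response"] != "") & (out["response"] != out["item"])]
        assert (erroneous["check_comment"] == REQUIRED_COMMENT).all()


class TestClassifyErrorsRegular:
    def test_matches_ra_aware_variant_on_single_responses(self, world, prepared_table):
        singles = prepared_table[prepared_table["RA"] == 0].reset_index(drop=True)
        via_ra = g.classify_errors(singles, also_classify_RAs=True)
        via_regular = g.classify_errors_regular(singles, access_col="accessed")
        pd.testing.assert_frame_equal(
            via_ra[g.CATEGORY_COLUMNS], via_regular[g.CATEGORY_COLUMNS]
        )

    def test_derived_accessed_from_equality(self, world):
        item = world.items[0]
        raw = pd.DataFrame(
            {
                "ID": ["P01"],
                "item_ID": [1],
                "item": [item],
                "response": [item],
                "accessed": [0],
            }
        )
        prepared = _prepared(world, raw).drop(columns=["accessed"])
        out = g.classify_errors_regular(prepared)
        assert (out[g.CATEGORY_COLUMNS].sum(axis=1) == 0).all()

    def test_empty_table_round_trips(self):
        out = g.classify_errors_regular(pd.DataFrame())
        assert out.empty
        assert set(g.CATEGORY_COLUMNS).issubset(out.columns)
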