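import pandas as pd
import pytest

import girasol as g


@pytest.fixture(scope="session")
def world():
    """Small engineered lexicon/embedding world for end-to-end tests."""
    return g.make_fixture_world(n_items=8, seed=11)


@pytest.fixture(scope="session")
def table4_resources():
    """Wordlist and embeddings realizing the classic taxonomy exemplars:
    chair/table and furnace/furniture semantically close (cosine 0.8),
    truck and sneaker semantically far from table (cosine 0.1)."""
    wordlist = g.Wordlist.from_words(
        ["table", "truck", "chair", "sneaker", "furniture", "furnace"]
    )
    store = g.make_toy_embeddings(
        [["table", "chair"], ["furniture", "furnace"], ["truck"], ["sneaker"]],
        within_cos=0.8,
        between_cos=0.1,
        seed=5,
    )
    return wordlist, store


@pytest.fixture()
def raw_attempts_table():
    """A miniature raw assessment table with a conduite d'approche."""
    return pd.DataFrame(
        {
            "ID": ["P01", "P01", "P01"],
            "task": ["naming"] * 3,
            "item_ID": [1, 2, 3],
            "item": ["taladro", "peine", "mesa"],
            "response": [
                "talablo, talabro, talabro, taladro, taladro",
                "peine",
                "",
            ],
            "accessed": [1, 1, 0],
        }
    )
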