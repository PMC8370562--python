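import math

import pytest
from hypothesis import given, settings, strategies as st

import srofluency as sf
from srofluency.scoring import (
    INTRUSION,
    PERSEVERATION,
    REPETITION,
    SAME_ENTITY_VARIANT,
    SUB_SUPERORDINATE,
    VALID,
)

from conftest import make_entries


def test_basic_classification_and_sro(lexicon, variant_map, relations):
    # car is not an animal -> intrusion; second cat -> perseveration
    entries = make_entries(["cat", "dog", "car", "cat", "horse"])
    t = sf.score_transcript(entries, lexicon, variant_map, relations)
    assert [e.validity for e in t.entries] == [
        VALID, VALID, INTRUSION, PERSEVERATION, VALID,
    ]
    assert [e.sro for e in t.entries] == [1, 2, None, None, 3]
    assert t.entries[3].perseveration_kind == REPETITION


def test_sub_superordinate_perseveration(lexicon, variant_map, relations):
    t = sf.score_transcript(make_entries(["ape", "gorilla"]), lexicon, variant_map, relations)
    assert t.entries[1].validity == PERSEVERATION
    assert t.entries[1].perseveration_kind == SUB_SUPERORDINATE
    # first occurrence stays valid regardless of order
    t2 = sf.score_transcript(make_entries(["gorilla", "ape"]), lexicon, variant_map, relations)
    assert t2.entries[0].validity == VALID
    assert t2.entries[1].validity == PERSEVERATION


def test_same_entity_variant_perseveration(lexicon, variant_map, relations):
    entries = make_entries(["grape", "raisin"], category="FRUITS")
    t = sf.score_transcript(entries, lexicon, variant_map, relations)
    assert t.entries[1].validity == PERSEVERATION
    assert t.entries[1].perseveration_kind == SAME_ENTITY_VARIANT


def test_variant_standardisation_feeds_repetition(lexicon, variant_map, relations):
    # hippo then hippopotamus: same canonical form, so a repetition
    entries = make_entries(["hippo", "hippopotamus"])
    t = sf.score_transcript(entries, lexicon, variant_map, relations)
    assert t.entries[0].canonical_word == "HIPPOPOTAMUS"
    assert t.entries[1].validity == PERSEVERATION
    assert t.entries[1].perseveration_kind == REPETITION


def test_empty_and_unordered_input(lexicon):
    assert sf.score_transcript([], lexicon).entries == []
    bad = make_entries(["cat", "dog"])
    bad = [bad[1], bad[0]]  # utterance_index now decreasing
    with pytest.raises(ValueError, match="utterance_index"):
        sf.score_transcript(bad, lexicon)


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.sampled_from(
            ["cat", "dog", "horse", "wasp", "apple", "zzz", "cat", "dog", "qqq"]
        ),
        min_size=1,
        max_size=25,
    )
)
def test_sro_bijection_and_conservation(words):
    """Valid entries' SRO is exactly 1..n; validity classes partition entries."""
    lexicon = sf.fixture_lexicon()
    t = sf.score_transcript(make_entries(words), lexicon)
    sros = [e.sro for e in t.valid_entries]
    assert sros == list(range(1, len(sros) + 1))
    n_by_class = {
        c: sum(1 for e in t.entries if e.validity == c)
        for c in (VALID, INTRUSION, PERSEVERATION)
    }
    assert sum(n_by_class.values()) == len(words)
    # invalid entries never carry an SRO
    assert all(e.sro is None for e in t.entries if e.validity != VALID)


def test_merge_categories_additivity(lexicon):
    animals = sf.score_transcript(
        make_entries(["cat", "dog", "horse"], category="ANIMALS"), lexicon
    )
    fruits = sf.score_transcript(
        make_entries(["apple", "pear"], category="FRUITS"), lexicon
    )
    merged = sf.merge_categories([animals, fruits])
    assert len(merged) == 5
    # SRO restarts per category
    assert list(merged["sro"]) == [1, 2, 3, 1, 2]
    with pytest.raises(ValueError, match="duplicate"):
        sf.merge_categories([animals, animals])


def test_observation_table_shape_and_missingness(lexicon, dictionary):
    animals = sf.score_transcript(
        make_entries(["condor", "cat", "dog", "car"], category="ANIMALS"), lexicon
    )
    obs = sf.build_observation_table([animals], lexicon, dictionary)
    assert len(obs) == 3  # car was an intrusion
    assert not obs["serial_recall_order"].isna().any()
    # CONDOR has no valence rating in the fixture lexicon
    assert obs.loc[obs.canonical_word == "CONDOR", "valence"].isna().all()
    for f in sf.FEATURE_NAMES:
        assert f in obs.columns


def test_positional_sets_partition(lexicon):
    words = ["cat", "dog", "horse", "sheep", "duck", "fish", "bear", "bull",
             "seal", "wasp", "panda", "moose"]
    t = sf.score_transcript(make_entries(words), lexicon)
    blocks = sf.positional_sets(t, block_size=5)
    assert {k: len(v) for k, v in blocks.items()} == {"1-5": 5, "6-10": 5, "11-15": 2}

    t3 = sf.score_transcript(make_entries(["cat", "dog", "horse"]), lexicon)
    assert {k: len(v) for k, v in sf.positional_sets(t3).items()} == {"1-5": 3}


def test_positional_sets_overflow(lexicon):
    words = lexicon.words("ANIMALS")[:23]
    t = sf.score_transcript(make_entries([w.lower() for w in words]), lexicon)
    blocks = sf.positional_sets(t, block_size=5, n_blocks=4)
    sizes = {k: len(v) for k, v in blocks.items()}
    assert sizes == {"1-5": 5, "6-10": 5, "11-15": 5, "16-20": 5, "overflow": 3}


def test_tally_counts_rates(lexicon):
    # cohort of 3311 words with 254 perseverations reproduces the 7.7% rate
    t1 = sf.score_transcript(make_entries(["cat", "dog"]), lexicon)
    counts = sf.tally_counts([t1])
    assert counts.total_words == 2 and counts.perseveration_rate == 0.0

    # proportions are over total words generated
    assert round(254 / 3311 * 100, 1) == 7.7
    assert round(20 / 3311 * 100, 1) == 0.6

    words = ["cat", "dog"] * 100  # 200 words: 2 valid, 198 repetitions
    t = sf.score_transcript(make_entries(words), lexicon)
    c = sf.tally_counts([t])
    assert c.total_words == 200
    assert c.total_perseverations == 198

    t_intr = sf.score_transcript(
        make_entries([w.lower() for w in lexicon.words("ANIMALS")[:20]] + ["xyzzy"]),
        lexicon,
    )
    c2 = sf.tally_counts([t_intr])
    assert c2.intrusion_rate == pytest.approx(1 / 21)
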