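import pytest

import srofluency as sf


@pytest.fixture(scope="session")
def lexicon():
    return sf.fixture_lexicon()


@pytest.fixture(scope="session")
def variant_map():
    return sf.fixture_variant_map()


@pytest.fixture(scope="session")
def relations():
    return sf.fixture_relations()


@pytest.fixture(scope="session")
def dictionary():
    return sf.fixture_dictionary()


def make_entries(words, participant="p1", group="g", category="ANIMALS"):
    """Raw utterance sequence from a word list, 1-based utterance order."""
    return [
        sf.RawEntry(
            participant_id=participant,
            group=group,
            category=category,
            utterance_index=i + 1,
            raw_word=w,
        )
        for i, w in enumerate(words)
    ]
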