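"""Non-semantic item-level features derived from orthography and phonology.

Six features are computed per word: graphemes count, syllables count,
consonant/vowel quantity ratio, phonological complexity (sonority-scored
consonant clusters per syllable), mean in-list orthographic Levenshtein
distance, and dictionary orthographic neighbourhood size (words at edit
distance exactly 1).

Phonemic transcriptions are tokenised symbol by symbol: each IPA symbol
is one phoneme and is tagged consonant or vowel (so a two-symbol
diphthong such as /əʊ/ contributes two vowel phonemes — BUFFALO
/bʌfələʊ/ has 7 phonemes, 3 consonants, ratio 0.43). Stress marks,
length marks and syllable dots are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

__all__ = [
    "PhonemicString",
    "SonorityTable",
    "DEFAULT_SONORITY",
    "tokenize_phonemic",
    "grapheme_count",
    "syllable_count",
    "consonant_ratio",
    "phonological_complexity",
    "levenshtein",
    "in_list_old",
    "dictionary_neighbourhood",
    "compute_word_features",
]

# Symbols ignored during tokenisation (stress, length, syllable breaks).
_IGNORED = set("ˈˌːˑ.·' ˈˌ()")

_VOWELS = set("aeiouæɑɒʌΛəɚɛεɜɝɪiɔoøʊuʉyʏɐɤɨœ")

# consonant token -> sonority class
_CONSONANT_CLASS = {
    "p": "voiceless_stop", "t": "voiceless_stop", "k": "voiceless_stop",
    "b": "voiced_stop", "d": "voiced_stop", "g": "voiced_stop", "ɡ": "voiced_stop",
    "f": "voiceless_fricative", "θ": "voiceless_fricative",
    "s": "voiceless_fricative", "ʃ": "voiceless_fricative",
    "h": "voiceless_fricative", "x": "voiceless_fricative",
    "v": "voiced_fricative", "ð": "voiced_fricative",
    "z": "voiced_fricative", "ʒ": "voiced_fricative",
    "m": "nasal", "n": "nasal", "ŋ": "nasal",
    "l": "liquid", "r": "liquid", "ɹ": "liquid", "ɾ": "liquid",
    "j": "glide", "w": "glide",
    "ʧ": "affricate", "ʤ": "affricate", "ʦ": "affricate",
}

#: Sonority scores per consonant class. The voiceless-fricative (5),
#: voiced-fricative (4), nasal (3) and voiceless-stop (7) values follow
#: the published sonority scoring model; the remaining classes fill the
#: scale and are configurable.
DEFAULT_CLASS_SCORES: dict[str, int] = {
    "voiceless_stop": 7,
    "voiced_stop": 6,
    "affricate": 6,
    "voiceless_fricative": 5,
    "voiced_fricative": 4,
    "nasal": 3,
    "liquid": 2,
    "glide": 1,
}


@dataclass(frozen=True)
class SonorityTable:
    """Maps consonant tokens to classes and classes to sonority scores."""

    class_scores: Mapping[str, int]
    token_class: Mapping[str, str]

    def score(self, token: str) -> int:
        cls = self.token_class.get(token)
        if cls is None:
            raise KeyError(f"consonant token {token!r} has no sonority class")
        return self.class_scores[cls]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SonorityTable":
        """Load a two-section TSV: lines `class<TAB>score` or `token<TAB>class`."""
        class_scores: dict[str, int] = {}
        token_class: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")
                if b.isdigit():
                    class_scores[a] = int(b)
                else:
                    token_class[a] = b
        return cls(class_scores, token_class)


DEFAULT_SONORITY = SonorityTable(DEFAULT_CLASS_SCORES, _CONSONANT_CLASS)


@dataclass(frozen=True)
class PhonemicString:
    """Tokenised transcription: parallel tuples of symbols and C/V tags."""

    symbols: tuple[str, ...]
    is_consonant: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_consonants(self) -> int:
        return sum(self.is_consonant)

    def consonant_clusters(self) -> list[list[str]]:
        """Maximal runs of consecutive consonant tokens."""
        clusters: list[list[str]] = []
        current: list[str] = []
        for sym, is_c in zip(self.symbols, self.is_consonant):
            if is_c:
                current.append(sym)
            elif current:
                clusters.append(current)
                current = []
        if current:
            clusters.append(current)
        return clusters

    def vowel_nuclei(self) -> int:
        """Number of maximal vowel runs (one nucleus per run)."""
        nuclei, in_run = 0, False
        for is_c in self.is_consonant:
            if not is_c and not in_run:
                nuclei += 1
            in_run = not is_c
        return nuclei


def tokenize_phonemic(transcription: str) -> PhonemicString:
    """Tokenise an IPA transcription, one phoneme per symbol."""
    symbols, tags = [], []
    for ch in transcription:
        if ch in _IGNORED:
            continue
        if ch in _VOWELS:
            symbols.append(ch)
            tags.append(False)
        elif ch in _CONSONANT_CLASS:
            symbols.append(ch)
            tags.append(True)
        else:
            raise ValueError(f"unrecognised phonemic symbol {ch!r} in {transcription!r}")
    if not symbols:
        raise ValueError(f"empty transcription {transcription!r}")
    return PhonemicString(tuple(symbols), tuple(tags))


def _strip_spaces(word: str) -> str:
    return word.replace(" ", "").replace("-", "")


def grapheme_count(word: str) -> int:
    """Letter count of the canonical form; spaces/hyphens not counted."""
    stripped = _strip_spaces(word)
    if not stripped:
        raise ValueError("empty word")
    return len(stripped)


def syllable_count(
    word: str,
    lexicon_syllables: int | None = None,
    phonemic: PhonemicString | str | None = None,
) -> int | None:
    """Syllables: lexicon value if present, else vowel nuclei of the
    transcription; None when neither source is available."""
    if lexicon_syllables is not None:
        return int(lexicon_syllables)
    if phonemic is None:
        return None
    if isinstance(phonemic, str):
        phonemic = tokenize_phonemic(phonemic)
    return phonemic.vowel_nuclei()


def consonant_ratio(phonemic: PhonemicString | str) -> float:
    """Consonant phonemes over total phonemes, in [0, 1]."""
    if isinstance(phonemic, str):
        phonemic = tokenize_phonemic(phonemic)
    return phonemic.n_consonants / len(phonemic)


def cluster_sonority(cluster: Sequence[str], table: SonorityTable = DEFAULT_SONORITY) -> int:
    """Sonority score of one consonant cluster.

    A singleton scores its class sonority; a longer cluster scores the
    sum of absolute differences of successive members' sonorities (so
    /nt/ = |3 - 7| = 4).
    """
    scores = [table.score(tok) for tok in cluster]
    if len(scores) == 1:
        return scores[0]
    return sum(abs(a - b) for a, b in zip(scores, scores[1:]))


def phonological_complexity(
    phonemic: PhonemicString | str,
    syllables: int,
    table: SonorityTable = DEFAULT_SONORITY,
) -> float:
    """Summed consonant-cluster sonority divided by the syllable count.

    PHEASANT /fɛzənt/ scores (5 + 4 + |3-7|) / 2 syllables = 6.5.
    """
    if syllables < 1:
        raise ValueError("syllables must be >= 1")
    if isinstance(phonemic, str):
        phonemic = tokenize_phonemic(phonemic)
    total = sum(cluster_sonority(c, table) for c in phonemic.consonant_clusters())
    return total / syllables


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance on space-stripped uppercase forms."""
    a, b = _strip_spaces(a.upper()), _strip_spaces(b.upper())
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


def in_list_old(word: str, others: Iterable[str]) -> float | None:
    """Mean Levenshtein distance from ``word`` to each word in ``others``.

    Returns None (missing) when the comparison set is empty — a word
    with no co-generated words has no in-list distance, not a zero one.
    """
    others = list(others)
    if not others:
        return None
    return sum(levenshtein(word, o) for o in others) / len(others)


def dictionary_neighbourhood(word: str, dictionary: Iterable[str]) -> int:
    """Count dictionary entries at edit distance exactly 1 from ``word``."""
    dictionary = set(dictionary)
    if not dictionary:
        raise ValueError("empty dictionary")
    target = _strip_spaces(word.upper())
    return sum(
        1
        for entry in dictionary
        if entry != target and levenshtein(target, entry) == 1
    )


def compute_word_features(
    word: str,
    phonemic: str,
    *,
    lexicon_syllables: int | None = None,
    co_words: Iterable[str] = (),
    dictionary: Iterable[str] | None = None,
    sonority: SonorityTable = DEFAULT_SONORITY,
) -> dict[str, float | None]:
    """All six computed features for one word, keyed by feature name."""
    phon = tokenize_phonemic(phonemic) if phonemic else None
    syllables = syllable_count(word, lexicon_syllables, phon)
    feats: dict[str, float | None] = {
        "graphemes_count": grapheme_count(word),
        "syllables_count": syllables,
        "consonant_vowel_ratio": consonant_ratio(phon) if phon else None,
        "phonological_complexity": (
            phonological_complexity(phon, syllables, sonority)
            if phon and syllables
            else None
        ),
        "in_list_levenshtein": in_list_old(word, co_words),
        "dictionary_neighbourhood": (
            dictionary_neighbourhood(word, dictionary) if dictionary else None
        ),
    }
    return feats
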