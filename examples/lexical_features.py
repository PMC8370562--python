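"""The six derived (non-semantic) word features, on published examples.

Each feature is computed from orthography or the phonemic transcription:
no norms are needed. The printed values match the documented worked
examples: PHEASANT 6.5, BUFFALO 0.43, PARROT 4.33, OTTER 7.
"""

import srofluency as sf

print("graphemes  OX:", sf.grapheme_count("OX"),
      " CATERPILLAR:", sf.grapheme_count("CATERPILLAR"),
      " GUINEA PIG:", sf.grapheme_count("GUINEA PIG"), "(space not counted)")

print("syllables  IGUANA:", sf.syllable_count("IGUANA", None, "ɪgwɑnə"),
      " SHRIMP:", sf.syllable_count("SHRIMP", None, "ʃrɪmp"))

print("consonant/vowel ratio  BUFFALO /bʌfələʊ/:",
      round(sf.consonant_ratio("bʌfələʊ"), 2), "(3 consonants of 7 phonemes)")

# clusters f (5), z (4) and nt (nasal 3 vs voiceless stop 7 -> |3-7| = 4),
# summed to 13 and divided by 2 syllables
print("phonological complexity  PHEASANT /fɛzənt/:",
      sf.phonological_complexity("fɛzənt", 2))

others = ["HORNET", "PANTHER", "OCELOT"]
print("in-list Levenshtein  PARROT vs", others, "->",
      [sf.levenshtein("PARROT", w) for w in others],
      "mean", round(sf.in_list_old("PARROT", others), 2))

print("orthographic neighbourhood  OTTER:",
      sf.dictionary_neighbourhood("OTTER", sf.fixture_dictionary()),
      "dictionary words at edit distance 1")
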