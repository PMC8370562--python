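"""Score a raw fluency transcript: validity flags and serial recall order.

Builds a short "animals" utterance sequence containing an intrusion
(car), a repetition (cat again) and a variant form (hippo), scores it
against the bundled lexicon, and prints one line per utterance. Valid
entries get serial recall order 1..n; flagged entries get none.
"""

import srofluency as sf

lexicon = sf.fixture_lexicon()
variants = sf.fixture_variant_map()
relations = sf.fixture_relations()

words = ["cat", "dog", "car", "cat", "hippo", "hippopotamus", "ape", "gorilla"]
entries = [
    sf.RawEntry("demo-01", "demo", "ANIMALS", i + 1, w) for i, w in enumerate(words)
]
transcript = sf.score_transcript(entries, lexicon, variants, relations)

print(f"{'utterance':<14}{'canonical':<15}{'validity':<15}{'kind':<20}SRO")
for raw, e in zip(words, transcript.entries):
    print(
        f"{raw:<14}{e.canonical_word:<15}{e.validity:<15}"
        f"{e.perseveration_kind or '-':<20}{e.sro if e.sro else '-'}"
    )

counts = sf.tally_counts([transcript])
print(
    f"\nvalid {counts.total_valid}, intrusions {counts.total_intrusions}, "
    f"perseverations {counts.total_perseverations} "
    f"(rates {counts.intrusion_rate:.1%} / {counts.perseveration_rate:.1%} of "
    f"{counts.total_words} words)"
)
# The raw fluency score is the valid count; only valid words enter the
# feature analyses, but flagged entries are kept for post-hoc tallies.
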