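"""Transcript scoring: validity classification and serial recall order.

Each uttered word is standardised and classified as *valid*, *intrusion*
(not in the lexicon for the target category) or *perseveration* (an
exact repetition of an earlier entry, a subordinate/superordinate of an
earlier valid word — ape/gorilla — or the same entity in a different
form — grape/raisin). Valid entries receive serial recall order (SRO)
1..n by production order; intrusions and perseverations are retained
with flags for post-hoc counts but excluded from all feature analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .lexicon import (
    COMPUTED_FEATURES,
    FEATURE_NAMES,
    RATED_FEATURES,
    SRO,
    FeatureTable,
    VariantMap,
    standardize,
)
from . import lexical

__all__ = [
    "RawEntry",
    "ScoredEntry",
    "ScoredTranscript",
    "RelationTable",
    "CohortCounts",
    "score_transcript",
    "merge_categories",
    "build_observation_table",
    "positional_sets",
    "tally_counts",
    "load_transcripts",
    "scored_to_frame",
]

VALID = "valid"
INTRUSION = "intrusion"
PERSEVERATION = "perseveration"

REPETITION = "repetition"
SUB_SUPERORDINATE = "sub_superordinate"
SAME_ENTITY_VARIANT = "same_entity_variant"


@dataclass(frozen=True)
class RawEntry:
    participant_id: str
    group: str
    category: str
    utterance_index: int
    raw_word: str


@dataclass(frozen=True)
class ScoredEntry:
    canonical_word: str
    utterance_index: int
    validity: str
    perseveration_kind: str | None = None
    sro: int | None = None


@dataclass
class ScoredTranscript:
    participant_id: str
    group: str
    category: str
    entries: list[ScoredEntry]

    @property
    def valid_entries(self) -> list[ScoredEntry]:
        return [e for e in self.entries if e.validity == VALID]

    @property
    def n_valid(self) -> int:
        return len(self.valid_entries)


class RelationTable:
    """Directed word-pair relations used by the perseveration rules.

    Relations are symmetric in effect: producing APE then GORILLA (or
    GORILLA then APE) flags the second as a perseveration either way.
    """

    def __init__(self, triples: Iterable[tuple[str, str, str]] = ()):
        self._rel: dict[frozenset[str], str] = {}
        for a, b, relation in triples:
            key = frozenset((a.upper(), b.upper()))
            if relation not in (SUB_SUPERORDINATE, SAME_ENTITY_VARIANT, "subordinate_of"):
                raise ValueError(f"unknown relation {relation!r}")
            relation = SUB_SUPERORDINATE if relation == "subordinate_of" else relation
            existing = self._rel.get(key)
            if existing is not None and existing != relation:
                raise ValueError(f"conflicting relations for pair {sorted(key)}")
            self._rel[key] = relation

    def relation(self, a: str, b: str) -> str | None:
        return self._rel.get(frozenset((a.upper(), b.upper())))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            (row["word_a"], row["word_b"], row["relation"]) for _, row in df.iterrows()
        )


EMPTY_RELATIONS = RelationTable()


def score_transcript(
    entries: Sequence[RawEntry],
    table: FeatureTable,
    variant_map: VariantMap | None = None,
    relations: RelationTable = EMPTY_RELATIONS,
) -> ScoredTranscript:
    """Classify one participant/category utterance sequence and assign SRO.

    Classification looks only at earlier entries (first occurrences stay
    valid). The intrusion check precedes the perseveration check; when
    several perseveration rules fire, repetition takes precedence over
    same-entity variant, which takes precedence over sub/superordinate.
    """
    if not entries:
        return ScoredTranscript("", "", "", [])
    pids = {e.participant_id for e in entries}
    cats = {e.category for e in entries}
    if len(pids) > 1 or len(cats) > 1:
        raise ValueError("entries must share one (participant, category)")
    indices = [e.utterance_index for e in entries]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("utterance_index must be strictly increasing")

    category = entries[0].category.upper()
    scored: list[ScoredEntry] = []
    seen: list[str] = []           # canonical forms of earlier entries
    seen_valid: list[str] = []     # canonical forms of earlier *valid* entries
    sro = 0
    for raw in entries:
        word = standardize(raw.raw_word, variant_map)
        if (word, category) not in table:
            scored.append(ScoredEntry(word, raw.utterance_index, INTRUSION))
            seen.append(word)
            continue
        kind = None
        if word in seen:
            kind = REPETITION
        else:
            for earlier in seen_valid:
                rel = relations.relation(word, earlier)
                if rel == SAME_ENTITY_VARIANT:
                    kind = SAME_ENTITY_VARIANT
                    break
            if kind is None:
                for earlier in seen_valid:
                    if relations.relation(word, earlier) == SUB_SUPERORDINATE:
                        kind = SUB_SUPERORDINATE
                        break
        if kind is not None:
            scored.append(ScoredEntry(word, raw.utterance_index, PERSEVERATION, kind))
        else:
            sro += 1
            scored.append(ScoredEntry(word, raw.utterance_index, VALID, sro=sro))
            seen_valid.append(word)
        seen.append(word)
    return ScoredTranscript(
        entries[0].participant_id, entries[0].group, category, scored
    )


def merge_categories(transcripts: Sequence[ScoredTranscript]) -> pd.DataFrame:
    """Stack valid entries of one participant's per-category transcripts.

    SRO restarts at 1 for each category and is kept as assigned; the
    result has columns participant_id, category, canonical_word, sro.
    """
    pids = {t.participant_id for t in transcripts}
    if len(pids) > 1:
        raise ValueError("transcripts must come from one participant")
    cats = [t.category for t in transcripts]
    if len(cats) != len(set(cats)):
        raise ValueError("duplicate category in merge")
    rows = [
        {
            "participant_id": t.participant_id,
            "category": t.category,
            "canonical_word": e.canonical_word,
            "sro": e.sro,
        }
        for t in transcripts
        for e in t.valid_entries
    ]
    return pd.DataFrame(rows, columns=["participant_id", "category", "canonical_word", "sro"])


def build_observation_table(
    transcripts: Sequence[ScoredTranscript],
    table: FeatureTable,
    dictionary: Iterable[str] | None = None,
    *,
    in_list_scope: str = "category",
    sonority: lexical.SonorityTable = lexical.DEFAULT_SONORITY,
) -> pd.DataFrame:
    """Per-participant observation table: one row per valid word, 17 columns.

    Rated features are joined from the lexicon (missing stays NaN);
    computed features come from :mod:`srofluency.lexical`. The in-list
    Levenshtein comparison set is the participant's other valid words,
    within the same category (default) or across both categories
    (``in_list_scope="all"``).
    """
    if in_list_scope not in ("category", "all"):
        raise ValueError("in_list_scope must be 'category' or 'all'")
    merged = merge_categories(transcripts)
    all_words = list(merged["canonical_word"])
    rows = []
    for _, rec in merged.iterrows():
        word, category = rec["canonical_word"], rec["category"]
        entry = table.get(word, category)
        if in_list_scope == "category":
            pool = [
                w
                for w, c in zip(merged["canonical_word"], merged["category"])
                if c == category and w != word
            ]
        else:
            pool = [w for w in all_words if w != word]
        computed = lexical.compute_word_features(
            word,
            entry.phonemic if entry else "",
            lexicon_syllables=entry.syllables if entry else None,
            co_words=pool,
            dictionary=dictionary,
            sonority=sonority,
        )
        row: dict[str, object] = {
            "participant_id": rec["participant_id"],
            "category": category,
            "canonical_word": word,
            SRO: rec["sro"],
        }
        for feat in RATED_FEATURES:
            row[feat] = entry.rating(feat) if entry else math.nan
        for feat in COMPUTED_FEATURES:
            val = computed[feat]
            row[feat] = math.nan if val is None else val
        rows.append(row)
    columns = ["participant_id", "category", "canonical_word", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)


def positional_sets(
    transcript: ScoredTranscript,
    block_size: int = 5,
    n_blocks: int = 4,
) -> dict[str, list[ScoredEntry]]:
    """Group valid entries into SRO blocks (1–5, 6–10, 11–15, 16–20, …).

    Entries beyond the last requested block go under ``"overflow"``.
    Empty blocks are omitted; a final partial block keeps its range label.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    blocks: dict[str, list[ScoredEntry]] = {}
    for e in transcript.valid_entries:
        block_idx = (e.sro - 1) // block_size
        if block_idx >= n_blocks:
            label = "overflow"
        else:
            lo = block_idx * block_size + 1
            label = f"{lo}-{lo + block_size - 1}"
        blocks.setdefault(label, []).append(e)
    return blocks


@dataclass
class CohortCounts:
    """Validity tallies per participant and pooled over the cohort."""

    per_participant: pd.DataFrame  # participant_id, group, valid, intrusions, perseverations
    total_words: int
    total_valid: int
    total_intrusions: int
    total_perseverations: int

    @property
    def intrusion_rate(self) -> float:
        return self.total_intrusions / self.total_words if self.total_words else 0.0

    @property
    def perseveration_rate(self) -> float:
        return self.total_perseverations / self.total_words if self.total_words else 0.0


def tally_counts(transcripts: Iterable[ScoredTranscript]) -> CohortCounts:
    """Raw CFT score (valid count over categories) and cohort-level rates.

    Rates are proportions of the total number of words generated.
    """
    per: dict[tuple[str, str], dict[str, int]] = {}
    for t in transcripts:
        key = (t.participant_id, t.group)
        counts = per.setdefault(key, {VALID: 0, INTRUSION: 0, PERSEVERATION: 0})
        for e in t.entries:
            counts[e.validity] += 1
    rows = [
        {
            "participant_id": pid,
            "group": group,
            "valid": c[VALID],
            "intrusions": c[INTRUSION],
            "perseverations": c[PERSEVERATION],
        }
        for (pid, group), c in per.items()
    ]
    df = pd.DataFrame(
        rows, columns=["participant_id", "group", "valid", "intrusions", "perseverations"]
    )
    return CohortCounts(
        per_participant=df,
        total_words=int(df[["valid", "intrusions", "perseverations"]].to_numpy().sum()) if len(df) else 0,
        total_valid=int(df["valid"].sum()) if len(df) else 0,
        total_intrusions=int(df["intrusions"].sum()) if len(df) else 0,
        total_perseverations=int(df["perseverations"].sum()) if len(df) else 0,
    )


def load_transcripts(path: str | Path) -> list[list[RawEntry]]:
    """Read a transcript CSV into per-(participant, category) entry lists.

    Columns: participant_id, group, category, utterance_index, raw_word.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "raw_word": str})
    sequences = []
    for (_, _), sub in df.groupby(["participant_id", "category"], sort=False):
        sub = sub.sort_values("utterance_index")
        sequences.append(
            [
                RawEntry(
                    participant_id=str(r["participant_id"]),
                    group=str(r["group"]),
                    category=str(r["category"]),
                    utterance_index=int(r["utterance_index"]),
                    raw_word=str(r["raw_word"]),
                )
                for _, r in sub.iterrows()
            ]
        )
    return sequences


def scored_to_frame(transcripts: Iterable[ScoredTranscript]) -> pd.DataFrame:
    """Flatten scored transcripts to the output CSV dialect."""
    rows = [
        {
            "participant_id": t.participant_id,
            "group": t.group,
            "category": t.category,
            "utterance_index": e.utterance_index,
            "canonical_word": e.canonical_word,
            "validity": e.validity,
            "perseveration_kind": e.perseveration_kind or "",
            "sro": "" if e.sro is None else e.sro,
        }
        for t in transcripts
        for e in t.entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "category", "utterance_index",
            "canonical_word", "validity", "perseveration_kind", "sro",
        ],
    )
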