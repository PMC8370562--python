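"""Feature lexicon, variant-standardisation map and dictionary word list.

The lexicon assigns each canonical word, within its semantic category
(e.g. ANIMALS, FRUITS), ten rated psycholinguistic features (typicality,
age of acquisition, concreteness, frequency, prevalence, recognition
time, valence, arousal, dominance, body-object interaction) plus a
phonemic transcription from which the non-semantic features are derived.
Any rating may be missing; missing cells stay missing (NaN) and are
handled downstream by pairwise-complete correlation — never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RATED_FEATURES",
    "COMPUTED_FEATURES",
    "FEATURE_NAMES",
    "SRO",
    "LexiconEntry",
    "FeatureTable",
    "VariantMap",
    "LexiconError",
    "load_feature_table",
    "write_feature_table",
    "load_variant_map",
    "load_dictionary",
    "standardize",
]

SRO = "serial_recall_order"

#: The ten rated semantic features carried by the lexicon, with their
#: closed bounds (None = unbounded, e.g. z-scored norms).
RATED_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "typicality": (1.0, 7.0),
    "age_of_acquisition": (0.0, None),
    "concreteness": (1.0, 5.0),
    "frequency": (1.0, 7.0),
    "prevalence": (None, None),
    "recognition_time": (None, None),
    "valence": (1.0, 9.0),
    "arousal": (1.0, 9.0),
    "dominance": (1.0, 9.0),
    "body_object_interaction": (1.0, 7.0),
}

RATED_FEATURES: tuple[str, ...] = tuple(RATED_BOUNDS)

#: The six non-semantic features derived from orthography/phonology.
COMPUTED_FEATURES: tuple[str, ...] = (
    "graphemes_count",
    "syllables_count",
    "consonant_vowel_ratio",
    "phonological_complexity",
    "in_list_levenshtein",
    "dictionary_neighbourhood",
)

#: All 17 item-level features, serial recall order first.
FEATURE_NAMES: tuple[str, ...] = (SRO,) + RATED_FEATURES + COMPUTED_FEATURES

# TSV column -> canonical feature name
_COLUMN_ALIASES = {
    "aoa": "age_of_acquisition",
    "boi": "body_object_interaction",
}


class LexiconError(ValueError):
    """Raised on malformed lexicon/variant-map input."""


@dataclass(frozen=True)
class LexiconEntry:
    """One canonical word of one category with its rated features.

    Missing ratings are ``nan``; ``phonemic`` is the verbatim UTF-8
    transcription (tokenisation lives in :mod:`srofluency.lexical`).
    """

    word: str
    category: str
    ratings: Mapping[str, float]
    phonemic: str = ""
    syllables: int | None = None

    def rating(self, feature: str) -> float:
        return self.ratings.get(feature, math.nan)


class FeatureTable:
    """Lexicon entries keyed by (word, category)."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        for e in entries:
            key = (e.word, e.category)
            if key in self._entries:
                raise LexiconError(f"duplicate lexicon entry {key}")
            if not e.word or e.word != e.word.strip() or e.word != e.word.upper():
                raise LexiconError(f"word {e.word!r} must be uppercase and trimmed")
            self._entries[key] = e
        self.feature_names = FEATURE_NAMES

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def categories(self) -> set[str]:
        return {c for _, c in self._entries}

    def words(self, category: str | None = None) -> list[str]:
        return sorted(
            w for w, c in self._entries if category is None or c == category
        )

    def get(self, word: str, category: str) -> LexiconEntry | None:
        return self._entries.get((word, category))

    def lookup(self, word: str, category: str, feature: str) -> float:
        """Return a rated feature value, NaN if unrated.

        Raises :class:`KeyError` when (word, category) is not in the
        lexicon — the distinct signal used for intrusion detection.
        """
        if feature not in RATED_FEATURES:
            raise ValueError(f"{feature!r} is not a rated feature")
        entry = self._entries.get((word, category))
        if entry is None:
            raise KeyError(f"({word}, {category}) not in lexicon")
        return entry.rating(feature)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self._entries.values():
            row = {"word": e.word, "category": e.category}
            row.update({f: e.rating(f) for f in RATED_FEATURES})
            row["phonemic"] = e.phonemic
            row["syllables"] = e.syllables
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class VariantMap:
    """Many-to-one map from raw forms to canonical lexicon headwords."""

    pairs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, str]) -> "VariantMap":
        vm = cls()
        for raw, canonical in pairs.items():
            vm.pairs[_normalise(raw)] = _normalise(canonical)
        return vm

    def resolve(self, raw: str) -> str:
        w = _normalise(raw)
        return self.pairs.get(w, w)


def _normalise(raw: str) -> str:
    return " ".join(raw.split()).upper()


def standardize(raw: str, variant_map: VariantMap | None = None) -> str:
    """Case-fold, trim and map a raw utterance to its canonical form.

    Unknown words pass through uppercased; lexicon membership is judged
    later, during transcript scoring. Idempotent by construction.
    """
    if not raw or not raw.strip():
        raise ValueError("empty utterance")
    if variant_map is None:
        return _normalise(raw)
    return variant_map.resolve(raw)


def _parse_cell(value, row_no: int, column: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if s == "":
        return math.nan
    try:
        return float(s)
    except ValueError as exc:
        raise LexiconError(
            f"row {row_no}: column {column!r}: unparseable value {s!r}"
        ) from exc


def load_feature_table(path: str | Path) -> FeatureTable:
    """Load the lexicon TSV, validating bounds row by row.

    Columns: word, category, typicality, aoa, concreteness, frequency,
    prevalence, recognition_time, valence, arousal, dominance, boi,
    phonemic, and optionally syllables. Empty cells become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=_COLUMN_ALIASES)
    missing_cols = {"word", "category"} - set(df.columns)
    if missing_cols:
        raise LexiconError(f"lexicon missing columns {sorted(missing_cols)}")

    entries = []
    for idx, row in df.iterrows():
        row_no = int(idx) + 2  # 1-based + header line
        ratings = {}
        for feat in RATED_FEATURES:
            if feat not in df.columns:
                continue
            val = _parse_cell(row[feat], row_no, feat)
            lo, hi = RATED_BOUNDS[feat]
            if not math.isnan(val):
                if (lo is not None and val < lo) or (hi is not None and val > hi):
                    raise LexiconError(
                        f"row {row_no}: column {feat!r}: value {val} outside "
                        f"bounds [{lo}, {hi}]"
                    )
            ratings[feat] = val
        syll_raw = str(row.get("syllables", "")).strip()
        syllables = int(float(syll_raw)) if syll_raw else None
        entries.append(
            LexiconEntry(
                word=_normalise(row["word"]),
                category=_normalise(row["category"]),
                ratings=ratings,
                phonemic=str(row.get("phonemic", "")).strip(),
                syllables=syllables,
            )
        )
    return FeatureTable(entries)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a lexicon TSV that round-trips through load_feature_table."""
    df = table.to_frame()
    df = df.rename(columns={v: k for k, v in _COLUMN_ALIASES.items()})
    df["syllables"] = df["syllables"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)
    )
    df.to_csv(path, sep="\t", index=False)


def load_variant_map(path: str | Path, table: FeatureTable | None = None) -> VariantMap:
    """Load the raw→canonical TSV (columns raw, canonical, category).

    When a FeatureTable is supplied, canonical targets must exist in it
    for their category.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    vm = VariantMap()
    for _, row in df.iterrows():
        raw, canonical = _normalise(row["raw"]), _normalise(row["canonical"])
        if table is not None:
            category = _normalise(row.get("category", ""))
            if category and (canonical, category) not in table:
                raise LexiconError(
                    f"variant target ({canonical}, {category}) not in lexicon"
                )
        vm.pairs[raw] = canonical
    # canonical forms map to themselves so the map is idempotent
    for canonical in list(vm.pairs.values()):
        vm.pairs.setdefault(canonical, canonical)
    return vm


def load_dictionary(path: str | Path) -> frozenset[str]:
    """Load a plain-text word list (one word per line) for neighbourhood counts."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().upper()
            if w:
                words.add(w)
    return frozenset(words)
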