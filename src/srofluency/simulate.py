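"""Synthetic lexicons and two-group fluency cohorts with planted structure.

The generator emulates the study conditions of a two-group, 1-minute,
two-category (animals/fruits) fluency design: per-participant valid word
counts drawn from a truncated Normal(33.80, 6.65) split 58/42 between
animals and fruits, perseverations injected at a 7.7% rate and
intrusions at 0.6% (as proportions of all words generated).

Retrieval order is planted through a Gaussian copula: a word's latent
retrieval score is a weighted sum of normal scores of its features plus
independent noise; ordering a random word sample by the latent score
yields a serial recall order whose Spearman correlation with a feature
has closed-form expectation rho_s = (6/pi) * asin(a/2) for loading a,
so any target Spearman is calibrated analytically by
a = 2 * sin(pi * rho_s / 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .lexicon import RATED_BOUNDS, RATED_FEATURES, FeatureTable, LexiconEntry
from .scoring import RawEntry

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SimulatedCohort",
    "make_lexicon",
    "calibrate_copula",
    "simulate_participant",
    "simulate_cohort",
]

# z-score bounds used to squash unbounded rated features are identity
_DEFAULT_CATEGORIES = {"ANIMALS": 60, "FRUITS": 40}

_CONSONANT_LETTERS = "BDFGKLMNPRSTVZ"
_VOWEL_LETTERS = "AEIOU"


@dataclass
class GroupSpec:
    """Generation parameters for one cohort group."""

    label: str
    n_participants: int
    word_count_mean: float = 33.80
    word_count_sd: float = 6.65
    planted_rho: dict[str, float] = field(default_factory=dict)
    perseveration_rate: float = 0.077
    intrusion_rate: float = 0.006
    animal_share: float = 0.58  # from category means 19.60 / 33.80
    education_mean: float = 14.0
    education_sd: float = 2.3
    mmse_mean: float = 29.0
    mmse_sd: float = 1.0
    covariate_confounding: float = 0.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for f, r in self.planted_rho.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted rho for {f!r} must be in (-1, 1)")
        for rate in (self.perseveration_rate, self.intrusion_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")


@dataclass
class CohortSpec:
    """A full synthetic cohort: groups plus shared lexicon parameters."""

    groups: list[GroupSpec]
    words_per_category: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORIES)
    )
    feature_covariance: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        groups = [GroupSpec(**g) for g in cfg.pop("groups")]
        cov = cfg.pop("feature_covariance", None)
        return cls(
            groups=groups,
            feature_covariance=np.asarray(cov, dtype=float) if cov is not None else None,
            **cfg,
        )


def calibrate_copula(target_rho_s: float) -> float:
    """Latent Pearson loading for a target Spearman correlation.

    Inverts the bivariate-normal identity rho_s = (6/pi) asin(a/2):
    a = 2 sin(pi * rho_s / 6).
    """
    if not -1.0 < target_rho_s < 1.0:
        raise ValueError("target Spearman must be in (-1, 1)")
    return 2.0 * math.sin(math.pi * target_rho_s / 6.0)


def _make_word(rng: np.random.Generator, n_syllables: int) -> tuple[str, str]:
    """One synthetic word from a toy CV grammar, with its transcription."""
    letters = []
    for _ in range(n_syllables):
        letters.append(rng.choice(list(_CONSONANT_LETTERS)))
        letters.append(rng.choice(list(_VOWEL_LETTERS)))
        if rng.random() < 0.3:
            letters.append(rng.choice(list(_CONSONANT_LETTERS)))
    word = "".join(letters)
    return word, word.lower()


def make_lexicon(
    words_per_category: Mapping[str, int] | None = None,
    feature_covariance: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> FeatureTable:
    """Generate a synthetic feature lexicon.

    Rated features are drawn from a multivariate normal with the given
    covariance (identity by default) and squashed monotonically into
    each feature's bounds via the normal CDF, so rank structure — and
    hence any Spearman correlation — is preserved. Phonemic
    transcriptions come from a toy consonant-vowel grammar, making every
    computed feature well-defined. Deterministic given the seed.
    """
    words_per_category = dict(words_per_category or _DEFAULT_CATEGORIES)
    k = len(RATED_FEATURES)
    if feature_covariance is None:
        feature_covariance = np.eye(k)
    feature_covariance = np.asarray(feature_covariance, dtype=float)
    if feature_covariance.shape != (k, k):
        raise ValueError(f"feature covariance must be {k}x{k}")
    # reject non-PSD covariance up front
    eigvals = np.linalg.eigvalsh((feature_covariance + feature_covariance.T) / 2)
    if eigvals.min() < -1e-10:
        raise ValueError("feature covariance must be positive semi-definite")

    rng = np.random.default_rng(seed)
    entries = []
    used: set[str] = set()  # words unique across categories, so category
    # membership is unambiguous and cross-category injections are intrusions
    for category, n_words in words_per_category.items():
        z = rng.multivariate_normal(
            np.zeros(k), feature_covariance, size=n_words, method="svd"
        )
        for i in range(n_words):
            n_syll = int(rng.integers(1, 4))
            word, phonemic = _make_word(rng, n_syll)
            while word in used:
                word, phonemic = _make_word(rng, n_syll)
            used.add(word)
            ratings = {}
            for j, feat in enumerate(RATED_FEATURES):
                lo, hi = RATED_BOUNDS[feat]
                zj = z[i, j] / math.sqrt(max(feature_covariance[j, j], 1e-12))
                if lo is not None and hi is not None:
                    ratings[feat] = lo + (hi - lo) * stats.norm.cdf(zj)
                elif lo is not None:  # lower-bounded (age of acquisition)
                    ratings[feat] = lo + 2.0 + 8.0 * stats.norm.cdf(zj)
                else:  # unbounded z-scored norms
                    ratings[feat] = float(z[i, j])
            entries.append(
                LexiconEntry(
                    word=word,
                    category=category.upper(),
                    ratings=ratings,
                    phonemic=phonemic,
                )
            )
    return FeatureTable(entries)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (van der Waerden scores)."""
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def _latent_scores(
    lexicon_words: Sequence[str],
    feature_values: pd.DataFrame,
    planted_rho: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent retrieval score per word: copula-loaded features + noise."""
    n = len(lexicon_words)
    loadings = {f: calibrate_copula(r) for f, r in planted_rho.items()}
    total = 0.0
    latent = np.zeros(n)
    for f, a in loadings.items():
        latent += a * _normal_scores(feature_values[f].to_numpy())
        total += a * a
    resid = max(0.0, 1.0 - total)
    latent += math.sqrt(resid) * rng.standard_normal(n)
    return latent


def _rated_frame(lexicon: FeatureTable, category: str) -> pd.DataFrame:
    words = lexicon.words(category)
    data = {
        f: [lexicon.get(w, category).rating(f) for w in words] for f in RATED_FEATURES
    }
    return pd.DataFrame(data, index=words)


def simulate_participant(
    lexicon: FeatureTable,
    spec: GroupSpec,
    participant_id: str,
    seed: int | np.random.SeedSequence,
    categories: Sequence[str] = ("ANIMALS", "FRUITS"),
) -> dict[str, list[RawEntry]]:
    """Generate one participant's raw utterance sequences per category.

    Valid words are a uniform random sample of the category lexicon
    ordered by descending latent retrieval score (so serial position
    carries the calibrated Spearman relation to each planted feature);
    perseverations (repeats of an earlier word in the sequence) and
    intrusions (a word from the other category) are then injected at the
    specified rates at random positions.
    """
    rng = np.random.default_rng(seed)
    total = max(2, int(round(rng.normal(spec.word_count_mean, spec.word_count_sd))))
    if len(categories) == 1:
        counts = {categories[0].upper(): total}
    elif len(categories) == 2:
        n_first = min(max(1, int(round(total * spec.animal_share))), total - 1)
        counts = {categories[0].upper(): n_first, categories[1].upper(): total - n_first}
    else:
        raise ValueError("one or two categories are supported")

    # rates are proportions of all words generated; injections on top of
    # k valid words therefore use odds p/(1 - p_pers - p_intr)
    denom = 1.0 - spec.perseveration_rate - spec.intrusion_rate
    out: dict[str, list[RawEntry]] = {}
    for category in categories:
        category = category.upper()
        pool = lexicon.words(category)
        k = counts[category]
        if k > len(pool):
            raise ValueError(
                f"requested {k} words but category {category} has only {len(pool)}"
            )
        chosen_idx = rng.choice(len(pool), size=k, replace=False)
        chosen = [pool[i] for i in chosen_idx]
        feats = _rated_frame(lexicon, category).loc[chosen]
        # the latent score acts as retrieval difficulty: easy (low) words
        # come first, so serial position correlates positively with it
        latent = _latent_scores(chosen, feats, spec.planted_rho, rng)
        order = np.argsort(latent, kind="stable")
        sequence: list[str] = [chosen[i] for i in order]

        n_pers = rng.binomial(k, spec.perseveration_rate / denom)
        n_intr = rng.binomial(k, spec.intrusion_rate / denom)
        other = [c for c in lexicon.categories if c != category]
        other_pool = lexicon.words(other[0]) if other else []
        for _ in range(n_pers):
            pos = int(rng.integers(1, len(sequence) + 1))
            # repeat a word already produced before the insertion point
            earlier = [w for w in sequence[:pos] if (w, category) in lexicon]
            if not earlier:
                continue
            sequence.insert(pos, earlier[int(rng.integers(len(earlier)))])
        for _ in range(n_intr):
            if not other_pool:
                break
            pos = int(rng.integers(0, len(sequence) + 1))
            sequence.insert(pos, other_pool[int(rng.integers(len(other_pool)))])

        out[category] = [
            RawEntry(
                participant_id=participant_id,
                group=spec.label,
                category=category,
                utterance_index=i + 1,
                raw_word=word.lower(),
            )
            for i, word in enumerate(sequence)
        ]
    return out


@dataclass
class SimulatedCohort:
    """Everything a downstream pipeline needs, plus generation metadata."""

    lexicon: FeatureTable
    sequences: list[list[RawEntry]]  # one list per (participant, category)
    metadata: pd.DataFrame  # participant_id, group, education_years, mmse, raw_cft

    def transcripts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": e.participant_id,
                "group": e.group,
                "category": e.category,
                "utterance_index": e.utterance_index,
                "raw_word": e.raw_word,
            }
            for seq in self.sequences
            for e in seq
        ]
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full cohort: transcripts plus covariate metadata.

    Covariates (education, MMSE) are drawn independently of outcomes by
    default (``covariate_confounding = 0``), so null calibration of the
    downstream ANCOVA is exact; raw CFT score is the actual valid word
    count. Reproducible from the master seed.
    """
    master = np.random.SeedSequence(spec.seed)
    lex_seed, *group_seeds = master.spawn(1 + len(spec.groups))
    lexicon = make_lexicon(spec.words_per_category, spec.feature_covariance, lex_seed)

    sequences: list[list[RawEntry]] = []
    meta_rows = []
    for gspec, gseed in zip(spec.groups, group_seeds):
        part_seeds = gseed.spawn(gspec.n_participants + 1)
        meta_rng = np.random.default_rng(part_seeds[-1])
        for i in range(gspec.n_participants):
            pid = f"{gspec.label}-{i + 1:03d}"
            per_cat = simulate_participant(lexicon, gspec, pid, part_seeds[i])
            raw_cft = 0
            for category, seq in per_cat.items():
                sequences.append(seq)
                seen: set[str] = set()
                for e in seq:
                    w = e.raw_word.upper()
                    if (w, category) in lexicon and w not in seen:
                        raw_cft += 1
                        seen.add(w)
            education = meta_rng.normal(gspec.education_mean, gspec.education_sd)
            education += gspec.covariate_confounding * (raw_cft - gspec.word_count_mean)
            mmse = min(30, max(24, int(round(meta_rng.normal(gspec.mmse_mean, gspec.mmse_sd)))))
            meta_rows.append(
                {
                    "participant_id": pid,
                    "group": gspec.label,
                    "education_years": round(float(education), 2),
                    "mmse": mmse,
                    "raw_cft": raw_cft,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    return SimulatedCohort(lexicon=lexicon, sequences=sequences, metadata=metadata)
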