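# Methods

## Scoring model

A category-fluency transcript is an ordered list of utterances for one
participant and one semantic category. Scoring proceeds in three rule
layers, applied to each utterance after case-folding, whitespace
trimming and variant standardisation (many-to-one raw → canonical map;
the canonical direction is owned by the map, not by code):

1. **Intrusion** — the canonical form is not in the lexicon for the
   target category. Membership is the only criterion; an unknown word is
   never guessed at.
2. **Perseveration** — the form repeats an earlier canonical form
   (repetition), is a sub-/superordinate of an earlier *valid* word, or
   is the same entity in a different form. Relations come from an
   editable relation table; when several rules fire, precedence is
   repetition > same-entity variant > sub/superordinate. The intrusion
   check runs first, so a repeated out-of-category word counts as an
   intrusion at each occurrence.
3. **Valid** — everything else; valid entries receive serial recall
   order (SRO) 1..n within the category, by production order.

Classification looks only backwards, so first occurrences always stay
valid, and permuting invalid entries never changes valid entries' SRO.
Flagged entries are retained with their flags for post-hoc tallies but
excluded from all feature analyses. Cohort-level perseveration and
intrusion rates are proportions of the total number of words generated.

## Item-level features

Ten rated features come from the lexicon and may be missing per cell;
missing ratings propagate to pairwise-complete correlation and are never
imputed. Six are computed:

* **graphemes count** — letters of the canonical form; spaces and
  hyphens are not counted. "Grapheme" is read as "letter", the reading
  consistent with the worked examples (OX = 2, CATERPILLAR = 11).
* **syllables count** — lexicon value when present, else the number of
  vowel-nucleus runs in the phonemic transcription.
* **consonant/vowel quantity ratio** — consonant phonemes over total
  phonemes. Transcriptions are tokenised symbol by symbol: each IPA
  symbol is one phoneme (a two-symbol diphthong counts as two), stress
  and length marks are ignored. This convention reproduces BUFFALO
  /bʌfələʊ/ = 3/7 = 0.43.
* **phonological complexity** — consonant clusters are maximal runs of
  consonant tokens; a singleton cluster scores its class sonority
  (voiceless stop 7, voiced stop 6, affricate 6, voiceless fricative 5,
  voiced fricative 4, nasal 3, liquid 2, glide 1 — the last four-value
  tail is configurable, the first four anchored to the published
  scoring model), and a longer cluster scores the sum of absolute
  differences of successive members' sonorities. The difference rule is
  inferred from the single documented multi-consonant case
  (/nt/ = |3−7| = 4) and is the main open convention in this feature;
  cluster scores are summed and divided by the syllable count
  (PHEASANT: (5+4+4)/2 = 6.5).
* **in-list orthographic Levenshtein distance** — mean unit-cost edit
  distance (via edlib) from a word to the participant's other valid
  words, computed on space-stripped uppercase forms. Default comparison
  scope is the same category; an all-words mode is available. An empty
  comparison set yields a missing value, not zero.
* **dictionary orthographic neighbourhood** — count of dictionary words
  at edit distance exactly 1; the word itself never counts. An empty
  dictionary is an error (distinct from a legitimate zero).

## Correlation profiles

Spearman's ρ is the product-moment correlation of mid-ranks
(tie-corrected), computed per participant over the merged categories
under pairwise deletion. A coefficient needs ≥ 3 complete pairs and a
non-constant vector, a p-value ≥ 4 pairs; below that the cell is
missing with a reason. p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df, standard at the 19–43 observations a
participant contributes; an exact permutation option exists for tiny n.
All 136 unordered pairs are computed; only the 16 SRO-anchored
coefficients are analysed further, after Fisher's rho-to-z
transformation. Plain atanh is used with no sample-size scaling: group
comparisons are invariant to a common monotone rescaling, and the
√((n−3)/1.06) standardised variant is exposed as a caller-side choice by
transforming the returned ρ instead.

## Feature graphs

Edges are formed by strict inequality p < α; missing p never forms an
edge. The four nodal metrics follow the formulas above with these
conventions: betweenness uses the fractional (all shortest paths) count
over ordered pairs, normalised by (N−1)(N−2) — for the hub of a star
this evaluates to 1, the saturation value of the printed denominator;
disconnected pairs contribute 0 to efficiency sums (1/∞ = 0); local
efficiency is computed inside the subgraph induced by the node's
neighbours with the node itself removed, and is 0 for degree < 2. The
edge-forming α is selected by building each participant's graph at 0.05
and 0.01, computing graph cost efficiency (mean nodal global efficiency
minus mean nodal cost), and running a paired two-tailed t-test across
participants; ties default to 0.05 with a warning. All metrics are
validated in the test suite against brute-force path enumeration on
small graphs and against networkx.

## Cohort statistics

The group comparison is a linear model: outcome ~ group + education +
MMSE + raw CFT score, with the group F from the full-vs-restricted model
comparison and partial η² = SS_group/(SS_group + SS_error). Listwise
deletion handles missing covariates. With no covariates this reduces
exactly to a one-way ANOVA (F = t²). Positional-set models (means of a
rated feature over SRO blocks 1–5, 6–10, …) drop the raw-score
covariate, since the raw score is a property of the whole minute, not
of a block. Edge-frequency comparisons are Pearson chi-square without
continuity correction, φ = √(χ²/n), degenerate when a margin is zero.
Outlier screening uses Q1 − k·IQR / Q3 + k·IQR with k = 2.28 (outliers)
and 1.5 (extreme values); quartiles use linear interpolation between
order statistics — the flags depend on this convention. Partial Spearman
rank-transforms all variables, residualises on covariate ranks, and
refers t to n−2−k df. Performance labels classify a score's percentile
(fraction of reference scores ≤ score) against the 24th/8th/2nd
cut-offs; the cut-off percentile itself falls in the lower band (a score
exactly at the 24th percentile is "low average"). Shapiro–Wilk and
Levene checks are advisories delegated to scipy.

## Synthetic cohorts

The generator reproduces the study conditions rather than
psycholinguistic dynamics. Defaults: valid words per participant ~
Normal(33.80, 6.65) truncated at 2, split 58/42 animals/fruits (the
ratio of the per-category means 19.60/14.20); perseveration rate 7.7%
and intrusion rate 0.6% of all generated words; two groups of 45. The
lexicon simulator draws rated features from a multivariate normal
(identity covariance by default) squashed monotonically into each
feature's bounds, and builds words from a toy consonant-vowel grammar so
every computed feature is defined.

Retrieval order is planted through a Gaussian copula. A target Spearman
ρ_s between SRO and a feature is converted to a latent Pearson loading
a = 2 sin(πρ_s/6); each sampled word's latent "retrieval difficulty" is
a × (normal scores of the feature) + √(1−Σa²) × noise, and the word
sample is ordered by ascending difficulty. Because the sample is drawn
uniformly *before* ordering, the latent/feature pair keeps the full
copula within the sample and the in-sample Spearman has the calibrated
expectation (an alternative — scoring the whole lexicon and taking the
top k — truncates the latent distribution and attenuates the realised
correlation substantially, so it is not used). Perseverations are
injected as plain repetitions of an earlier word and intrusions as words
from the other category, at positions chosen uniformly; injection
frequencies use the odds p/(1−p_pers−p_intr) so the expected proportions
of total words match the target rates. Covariates (education, MMSE) are
generated independently of outcomes by default, making null ANCOVA
calibration exact; a confounding knob couples education to the raw
score for stress tests.

What the simulator does **not** emulate: semantic clustering and
switching dynamics, retrieval timing, real norm distributions (the
fixture lexicon's ratings are synthetic stand-ins apart from a handful
of published anchor values), and discreteness of real rating scales.
Passing recovery and calibration tests therefore demonstrates
correctness of the estimators under the stated generative model, not
fidelity to any real cohort.

Two quantitative caveats, both visible in the tests' tolerances: the
sample Spearman estimator carries a small-sample bias of order 1/n
(≈ −0.013 at ρ = 0.6, n = 40), and merging two categories of unequal
length attenuates the merged coefficient relative to the per-category
one, because merged ranks key on absolute position rather than
within-category quantile. Parameter-recovery checks therefore plant and
measure within a single 40-word category; planted effects in two-group
pipelines remain clearly detectable after merging but are numerically
smaller than their per-category targets.

## Problem sizes and numerics

Test-suite simulations use 200 participants × 40 words per planted
target, 1000 random graphs of ≤ 6 nodes for oracle equivalence, and
1000 null replicates of 45+45 for ANCOVA calibration — sizes at which
Monte-Carlo error is comfortably inside the asserted tolerances
(±0.05 for recovery; ±2 SE of the nominal 5% for calibration). All
randomness flows from numpy SeedSequence spawning, so every pipeline
output is byte-identical across runs with the same master seed.
Degenerate inputs are defined, not patched: constant vectors give
missing correlations, |ρ| = 1 gives the smallest representable p with a
flag, a perfectly covariate-explained outcome gives F = 0, and empty
comparison sets give missing values rather than zeros.
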