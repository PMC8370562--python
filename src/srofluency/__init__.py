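"""srofluency: item-level scoring of category fluency transcripts.

Quantifies semantic memory by correlating the serial recall order (SRO)
of words produced in a timed category-fluency task with 16 semantic and
non-semantic word features, summarising the correlation structure as a
binary graph, and comparing groups with covariate-adjusted statistics.
Ships a synthetic-cohort simulator so the whole pipeline is testable
without participant data.
"""

from importlib import resources

from .lexicon import (
    COMPUTED_FEATURES,
    FEATURE_NAMES,
    RATED_FEATURES,
    SRO,
    FeatureTable,
    LexiconEntry,
    VariantMap,
    load_dictionary,
    load_feature_table,
    load_variant_map,
    standardize,
    write_feature_table,
)
from .lexical import (
    DEFAULT_SONORITY,
    PhonemicString,
    SonorityTable,
    consonant_ratio,
    dictionary_neighbourhood,
    grapheme_count,
    in_list_old,
    levenshtein,
    phonological_complexity,
    syllable_count,
    tokenize_phonemic,
)
from .scoring import (
    RawEntry,
    RelationTable,
    ScoredEntry,
    ScoredTranscript,
    build_observation_table,
    load_transcripts,
    merge_categories,
    positional_sets,
    score_transcript,
    tally_counts,
)
from .correlations import (
    CorrelationMatrix,
    CorrelationProfile,
    fisher_z,
    full_matrix,
    spearman,
    spearman_p,
    sro_profile,
)
from .graph import (
    EdgeRuleReport,
    FeatureGraph,
    NodalMetrics,
    betweenness,
    build_graph,
    degree,
    global_efficiency,
    graph_cost_efficiency,
    local_efficiency,
    nodal_metrics,
    select_edge_rule,
    shortest_paths,
)
from .cohort import (
    ancova,
    bonferroni_threshold,
    chi_square_edges,
    classify_performance,
    cross_category_slope,
    outlier_flags,
    partial_spearman,
    positional_mean,
)
from .simulate import (
    CohortSpec,
    GroupSpec,
    SimulatedCohort,
    calibrate_copula,
    make_lexicon,
    simulate_cohort,
    simulate_participant,
)
from .pipeline import PipelineResult, run_pipeline, run_pipeline_from_spec

__version__ = "0.1.0"


def _data_path(name: str):
    return resources.files("srofluency.data") / name


def fixture_lexicon() -> FeatureTable:
    """Small bundled lexicon. Ratings are synthetic stand-ins except the
    handful of published anchor values; real-data users must supply
    their own norms."""
    return load_feature_table(_data_path("fixture_lexicon.tsv"))


def fixture_variant_map() -> VariantMap:
    return load_variant_map(_data_path("fixture_variants.tsv"))


def fixture_relations() -> RelationTable:
    return RelationTable.from_tsv(_data_path("fixture_relations.tsv"))


def fixture_dictionary() -> frozenset[str]:
    return load_dictionary(_data_path("fixture_dictionary.txt"))
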