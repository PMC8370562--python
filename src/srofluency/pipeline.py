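"""End-to-end pipeline: transcripts -> profiles -> graphs -> group statistics.

Ties the modules together in the order the scoring methodology
prescribes: score and validate each transcript, merge categories into
per-participant observation tables, compute the 17x17 Spearman matrices
and the 16 SRO-anchored Fisher-z coefficients, select the edge-forming
significance rule by graph cost efficiency, extract the SRO node's
metrics, and compare groups by ANCOVA (education, MMSE and raw fluency
score as covariates) plus chi-square edge-frequency tests.

Every artefact is also rendered to deterministic CSV/JSON text so that a
fixed master seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from . import cohort as cohort_stats
from .correlations import CorrelationMatrix, full_matrix, sro_profile
from .graph import EdgeRuleReport, build_graph, nodal_metrics, select_edge_rule
from .lexicon import SRO, FeatureTable
from .scoring import (
    build_observation_table,
    scored_to_frame,
    score_transcript,
    tally_counts,
)
from .simulate import CohortSpec, SimulatedCohort, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_from_spec"]

_COVARIATES = ["education_years", "mmse", "raw_cft"]
_METRIC_NAMES = ["degree", "betweenness", "global_efficiency", "local_efficiency"]


@dataclass
class PipelineResult:
    scored: pd.DataFrame
    counts: pd.DataFrame
    profiles: pd.DataFrame       # wide: one row per participant, 16 z columns
    matrices: list[CorrelationMatrix]
    edge_rule: EdgeRuleReport
    sro_metrics: pd.DataFrame    # participant, degree, betweenness, ...
    edge_presence: pd.DataFrame  # participant x 16 SRO-edge indicators
    comparisons: pd.DataFrame    # ANCOVA table over 16 z's + 4 metrics
    edge_tests: pd.DataFrame     # chi-square edge-frequency tests

    def to_text_outputs(self) -> dict[str, str]:
        """Render every artefact as deterministic text (CSV/JSON)."""
        out = {
            "scored.csv": self.scored.to_csv(index=False),
            "counts.csv": self.counts.to_csv(index=False),
            "profiles.csv": self.profiles.to_csv(index=False, float_format="%.10g"),
            "sro_metrics.csv": self.sro_metrics.to_csv(index=False, float_format="%.10g"),
            "edge_presence.csv": self.edge_presence.to_csv(index=False),
            "comparisons.csv": self.comparisons.to_csv(index=False, float_format="%.10g"),
            "edge_tests.csv": self.edge_tests.to_csv(index=False, float_format="%.10g"),
            "edge_rule.json": json.dumps(self.edge_rule.to_dict(), indent=1, sort_keys=True),
        }
        return out


def run_pipeline(
    cohort: SimulatedCohort,
    lexicon: FeatureTable | None = None,
    alphas: tuple[float, float] = (0.05, 0.01),
) -> PipelineResult:
    """Run the full scoring and analysis pipeline on a cohort."""
    lexicon = lexicon or cohort.lexicon
    dictionary = set()
    for category in lexicon.categories:
        dictionary.update(lexicon.words(category))

    transcripts = [score_transcript(seq, lexicon) for seq in cohort.sequences if seq]
    by_participant: dict[str, list] = {}
    for t in transcripts:
        by_participant.setdefault(t.participant_id, []).append(t)

    counts = tally_counts(transcripts)

    matrices, profile_rows, metric_rows, presence_rows = [], [], [], []
    for pid, trs in by_participant.items():
        obs = build_observation_table(trs, lexicon, dictionary)
        m = full_matrix(obs, participant_id=pid)
        matrices.append(m)
        prof = sro_profile(m)
        row = {"participant_id": pid, "group": trs[0].group}
        row.update({f"z_{f}": prof.z[f] for f in prof.features})
        profile_rows.append(row)

    edge_rule = select_edge_rule(matrices, alphas)
    alpha = edge_rule.selected_alpha
    for m in matrices:
        g = build_graph(m, alpha)
        nm = nodal_metrics(g, SRO)
        metric_rows.append(
            {
                "participant_id": m.participant_id,
                "degree": nm.degree,
                "betweenness": nm.betweenness,
                "global_efficiency": nm.global_efficiency,
                "local_efficiency": nm.local_efficiency,
                "cost": nm.cost,
            }
        )
        i = g.index(SRO)
        pres = {"participant_id": m.participant_id}
        for j, f in enumerate(g.nodes):
            if f != SRO:
                pres[f] = int(g.adjacency[i, j])
        presence_rows.append(pres)

    profiles = pd.DataFrame(profile_rows)
    sro_metrics = pd.DataFrame(metric_rows)
    presence = pd.DataFrame(presence_rows)

    meta = cohort.metadata.set_index("participant_id")
    order = profiles["participant_id"]
    group = meta.loc[order, "group"].to_numpy()
    covariates = meta.loc[order, _COVARIATES].reset_index(drop=True)

    comp_rows = []
    outcome_cols = [c for c in profiles.columns if c.startswith("z_")]
    merged_metrics = sro_metrics.set_index("participant_id").loc[order]
    for col in outcome_cols + _METRIC_NAMES:
        values = (
            profiles[col].to_numpy()
            if col in profiles
            else merged_metrics[col].to_numpy(dtype=float)
        )
        res = cohort_stats.ancova(values, group, covariates, outcome_name=col)
        comp_rows.append(
            {
                "outcome": col,
                "F": res.f_statistic,
                "df1": res.df_num,
                "df2": res.df_den,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_squared,
            }
        )
    comparisons = pd.DataFrame(comp_rows)

    edge_rows = []
    presence_idx = presence.set_index("participant_id").loc[order]
    for f in presence_idx.columns:
        res = cohort_stats.chi_square_edges(
            presence_idx[f].to_numpy(), group, edge_label=f"{SRO}~{f}"
        )
        edge_rows.append(
            {
                "edge": res.edge,
                "chi_square": res.chi_square,
                "p": res.p,
                "phi": res.phi,
                "degenerate": res.degenerate,
            }
        )
    edge_tests = pd.DataFrame(edge_rows)

    return PipelineResult(
        scored=scored_to_frame(transcripts),
        counts=counts.per_participant,
        profiles=profiles,
        matrices=matrices,
        edge_rule=edge_rule,
        sro_metrics=sro_metrics,
        edge_presence=presence,
        comparisons=comparisons,
        edge_tests=edge_tests,
    )


def run_pipeline_from_spec(spec: CohortSpec) -> PipelineResult:
    """Simulate a cohort from a spec and run the full pipeline on it."""
    return run_pipeline(simulate_cohort(spec))
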