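"""Cohort-level statistics over correlation profiles and graph metrics.

Group comparisons are one-way ANCOVAs (a linear model with the group
factor plus covariates: years of education, MMSE, and the raw fluency
score), reporting the group F, p and partial eta squared. Edge
frequencies are compared with Pearson chi-square (phi effect size);
post hocs use positional-set means, the Hoaglin–Iglewicz–Tukey
2.28x IQR outlier rule, partial Spearman correlation, OLS cross-category
slopes, Bonferroni thresholds and percentile-based performance labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .correlations import spearman, spearman_p
from .scoring import ScoredTranscript
from .lexicon import FeatureTable

__all__ = [
    "GroupComparisonResult",
    "EdgeFrequencyResult",
    "PerformanceLabel",
    "ancova",
    "chi_square_edges",
    "positional_mean",
    "outlier_flags",
    "partial_spearman",
    "classify_performance",
    "cross_category_slope",
    "bonferroni_threshold",
    "normality_advisory",
    "variance_homogeneity_advisory",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    outcome: str
    f_statistic: float
    df_num: int
    df_den: int
    p: float
    partial_eta_squared: float
    adjusted_means: dict[str, float]
    n_used: int


def _design(group: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    g = (group == levels[1]).astype(float)
    cols = [np.ones_like(g), g]
    names = ["intercept", f"group[{levels[1]}]"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def ancova(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
    outcome_name: str = "outcome",
) -> GroupComparisonResult:
    """One-way ANCOVA for a two-level group factor.

    The group F comes from comparing the full model (group + covariates)
    with the covariates-only model; partial eta squared is
    SS_group / (SS_group + SS_error). Rows with any missing value are
    dropped listwise. With no covariates this reduces to a one-way ANOVA.
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(dict(covariates))
    mask = ~np.isnan(y)
    if covariates is not None:
        mask &= ~covariates.isna().any(axis=1).to_numpy()
    y, group = y[mask], group[mask]
    covariates = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    levels = sorted(pd.unique(group))
    if any((group == lev).sum() < 2 for lev in levels):
        raise ValueError("need at least two participants per group")

    X_full, names = _design(group, covariates)
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # identify a collinear column by leave-one-out rank
        for j in range(X_full.shape[1]):
            reduced = np.delete(X_full, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"rank-deficient design: column {names[j]!r} is collinear")
        raise ValueError("rank-deficient design")

    full = sm.OLS(y, X_full).fit()
    X_restricted = np.delete(X_full, 1, axis=1)  # drop the group column
    restricted = sm.OLS(y, X_restricted).fit()

    ss_group = float(restricted.ssr - full.ssr)
    ss_error = float(full.ssr)
    df_num = 1
    df_den = int(full.df_resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    tiny = 1e-12 * max(tss, 1.0)
    if ss_group <= tiny and ss_error <= tiny:
        # covariates alone already fit perfectly; the group adds nothing
        f_stat, p, ss_group = 0.0, 1.0, 0.0
    elif ss_error <= tiny:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_group / df_num) / (ss_error / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    eta = ss_group / (ss_group + ss_error) if (ss_group + ss_error) > 0 else 0.0

    # adjusted means: predictions at covariate means for each group level
    adjusted = {}
    for lev in levels:
        row = [1.0, 1.0 if lev == levels[1] else 0.0]
        if covariates is not None:
            row.extend(covariates.mean().to_numpy(dtype=float))
        adjusted[str(lev)] = float(np.asarray(row) @ full.params)

    return GroupComparisonResult(
        outcome=outcome_name,
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p=p,
        partial_eta_squared=float(eta),
        adjusted_means=adjusted,
        n_used=int(y.size),
    )


@dataclass(frozen=True)
class EdgeFrequencyResult:
    edge: str
    table: np.ndarray  # 2x2 group x presence counts
    chi_square: float
    p: float
    phi: float
    degenerate: bool


def chi_square_edges(
    presence: Sequence[int],
    group: Sequence[str],
    edge_label: str = "edge",
) -> EdgeFrequencyResult:
    """Pearson chi-square (no continuity correction) on a 2x2
    group x edge-presence table, with phi = sqrt(chi2 / n)."""
    presence = np.asarray(presence, dtype=int)
    group = np.asarray(group)
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    table = np.array(
        [
            [int(((group == lev) & (presence == 1)).sum()),
             int(((group == lev) & (presence == 0)).sum())]
            for lev in levels
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EdgeFrequencyResult(edge_label, table, math.nan, math.nan, math.nan, True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    phi = math.sqrt(chi2 / table.sum())
    return EdgeFrequencyResult(edge_label, table, float(chi2), float(p), phi, False)


def positional_mean(
    transcripts: Sequence[ScoredTranscript],
    table: FeatureTable,
    feature: str,
    block: tuple[int, int] = (1, 5),
    per_category: bool = False,
) -> pd.DataFrame:
    """Per-participant mean rated-feature value over an SRO block.

    The block is a closed SRO range within each category (merged default,
    so a (1, 5) block covers up to 10 words over two categories). Words
    without a rating are excluded; a block with no rated words yields NaN.
    """
    lo, hi = block
    rows: dict[tuple, list[float]] = {}
    participants: dict[tuple, tuple[str, str]] = {}
    for t in transcripts:
        key0 = (t.participant_id, t.category) if per_category else (t.participant_id,)
        participants.setdefault(key0, (t.participant_id, t.category if per_category else ""))
        for e in t.valid_entries:
            if not lo <= e.sro <= hi:
                continue
            entry = table.get(e.canonical_word, t.category)
            val = entry.rating(feature) if entry else math.nan
            key = (t.participant_id, t.category) if per_category else (t.participant_id,)
            participants[key] = (t.participant_id, t.category if per_category else "")
            if not math.isnan(val):
                rows.setdefault(key, []).append(val)
    out = []
    for key, (pid, cat) in participants.items():
        vals = rows.get(key, [])
        rec = {"participant_id": pid, "mean": float(np.mean(vals)) if vals else math.nan}
        if per_category:
            rec["category"] = cat
        out.append(rec)
    return pd.DataFrame(out)


def outlier_flags(
    values: Sequence[float],
    k: float = 2.28,
    extreme_k: float = 1.5,
) -> pd.DataFrame:
    """Hoaglin–Iglewicz–Tukey IQR screening.

    A value is an *outlier* when it lies beyond Q1 - k*IQR or Q3 + k*IQR
    (k = 2.28), and an *extreme value* analogously with extreme_k = 1.5.
    Quartiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(values)) < 4:
        raise ValueError("need at least four values")
    q1, q3 = np.nanpercentile(values, [25, 75])
    iqr = q3 - q1
    out_lo, out_hi = q1 - k * iqr, q3 + k * iqr
    ext_lo, ext_hi = q1 - extreme_k * iqr, q3 + extreme_k * iqr
    return pd.DataFrame(
        {
            "value": values,
            "outlier": (values < out_lo) | (values > out_hi),
            "extreme": (values < ext_lo) | (values > ext_hi),
        }
    )


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
) -> tuple[float, float]:
    """Spearman's partial non-parametric correlation.

    All variables are rank-transformed; x- and y-ranks are residualised
    on the covariate ranks (with intercept) and the residuals correlated.
    p uses t with df = n - 2 - #covariates. With no covariates this is a
    plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(dict(covariates))
    mask = ~(np.isnan(x) | np.isnan(y))
    if covariates is not None:
        mask &= ~covariates.isna().any(axis=1).to_numpy()
    x, y = x[mask], y[mask]
    n = x.size
    k = 0 if covariates is None else covariates.shape[1]
    if n < k + 4:
        raise ValueError("too few complete cases")
    if covariates is None or k == 0:
        rho = spearman(x, y)
        return rho, spearman_p(rho, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack(
        [np.ones(n)] + [stats.rankdata(covariates.loc[mask, c]) for c in covariates.columns]
    )
    res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    if np.ptp(res_x) == 0 or np.ptp(res_y) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, float(np.finfo(float).tiny)
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), df=df))


@dataclass(frozen=True)
class PerformanceLabel:
    label: str
    percentile: float
    cutoffs: tuple[float, float, float] = (24.0, 8.0, 2.0)


def classify_performance(
    score: float,
    reference: Sequence[float],
    cutoffs: tuple[float, float, float] = (24.0, 8.0, 2.0),
) -> PerformanceLabel:
    """Percentile-band performance label against a normative reference.

    Above the 24th percentile is within normal limits; (8th, 24th] is
    low average; (2nd, 8th] below average; at or below the 2nd percentile
    exceptionally low. The percentile is the percentage of reference
    scores less than or equal to the score.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference distribution")
    pct = float(stats.percentileofscore(reference, score, kind="weak"))
    c_wnl, c_low, c_exc = cutoffs
    if pct > c_wnl:
        label = "within_normal_limits"
    elif pct > c_low:
        label = "low_average"
    elif pct > c_exc:
        label = "below_average"
    else:
        label = "exceptionally_low"
    return PerformanceLabel(label, pct, cutoffs)


def cross_category_slope(
    animals: Sequence[float], fruits: Sequence[float]
) -> tuple[float, float, float]:
    """OLS regression of fruit counts on animal counts: (slope, intercept, p)."""
    animals = np.asarray(animals, dtype=float)
    fruits = np.asarray(fruits, dtype=float)
    if animals.size < 2:
        raise ValueError("need at least two paired counts")
    if np.ptp(animals) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(animals, fruits)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def bonferroni_threshold(alpha: float = 0.05, m: int = 20) -> float:
    """Family-wise threshold alpha/m (0.05/20 = 0.0025)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def normality_advisory(values: Sequence[float], alpha: float = 0.05) -> dict:
    """Shapiro–Wilk advisory (delegated to scipy); never blocks a pipeline."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    stat, p = stats.shapiro(values)
    return {"statistic": float(stat), "p": float(p), "normal": bool(p >= alpha)}


def variance_homogeneity_advisory(
    values: Sequence[float], group: Sequence[str], alpha: float = 0.05
) -> dict:
    """Levene advisory (delegated to scipy) on two-group spread equality."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group))
    samples = [values[group == lev] for lev in levels]
    stat, p = stats.levene(*samples)
    return {"statistic": float(stat), "p": float(p), "homogeneous": bool(p >= alpha)}
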