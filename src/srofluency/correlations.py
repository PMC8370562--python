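"""Per-participant correlation structure of the 17 item-level features.

Spearman's rho (product-moment correlation of mid-ranks, tie-corrected)
is computed for all 136 unordered feature pairs under pairwise deletion
of missing values. Two-tailed p-values use the t approximation
t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom. The 16
coefficients anchored on serial recall order form the participant's
correlation profile and are variance-stabilised with Fisher's rho-to-z
transformation z = atanh(rho) before any group statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import FEATURE_NAMES, SRO

__all__ = [
    "CorrelationMatrix",
    "CorrelationProfile",
    "spearman",
    "spearman_p",
    "spearman_p_exact",
    "fisher_z",
    "full_matrix",
    "sro_profile",
]

MIN_N_RHO = 3   # below this a coefficient is undefined
MIN_N_P = 4     # below this a p-value is undefined

_TINY_P = np.finfo(float).tiny


def spearman(x, y) -> float:
    """Spearman's rho over pairwise-complete pairs; NaN when undefined.

    Undefined for fewer than three complete pairs or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < MIN_N_RHO:
        return math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_p(rho: float, n: int) -> float:
    """Two-tailed p for a Spearman coefficient via the t approximation."""
    if math.isnan(rho) or n < MIN_N_P:
        return math.nan
    if abs(rho) >= 1.0:
        return float(_TINY_P)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_p_exact(x, y) -> float:
    """Exact-permutation two-tailed p, for very small samples (n < 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    res = stats.permutation_test(
        (x, y),
        lambda a, b: spearman(a, b),
        permutation_type="pairings",
        alternative="two-sided",
        n_resamples=np.inf,
    )
    return float(res.pvalue)


def fisher_z(rho: float) -> float:
    """Fisher's rho-to-z: z = atanh(rho) = 0.5*ln((1+rho)/(1-rho))."""
    if math.isnan(rho):
        return math.nan
    if abs(rho) >= 1.0:
        raise ValueError("Fisher z undefined for |rho| >= 1")
    return float(np.arctanh(rho))


@dataclass
class CorrelationMatrix:
    """17x17 Spearman rho / p / pairwise-n matrices for one participant."""

    participant_id: str
    features: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_obs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format unique pairs: feature_a, feature_b, rho, p, n_obs."""
        rows = []
        feats = self.features
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                rows.append(
                    {
                        "feature_a": a,
                        "feature_b": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "n_obs": self.n_obs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CorrelationProfile:
    """The 16 SRO-anchored coefficients of one participant, Fisher-z scaled."""

    participant_id: str
    features: tuple[str, ...]  # the 16 non-SRO features
    rho: pd.Series
    z: pd.Series
    n_obs: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.rho, "z": self.z, "n_obs": self.n_obs},
            index=pd.Index(self.features, name="feature"),
        )


def full_matrix(
    obs: pd.DataFrame,
    participant_id: str | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> CorrelationMatrix:
    """All 136 feature-to-feature Spearman correlations for one participant.

    ``obs`` is an observation table holding the 17 feature columns (one
    row per valid word, categories merged). Pairs with fewer than three
    complete observations or a constant column stay NaN.
    """
    if participant_id is None:
        ids = obs["participant_id"].unique() if "participant_id" in obs else ["?"]
        participant_id = str(ids[0])
    k = len(features)
    data = obs.loc[:, list(features)].to_numpy(dtype=float)
    if data.shape[0] < MIN_N_RHO:
        warnings.warn(
            f"participant {participant_id}: fewer than {MIN_N_RHO} observations; "
            "correlation matrix is all-missing"
        )
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_obs = np.zeros((k, k), dtype=int)
    for i in range(k):
        rho[i, i] = 1.0
        p[i, i] = 0.0
        n_obs[i, i] = int(np.sum(~np.isnan(data[:, i])))
        for j in range(i + 1, k):
            mask = ~(np.isnan(data[:, i]) | np.isnan(data[:, j]))
            n = int(mask.sum())
            n_obs[i, j] = n_obs[j, i] = n
            r = spearman(data[:, i], data[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = spearman_p(r, n)
    idx = pd.Index(features)
    return CorrelationMatrix(
        participant_id=participant_id,
        features=tuple(features),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_obs=pd.DataFrame(n_obs, index=idx, columns=idx),
    )


def sro_profile(matrix: CorrelationMatrix) -> CorrelationProfile:
    """Extract the 16 SRO-anchored coefficients and Fisher-z them."""
    others = tuple(f for f in matrix.features if f != SRO)
    rho = matrix.rho.loc[SRO, list(others)]
    z = rho.map(lambda r: math.nan if math.isnan(r) or abs(r) >= 1 else fisher_z(r))
    n_obs = matrix.n_obs.loc[SRO, list(others)]
    return CorrelationProfile(
        participant_id=matrix.participant_id,
        features=others,
        rho=rho,
        z=z,
        n_obs=n_obs,
    )
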