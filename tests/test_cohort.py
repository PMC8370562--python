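import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import srofluency as sf
from srofluency.cohort import (
    ancova,
    bonferroni_threshold,
    chi_square_edges,
    classify_performance,
    cross_category_slope,
    outlier_flags,
    partial_spearman,
    positional_mean,
)

from conftest import make_entries


def test_ancova_reduces_to_anova_without_covariates():
    rng = np.random.default_rng(0)
    y = rng.normal(size=30)
    g = np.array(["a"] * 15 + ["b"] * 15)
    res = ancova(y, g)
    t, p = stats.ttest_ind(y[g == "a"], y[g == "b"])
    assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_ancova_outcome_equal_to_covariate():
    rng = np.random.default_rng(1)
    cov = rng.normal(size=40)
    g = np.array(["a"] * 20 + ["b"] * 20)
    res = ancova(cov, g, pd.DataFrame({"c": cov}))
    assert res.f_statistic == pytest.approx(0.0, abs=1e-8)


def test_ancova_detects_planted_gap():
    rng = np.random.default_rng(2)
    n = 200
    g = np.array(["a"] * n + ["b"] * n)
    y = rng.normal(size=2 * n)
    y[n:] += 1.0  # 1 SD group gap
    cov = pd.DataFrame({"e": rng.normal(size=2 * n), "m": rng.normal(size=2 * n)})
    res = ancova(y, g, cov)
    assert res.p < 0.01
    assert res.partial_eta_squared > 0.1
    assert res.adjusted_means["b"] > res.adjusted_means["a"]


def test_ancova_collinear_design_errors():
    rng = np.random.default_rng(3)
    g = np.array(["a"] * 10 + ["b"] * 10)
    x = rng.normal(size=20)
    with pytest.raises(ValueError, match="collinear"):
        ancova(rng.normal(size=20), g, pd.DataFrame({"x": x, "x2": 2 * x}))


def test_ancova_null_calibration():
    """Type-I error of the group term stays at the nominal rate under the null."""
    rng = np.random.default_rng(4)
    g = np.array(["a"] * 45 + ["b"] * 45)
    B = 400
    rej = 0
    for _ in range(B):
        y = rng.normal(size=90)
        cov = pd.DataFrame(rng.normal(size=(90, 3)), columns=["e", "m", "c"])
        rej += ancova(y, g, cov).p < 0.05
    rate = rej / B
    se = math.sqrt(0.05 * 0.95 / B)
    assert abs(rate - 0.05) < 3 * se


def test_chi_square_closed_form():
    presence = np.array([1] * 30 + [0] * 15 + [1] * 15 + [0] * 30)
    group = np.array(["a"] * 45 + ["b"] * 45)
    res = chi_square_edges(presence, group)
    assert res.chi_square == pytest.approx(10.0)
    assert res.phi == pytest.approx(1 / 3)
    assert not res.degenerate


def test_chi_square_invariances():
    rng = np.random.default_rng(5)
    presence = rng.integers(0, 2, size=60)
    group = np.array(["a"] * 30 + ["b"] * 30)
    base = chi_square_edges(presence, group)
    swapped_groups = chi_square_edges(presence, np.where(group == "a", "b", "a"))
    swapped_presence = chi_square_edges(1 - presence, group)
    assert base.chi_square == pytest.approx(swapped_groups.chi_square)
    assert base.chi_square == pytest.approx(swapped_presence.chi_square)


def test_chi_square_degenerate_margin():
    presence = np.ones(90, dtype=int)
    group = np.array(["a"] * 45 + ["b"] * 45)
    res = chi_square_edges(presence, group)
    assert res.degenerate
    assert math.isnan(res.chi_square)

    identical = chi_square_edges(
        np.array([1, 0] * 20), np.array(["a", "a", "b", "b"] * 10)
    )
    assert identical.chi_square == pytest.approx(0.0)
    assert identical.phi == pytest.approx(0.0)


def test_positional_mean_block_average(lexicon):
    # first five animals with valence 7.00, 6.95, 5.84, 4.80, 6.42 -> 6.202
    # (fixture words chosen to carry those ratings)
    words = ["dog", "cat", "horse", "mouse", "fish"]
    vals = [lexicon.lookup(w.upper(), "ANIMALS", "valence") for w in words]
    t = sf.score_transcript(make_entries(words), lexicon)
    out = positional_mean([t], lexicon, "valence", block=(1, 5))
    assert out.loc[0, "mean"] == pytest.approx(np.mean(vals))

    # block beyond the participant's word count -> missing
    out2 = positional_mean([t], lexicon, "valence", block=(6, 10))
    assert math.isnan(out2.loc[0, "mean"])


def test_outlier_flags_arithmetic():
    # quartiles Q1=10, Q3=20 -> 2.28 bounds (-12.8, 42.8), 1.5 bounds (-5, 35)
    values = [10, 10, 10, 20, 20, 20, 40]
    q1, q3 = np.percentile(values, [25, 75])
    flags = outlier_flags(values)
    assert list(flags["outlier"]) == [False] * 7  # 40 < Q3 + 2.28*IQR
    assert flags.loc[6, "extreme"] == (40 > q3 + 1.5 * (q3 - q1))

    with_big = values + [50]
    flags2 = outlier_flags(with_big)
    q1b, q3b = np.percentile(with_big, [25, 75])
    assert bool(flags2.loc[7, "outlier"]) == (50 > q3b + 2.28 * (q3b - q1b))


def test_outlier_flags_monotone_in_k():
    rng = np.random.default_rng(6)
    values = rng.standard_t(df=2, size=50)
    n_flags = [outlier_flags(values, k=k)["outlier"].sum() for k in (0.5, 1.5, 2.28, 5.0)]
    assert n_flags == sorted(n_flags, reverse=True)
    assert outlier_flags(values, k=np.inf)["outlier"].sum() == 0


def test_partial_spearman_reductions():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=50), rng.normal(size=50)
    rho0, p0 = partial_spearman(x, y)
    assert rho0 == pytest.approx(sf.spearman(x, y))
    assert p0 == pytest.approx(sf.spearman_p(rho0, 50))

    # independent covariates barely move the estimate
    cov = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
    rho1, _ = partial_spearman(x, y, cov)
    assert abs(rho1 - rho0) < 0.25

    # y an exact monotone function of a covariate -> partial rho ~ 0
    z = rng.normal(size=200)
    y2 = np.exp(z)
    x2 = rng.normal(size=200)
    rho2, _ = partial_spearman(x2, y2, pd.DataFrame({"z": z}))
    assert abs(rho2) < 0.1


def test_classify_performance_bands():
    reference = np.arange(1, 101)  # percentile of k is exactly k
    assert classify_performance(50, reference).label == "within_normal_limits"
    assert classify_performance(24, reference).label == "low_average"  # boundary
    assert classify_performance(8, reference).label == "below_average"
    assert classify_performance(2, reference).label == "exceptionally_low"
    assert classify_performance(1, reference).label == "exceptionally_low"
    with pytest.raises(ValueError):
        classify_performance(5, [])


def test_cross_category_slope():
    animals = np.array([10, 15, 20, 25, 30.0])
    slope, intercept, _ = cross_category_slope(animals, 0.5 * animals)
    assert slope == pytest.approx(0.5)
    assert intercept == pytest.approx(0.0, abs=1e-12)

    rng = np.random.default_rng(8)
    a = rng.normal(20, 4, size=500)
    f = rng.normal(14, 3, size=500)
    s, _, p = cross_category_slope(a, f)
    assert abs(s) < 0.15 and p > 0.001

    with pytest.raises(ValueError, match="variance"):
        cross_category_slope([5, 5, 5], [1, 2, 3])


@pytest.mark.parametrize(
    "alpha, m, expected", [(0.05, 20, 0.0025), (0.05, 1, 0.05), (0.01, 16, 0.000625)]
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)
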