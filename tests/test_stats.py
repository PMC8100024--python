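import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonemorph.stats import (
    compare_k,
    compare_two,
    correlate_2d3d,
    dunn_posthoc,
    gate_tests,
    holm_sidak,
)


def test_gating_parametric_for_normal_equal_variance():
    rng = np.random.default_rng(0)
    a, b = rng.normal(10, 1, 12), rng.normal(10, 1, 12)
    family, shapiro_ps, levene_p, _ = gate_tests([a, b])
    assert family == "parametric"
    assert len(shapiro_ps) == 2 and all(p > 0.05 for p in shapiro_ps)
    assert levene_p > 0.05


def test_gating_nonparametric_for_skewed_data():
    rng = np.random.default_rng(1)
    a = np.exp(rng.normal(0, 1.5, 30))  # heavily lognormal
    b = rng.normal(1, 0.1, 30)
    family, *_ = gate_tests([a, b])
    assert family == "nonparametric"


def test_gating_small_or_degenerate_groups_warn():
    with pytest.warns(UserWarning, match="n < 3"):
        family, _, _, flags = gate_tests([[1.0, 2.0], [3.0, 4.0, 5.0]])
    assert family == "nonparametric" and "n<3" in flags
    with pytest.warns(UserWarning, match="constant"):
        family, _, _, flags = gate_tests([[2.0, 2.0, 2.0], [1.0, 3.0, 5.0]])
    assert "degenerate-variance" in flags


def test_compare_two_parametric_matches_scipy():
    rng = np.random.default_rng(2)
    a, b = rng.normal(5, 1, 10), rng.normal(6, 1, 10)
    res = compare_two(a, b, family="parametric")
    ref = sps.ttest_ind(a, b)
    assert res.test == "t"
    assert res.p_value == pytest.approx(ref.pvalue)


def test_compare_two_exact_mann_whitney_for_separated_groups():
    from math import comb

    a = np.arange(1.0, 9.0)
    b = np.arange(101.0, 109.0)
    res = compare_two(a, b, family="nonparametric")
    assert res.test == "mann-whitney"
    # fully separated samples: only the two extreme orderings, out of C(16, 8)
    assert res.p_value == pytest.approx(2.0 / comb(16, 8), rel=1e-12)


def test_compare_two_paired_modes():
    rng = np.random.default_rng(3)
    a = rng.normal(5, 1, 12)
    b = a + rng.normal(0.5, 0.2, 12)
    res = compare_two(a, b, family="parametric", paired=True)
    assert res.test == "paired t"
    assert res.p_value == pytest.approx(sps.ttest_rel(a, b).pvalue)
    res_np = compare_two(a, b, family="nonparametric", paired=True)
    assert res_np.test == "wilcoxon"


def test_compare_two_rejects_unknown_family_and_empty_group():
    with pytest.raises(ValueError, match="family"):
        compare_two([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], family="bayesian")
    with pytest.raises(ValueError, match="finite"):
        compare_two([np.nan], [1.0, 2.0])


def test_holm_sidak_closed_form():
    p = np.array([0.01, 0.04])
    adj = holm_sidak(p)
    assert adj[0] == pytest.approx(1.0 - (1.0 - 0.01) ** 2)
    assert adj[1] == pytest.approx(0.04)
    # against a direct implementation on random p-values, any order
    rng = np.random.default_rng(4)
    p = rng.uniform(0.001, 0.9, 7)
    order = np.argsort(p)
    m = len(p)
    expect = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, 1.0 - (1.0 - p[idx]) ** (m - rank))
        expect[idx] = min(1.0, running)
    assert np.allclose(holm_sidak(p), expect)


def test_dunn_posthoc_matches_manual_computation():
    groups = [[1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0, 8.0], [20.0, 21.0, 22.0, 23.0]]
    out = dunn_posthoc(groups, labels=["a", "b", "c"])
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    mr = [ranks[i * 4:(i + 1) * 4].mean() for i in range(3)]
    se = np.sqrt((n * (n + 1) / 12.0) * (1 / 4 + 1 / 4))
    z01 = (mr[0] - mr[1]) / se
    assert out.statistic.iloc[0] == pytest.approx(z01)
    assert out.p_raw.iloc[0] == pytest.approx(2 * sps.norm.sf(abs(z01)))
    assert list(out.contrast) == ["a vs b", "a vs c", "b vs c"]
    assert np.all(out.p_adj >= out.p_raw - 1e-15)


def test_dunn_tie_correction_changes_se():
    no_ties = dunn_posthoc([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    with_ties = dunn_posthoc([[1.0, 2.0, 2.0], [2.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    # tie-corrected variance is strictly smaller, so |z| grows for equal
    # mean-rank differences; just assert the term is active (different SEs)
    assert not np.allclose(no_ties.statistic, with_ties.statistic)


def test_compare_k_parametric_path():
    rng = np.random.default_rng(5)
    groups = [rng.normal(m, 1, 10) for m in (5.0, 5.2, 7.0)]
    res = compare_k(groups, labels=["SHAM", "CONT", "RIS"])
    assert res.test == "anova"
    assert res.p_value == pytest.approx(sps.f_oneway(*groups).pvalue)
    assert list(res.contrasts.contrast) == ["SHAM vs CONT", "SHAM vs RIS", "CONT vs RIS"]
    assert np.allclose(res.contrasts.p_adj, holm_sidak(res.contrasts.p_raw))


def test_compare_k_nonparametric_path():
    rng = np.random.default_rng(6)
    groups = [np.exp(rng.normal(m, 1.0, 12)) for m in (0.0, 0.0, 2.0)]
    res = compare_k(groups)
    assert res.test == "kruskal-wallis"
    assert res.p_value == pytest.approx(sps.kruskal(*groups).pvalue)
    assert len(res.contrasts) == 3


def test_compare_k_defers_to_two_groups():
    res = compare_k([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]], family="parametric")
    assert res.test == "t"


def test_correlate_2d3d_perfect_and_degenerate():
    rows = []
    for i in range(6):
        rows.append({"specimen": f"s{i}", "parameter": "Tb.A",
                     "value_2d": 30.0 + 5 * i, "value_3d": 28.0 + 5 * i})
        rows.append({"specimen": f"s{i}", "parameter": "Tb.Th",
                     "value_2d": 0.2, "value_3d": 0.15 + 0.01 * i})
    out = correlate_2d3d(pd.DataFrame(rows))
    tba = out[out.pair.str.startswith("Tb.A")].iloc[0]
    assert tba.r == pytest.approx(1.0)
    assert tba.n == 6
    with pytest.warns(UserWarning, match="zero variance|fewer than 3"):
        out2 = correlate_2d3d(pd.DataFrame(rows))
    tbth = out2[out2.pair.str.startswith("Tb.Th")].iloc[0]
    assert np.isnan(tbth.r)


def test_correlate_2d3d_ignores_incomplete_pairs():
    df = pd.DataFrame({
        "specimen": ["a", "b", "c", "d"],
        "parameter": ["Tb.Sp"] * 4,
        "value_2d": [0.3, 0.4, np.nan, 0.5],
        "value_3d": [0.25, 0.33, 0.4, 0.41],
    })
    out = correlate_2d3d(df)
    assert out.iloc[0].n == 3
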