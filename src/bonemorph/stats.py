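"""Group-comparison and correlation statistics for cohort measurement tables.

The pipeline mirrors common practice in preclinical skeletal studies:

* gating — every group is checked for normality (Shapiro–Wilk) and, jointly,
  for homogeneity of variances (Levene, mean-centred); only if all pass at
  alpha does the comparison run parametrically;
* two groups — unpaired Student's t-test, or the two-sided Mann–Whitney U
  (exact null distribution for n <= 10 per side) on the nonparametric route;
  a paired mode (paired t / Wilcoxon) is available for within-animal designs;
* three groups — one-way ANOVA with Holm–Šidák-adjusted pairwise t contrasts,
  or Kruskal–Wallis with tie-corrected Dunn z contrasts under the same
  Holm–Šidák step-down;
* 2D↔3D agreement — Pearson correlation of specimen-matched histology and
  micro-CT trabecular parameters, reported with per-modality means ± SDs.

No correction is applied across the many (compartment, zone, parameter)
cells — significance is per cell, which is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "gate_tests",
    "compare_two",
    "compare_k",
    "holm_sidak",
    "dunn_posthoc",
    "correlate_2d3d",
]


@dataclass
class ComparisonResult:
    """Outcome of one group comparison."""

    test: str
    statistic: float
    p_value: float
    family: str  # parametric | nonparametric
    shapiro_p: tuple = ()
    levene_p: float = float("nan")
    contrasts: pd.DataFrame | None = None  # pairwise post-hoc table
    flags: tuple = ()


def _clean(samples):
    out = []
    for s in samples:
        a = np.asarray(s, dtype=float)
        a = a[np.isfinite(a)]
        if len(a) == 0:
            raise ValueError("a group has no finite observations")
        out.append(a)
    return out


def gate_tests(samples, alpha: float = 0.05) -> tuple[str, tuple, float, tuple]:
    """Choose the test family for a set of group samples.

    Parametric iff every group passes Shapiro–Wilk at ``alpha`` AND Levene's
    test (mean-centred) passes at ``alpha``.  Groups with n < 3 or degenerate
    (zero-variance) groups force the nonparametric route with a warning.

    Returns ``(family, shapiro_ps, levene_p, flags)``.
    """
    samples = _clean(samples)
    flags = []
    if any(len(s) < 3 for s in samples):
        warnings.warn("group with n < 3: forcing nonparametric tests", stacklevel=2)
        return "nonparametric", (), float("nan"), ("n<3",)
    if any(np.ptp(s) == 0 for s in samples):
        warnings.warn("constant-valued group: forcing nonparametric tests", stacklevel=2)
        return "nonparametric", (), float("nan"), ("degenerate-variance",)
    shapiro_ps = tuple(float(sps.shapiro(s).pvalue) for s in samples)
    levene_p = float(sps.levene(*samples, center="mean").pvalue)
    family = (
        "parametric"
        if all(p > alpha for p in shapiro_ps) and levene_p > alpha
        else "nonparametric"
    )
    return family, shapiro_ps, levene_p, tuple(flags)


def _mwu_method(a, b) -> str:
    return "exact" if max(len(a), len(b)) <= 10 and not _has_ties(a, b) else "asymptotic"


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def compare_two(
    a,
    b,
    family: str = "auto",
    paired: bool = False,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison with optional automatic family gating.

    Parametric: Student's t (unpaired by default; ``paired=True`` for the
    within-animal OA-vs-HT design).  Nonparametric: two-sided Mann–Whitney U,
    exact when both groups have n <= 10 and no ties; Wilcoxon signed-rank
    when paired.
    """
    a, b = _clean([a, b])
    shapiro_ps: tuple = ()
    levene_p = float("nan")
    flags: tuple = ()
    if family == "auto":
        family, shapiro_ps, levene_p, flags = gate_tests([a, b], alpha)
    if family == "parametric":
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t"
        else:
            res = sps.ttest_ind(a, b)
            name = "t"
    elif family == "nonparametric":
        if paired:
            res = sps.wilcoxon(a, b)
            name = "wilcoxon"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=_mwu_method(a, b))
            name = "mann-whitney"
    else:
        raise ValueError(f"unknown family {family!r}")
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        family=family,
        shapiro_p=shapiro_ps,
        levene_p=levene_p,
        flags=flags,
    )


def holm_sidak(p_raw) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in the input order.

    Sorted ascending, p_(i) maps to 1 - (1 - p_(i))^(m - i + 1), with
    monotonicity enforced down the ordering.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    return multipletests(p_raw, method="holm-sidak")[1]


def dunn_posthoc(groups, labels=None) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after a Kruskal–Wallis omnibus.

    Mean ranks over the pooled sample, tie-corrected variance, two-sided
    normal p-values, Holm–Šidák step-down across the contrasts.
    """
    groups = _clean(groups)
    k = len(groups)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + len(g)].mean()))
        start += len(g)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"contrast": f"{labels[i]} vs {labels[j]}",
                         "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak(out["p_raw"].to_numpy())
    return out


def compare_k(
    groups,
    family: str = "auto",
    labels=None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Three-or-more-group comparison with post-hoc pairwise contrasts.

    Parametric: one-way ANOVA with pairwise t contrasts under Holm–Šidák.
    Nonparametric: Kruskal–Wallis with Dunn contrasts under the same
    step-down.  With fewer than three groups, defers to :func:`compare_two`.
    """
    groups = _clean(groups)
    if len(groups) < 3:
        return compare_two(*groups, family=family, alpha=alpha)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    shapiro_ps: tuple = ()
    levene_p = float("nan")
    flags: tuple = ()
    if family == "auto":
        family, shapiro_ps, levene_p, flags = gate_tests(groups, alpha)
    if family == "parametric":
        omni = sps.f_oneway(*groups)
        name = "anova"
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                t = sps.ttest_ind(groups[i], groups[j])
                rows.append({"contrast": f"{labels[i]} vs {labels[j]}",
                             "statistic": float(t.statistic),
                             "p_raw": float(t.pvalue)})
        contrasts = pd.DataFrame(rows)
        contrasts["p_adj"] = holm_sidak(contrasts["p_raw"].to_numpy())
    else:
        omni = sps.kruskal(*groups)
        name = "kruskal-wallis"
        contrasts = dunn_posthoc(groups, labels)
    return ComparisonResult(
        test=name,
        statistic=float(omni.statistic),
        p_value=float(omni.pvalue),
        family=family,
        shapiro_p=shapiro_ps,
        levene_p=levene_p,
        contrasts=contrasts,
        flags=flags,
    )


#: row labels of the 2D-histology vs 3D-micro-CT correlation table; the 2D
#: areal fraction Tb.A is matched against the 3D volume fraction BV/TV
PAIR_LABELS = {
    "Tb.A": "Tb.A and BV/TV (%)",
    "Tb.Th": "Tb.Th (mm)",
    "Tb.Sp": "Tb.Sp (mm)",
    "Tb.N": "Tb.N (1/mm)",
}


def correlate_2d3d(paired: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of specimen-matched 2D and 3D trabecular parameters.

    ``paired`` needs columns ``specimen, parameter, value_2d, value_3d`` with
    one row per specimen and parameter (``Tb.A`` rows carry the 2D areal
    fraction in ``value_2d`` and the matched 3D BV/TV in ``value_3d``).
    Returns one row per parameter with n, per-modality mean ± SD, Pearson r
    and the two-sided p-value; parameters with fewer than three complete
    pairs or zero variance yield NaN with a warning.
    """
    rows = []
    for param, label in PAIR_LABELS.items():
        merged = paired[paired.parameter == param].dropna(subset=["value_2d", "value_3d"])
        if len(merged) == 0:
            continue
        x = merged.value_2d.to_numpy(float)
        y = merged.value_3d.to_numpy(float)
        row = {
            "pair": label,
            "n": len(x),
            "mean_2d": x.mean(),
            "sd_2d": x.std(ddof=1) if len(x) > 1 else np.nan,
            "mean_3d": y.mean(),
            "sd_3d": y.std(ddof=1) if len(y) > 1 else np.nan,
        }
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"{label}: fewer than 3 complete pairs or zero variance; r omitted",
                stacklevel=2,
            )
            row["r"] = np.nan
            row["p"] = np.nan
        else:
            r, p = sps.pearsonr(x, y)
            row["r"] = float(r)
            row["p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
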