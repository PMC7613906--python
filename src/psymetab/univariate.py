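"""Univariate confirmation: fold changes, group comparisons, exact tests.

The comparison ladder mirrors standard metabolomics/clinical practice:
ordinary one-way ANOVA with Tukey's post hoc when groups are normal with
equal variances; Brown-Forsythe and Welch ANOVA with Dunnett's T3 post hoc
under variance heterogeneity; Kruskal-Wallis with Dunn's post hoc for
non-normal data (or small groups); Mann-Whitney U for two-group non-normal
comparisons; Fisher's exact test for categorical tables; Bonferroni
correction throughout.

Dunn's test and Dunnett's T3 are implemented here directly (rank-based z
statistics with tie correction, and pairwise Welch t with Welch-Satterthwaite
degrees of freedom and a Sidak-form family adjustment, respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "GroupComparisonResult",
    "fold_changes",
    "compare_groups",
    "dunn_posthoc",
    "dunnett_t3_posthoc",
    "fisher_exact",
    "bonferroni_adjust",
]


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, m * p).

    ``m`` defaults to the number of p values and may not be smaller than it
    (it may be larger, for corrections across a wider family).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p values ({p.size})")
    return np.minimum(1.0, m * p)


def fold_changes(
    values: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    bins: list[str] | None = None,
    reference: str = "Control",
) -> pd.DataFrame:
    """Per-bin fold change of each group mean over the reference group mean."""
    groups = pd.Series(np.asarray(groups).astype(str), index=values.index)
    if reference not in set(groups):
        raise ValueError(f"reference group {reference!r} not present")
    cols = list(bins) if bins is not None else list(values.columns)
    missing = [b for b in cols if b not in values.columns]
    if missing:
        raise ValueError(f"unknown bins {missing}")
    sub = values[cols]
    ref_mean = sub[groups == reference].mean(axis=0)
    zero = ref_mean[ref_mean == 0]
    if len(zero):
        raise ValueError(f"zero reference mean for bins {list(zero.index)}")
    out = {}
    for g in sorted(set(groups)):
        if g == reference:
            continue
        out[f"fold_{g}_vs_{reference}"] = sub[groups == g].mean(axis=0) / ref_mean
    return pd.DataFrame(out)


@dataclass
class GroupComparisonResult:
    variable: str
    method: str
    omnibus_stat: float
    omnibus_p: float
    posthoc: pd.DataFrame  # group1, group2, p_raw, p_adjusted, fold_change
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.omnibus_p <= self.alpha)


def _group_arrays(values, groups) -> tuple[list[str], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values/groups length mismatch")
    names = sorted(np.unique(groups))
    arrays = [values[groups == g] for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    return names, arrays


def dunn_posthoc(names: list[str], arrays: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank test with tie correction, Bonferroni family adjust."""
    all_vals = np.concatenate(arrays)
    n_total = all_vals.size
    ranks = stats.rankdata(all_vals)
    mean_ranks, start = {}, 0
    for g, a in zip(names, arrays):
        mean_ranks[g] = ranks[start : start + a.size].mean()
        start += a.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    for g1, g2 in combinations(names, 2):
        n1 = arrays[names.index(g1)].size
        n2 = arrays[names.index(g2)].size
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "stat": z, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bonferroni_adjust(df["p_raw"].to_numpy())
    return df


def dunnett_t3_posthoc(names: list[str], arrays: list[np.ndarray]) -> pd.DataFrame:
    """Dunnett's T3: pairwise Welch t, Welch-Satterthwaite df, Sidak family form."""
    k = len(list(combinations(names, 2)))
    rows = []
    for g1, g2 in combinations(names, 2):
        a = arrays[names.index(g1)]
        b = arrays[names.index(g2)]
        v1, v2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = np.sqrt(v1 + v2)
        if se == 0:
            tstat, p = 0.0, 1.0
        else:
            tstat = (a.mean() - b.mean()) / se
            df_ws = (v1 + v2) ** 2 / (v1**2 / (a.size - 1) + v2**2 / (b.size - 1))
            p = 2.0 * stats.t.sf(abs(tstat), df_ws)
        rows.append({"group1": g1, "group2": g2, "stat": tstat, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = 1.0 - (1.0 - df["p_raw"]) ** k
    return df


def _tukey_posthoc(names: list[str], arrays: list[np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "stat": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
            }
        )
    df = pd.DataFrame(rows)
    # Tukey's p values are already family-adjusted
    df["p_adjusted"] = df["p_raw"]
    return df


def _pair_folds(names: list[str], arrays: list[np.ndarray], posthoc: pd.DataFrame) -> pd.DataFrame:
    means = {g: a.mean() for g, a in zip(names, arrays)}
    folds = []
    for _, row in posthoc.iterrows():
        m2 = means[row["group2"]]
        folds.append(means[row["group1"]] / m2 if m2 != 0 else np.nan)
    posthoc = posthoc.copy()
    posthoc["fold_change"] = folds
    return posthoc


def _auto_method(names: list[str], arrays: list[np.ndarray], alpha: float) -> str:
    """Decision rule: normality gate (Shapiro-Wilk per group), then variance gate."""
    normal = True
    for a in arrays:
        if a.size < 3:
            normal = False
            break
        if np.ptp(a) == 0:
            normal = False
            break
        if stats.shapiro(a).pvalue < alpha:
            normal = False
            break
    if not normal:
        return "mann_whitney" if len(names) == 2 else "kruskal_dunn"
    if stats.levene(*arrays).pvalue < alpha:
        return "welch_bf_dunnettT3"
    return "anova_tukey"


def compare_groups(
    values,
    groups,
    method: str = "auto",
    alpha: float = 0.05,
    variable: str = "",
) -> GroupComparisonResult:
    """Omnibus group comparison with the matching post-hoc test.

    ``method`` is one of 'anova_tukey', 'welch_bf_dunnettT3', 'kruskal_dunn',
    'mann_whitney', or 'auto' (Shapiro-Wilk normality gate at ``alpha``, then
    a Levene equal-variance gate choosing between ordinary and
    heteroscedastic ANOVA).
    """
    names, arrays = _group_arrays(values, groups)
    if all(a.var(ddof=1) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("degenerate data: zero variance everywhere")
    if method == "auto":
        method = _auto_method(names, arrays, alpha)
    extras: dict = {}

    if method == "mann_whitney":
        if len(names) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided", method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = pd.DataFrame(
            [{"group1": names[0], "group2": names[1], "stat": stat, "p_raw": p, "p_adjusted": p}]
        )
    elif method == "anova_tukey":
        f, p = stats.f_oneway(*arrays)
        stat, p = float(f), float(p)
        posthoc = _tukey_posthoc(names, arrays)
    elif method == "welch_bf_dunnettT3":
        vals = np.concatenate(arrays)
        grp = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
        welch = anova_oneway(vals, grp, use_var="unequal", welch_correction=True)
        bf = anova_oneway(vals, grp, use_var="bf")
        stat, p = float(welch.statistic), float(welch.pvalue)
        extras["brown_forsythe_stat"] = float(bf.statistic)
        extras["brown_forsythe_p"] = float(bf.pvalue)
        posthoc = dunnett_t3_posthoc(names, arrays)
    elif method == "kruskal_dunn":
        h, p = stats.kruskal(*arrays)
        stat, p = float(h), float(p)
        posthoc = dunn_posthoc(names, arrays)
    else:
        raise ValueError(f"unknown method {method!r}")

    posthoc = _pair_folds(names, arrays, posthoc)
    return GroupComparisonResult(
        variable=variable,
        method=method,
        omnibus_stat=stat,
        omnibus_p=float(min(p, 1.0)),
        posthoc=posthoc,
        alpha=alpha,
        extras=extras,
    )


def fisher_exact(table) -> tuple[float, float, str]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (p, odds_ratio, note).  The p value sums hypergeometric
    probabilities no larger than the observed table's.  The odds ratio is
    the sample ratio; with a zero cell the Haldane-Anscombe correction
    (add 0.5 to every cell) is applied and noted.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table must hold non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    note = ""
    if np.any(t == 0):
        th = t + 0.5
        odds = float(th[0, 0] * th[1, 1] / (th[0, 1] * th[1, 0]))
        note = "Haldane-Anscombe corrected odds ratio (zero cell)"
    else:
        odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return p, odds, note
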