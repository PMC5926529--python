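"""Group-comparison statistics for anti-saccade cohorts.

The battery mirrors standard practice for skewed oculomotor data with three
groups: homoscedasticity is assessed with the Brown-Forsythe (median
centred) Levene test; the omnibus group test is the Kruskal-Wallis H when
variances are homogeneous, otherwise Welch's heteroscedastic ANOVA applied
to the pooled mid-ranks.  Post hoc pairwise contrasts use Dunn's rank test
with tie correction and Bonferroni adjustment.  Latency distributions are
compared pairwise with two-sample two-sided Kolmogorov-Smirnov tests.
Proportions (directional-error and correction rates) are compared with a
Pearson chi-square test on the 2 x 3 table followed by the Marascuilo
procedure, whose per-pair critical range is

    r_ij = sqrt(chi2_{1-alpha; k-1}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j).

All tests are two-sided at the 5% level unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "ProportionTestResult",
    "compare_groups",
    "welch_anova_on_values",
    "dunn_posthoc",
    "ks_pairwise",
    "proportion_tests",
    "spearman_vs_icars",
    "variability_summary",
]


@dataclass
class GroupComparison:
    parameter: str
    eccentricity: int | None
    levene_stat: float
    levene_p: float
    test_used: str  # "kruskal_wallis" | "welch_on_ranks"
    statistic: float
    df: tuple[float, float] | int
    p_value: float
    posthoc: pd.DataFrame  # pair, z, p_raw, p_adjusted


@dataclass
class ProportionTestResult:
    groups: list[str]
    successes: np.ndarray
    n: np.ndarray
    proportions: np.ndarray
    chi2: float
    df: int
    p_value: float
    marascuilo: pd.DataFrame  # pair, difference_pp, critical_pp, significant
    alpha: float


def welch_anova_on_values(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p).  Applied to pooled ranks this is the
    'Welch test on ranked data' used when Levene rejects homoscedasticity.
    """
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    variances = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(variances <= 0):
        # degenerate within-group spread: fall back to a tiny variance floor
        variances = np.maximum(variances, 1e-12)
    w = ns / variances
    wsum = w.sum()
    mw = (w * means).sum() / wsum
    h = ((1.0 - w / wsum) ** 2 / (ns - 1.0)).sum()
    f = ((w * (means - mw) ** 2).sum() / (k - 1)) / (
        1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * h
    )
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * h)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def _tie_correction(pooled_ranks_source: np.ndarray) -> float:
    """Sum(t^3 - t) / (12 (N - 1)) over tied groups of the pooled sample."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    n = pooled_ranks_source.size
    if n <= 1:
        return 0.0
    return float(np.sum(counts**3 - counts) / (12.0 * (n - 1.0)))


def dunn_posthoc(
    values_by_group: dict[str, np.ndarray], n_comparisons: int | None = None
) -> pd.DataFrame:
    """Dunn's pairwise rank comparison with tie correction and Bonferroni.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with T the tie correction; two-sided p from the normal approximation,
    multiplied by the number of pairs and capped at 1.
    """
    names = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    tie = _tie_correction(pooled)
    mean_ranks = {}
    i = 0
    for g in names:
        m = len(values_by_group[g])
        mean_ranks[g] = float(np.mean(ranks[i : i + m]))
        i += m
    m_comp = n_comparisons or len(names) * (len(names) - 1) // 2
    var_unit = n_total * (n_total + 1.0) / 12.0 - tie
    rows = []
    for g1, g2 in combinations(names, 2):
        n1, n2 = len(values_by_group[g1]), len(values_by_group[g2])
        denom = np.sqrt(var_unit * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / denom if denom > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            dict(
                pair=f"{g1} vs {g2}",
                z=float(z),
                p_raw=p_raw,
                p_adjusted=min(1.0, m_comp * p_raw),
            )
        )
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    use_levene_gate: bool = True,
    alpha_levene: float = 0.05,
    parameter: str = "",
    eccentricity: int | None = None,
) -> GroupComparison:
    """Omnibus comparison of one saccadic parameter across groups.

    Brown-Forsythe Levene gates the omnibus choice: heteroscedastic data go
    to Welch's ANOVA on the pooled mid-ranks, otherwise Kruskal-Wallis.
    Dunn-Bonferroni pairwise contrasts are always computed.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    samples = list(arrays.values())
    lev_stat, lev_p = stats.levene(*samples, center="median")
    if use_levene_gate and lev_p < alpha_levene:
        pooled = np.concatenate(samples)
        ranks = stats.rankdata(pooled)
        split = np.cumsum([s.size for s in samples])[:-1]
        rank_groups = np.split(ranks, split)
        f, df1, df2, p = welch_anova_on_values(rank_groups)
        test_used, statistic, df = "welch_on_ranks", f, (df1, df2)
    else:
        h, p = stats.kruskal(*samples)
        test_used, statistic, df = "kruskal_wallis", float(h), len(samples) - 1
    return GroupComparison(
        parameter=parameter,
        eccentricity=eccentricity,
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        test_used=test_used,
        statistic=statistic,
        df=df,
        p_value=float(p),
        posthoc=dunn_posthoc(arrays),
    )


def ks_pairwise(
    values_by_group: dict[str, np.ndarray]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Two-sample two-sided Kolmogorov-Smirnov test for every group pair."""
    out = {}
    for g1, g2 in combinations(values_by_group, 2):
        a = np.asarray(values_by_group[g1], dtype=float)
        b = np.asarray(values_by_group[g2], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 values")
        res = stats.ks_2samp(a, b, alternative="two-sided")
        out[(g1, g2)] = (float(res.statistic), float(res.pvalue))
    return out


def proportion_tests(
    successes_by_group: dict[str, int],
    n_by_group: dict[str, int],
    alpha: float = 0.05,
) -> ProportionTestResult:
    """Chi-square equality-of-proportions test plus the Marascuilo procedure.

    Differences and critical ranges are reported in percentage points.
    A pair is significant when its observed absolute difference exceeds its
    critical range.
    """
    groups = list(successes_by_group)
    if len(groups) != 3:
        raise ValueError("the proportion battery expects exactly 3 groups")
    succ = np.array([successes_by_group[g] for g in groups], dtype=float)
    n = np.array([n_by_group[g] for g in groups], dtype=float)
    if np.any(n < 1):
        raise ValueError("every group needs at least one trial")
    if np.any(succ < 0) or np.any(succ > n):
        raise ValueError("successes must lie in [0, n]")
    props = succ / n
    table = np.vstack([succ, n - succ])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    crit_root = np.sqrt(stats.chi2.ppf(1.0 - alpha, len(groups) - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        diff_pp = abs(props[i] - props[j]) * 100.0
        critical_pp = (
            crit_root
            * np.sqrt(
                props[i] * (1 - props[i]) / n[i] + props[j] * (1 - props[j]) / n[j]
            )
            * 100.0
        )
        rows.append(
            dict(
                pair=f"{groups[i]} vs {groups[j]}",
                difference_pp=float(diff_pp),
                critical_pp=float(critical_pp),
                significant=bool(diff_pp > critical_pp),
            )
        )
    return ProportionTestResult(
        groups=groups,
        successes=succ,
        n=n,
        proportions=props,
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        marascuilo=pd.DataFrame(rows),
        alpha=alpha,
    )


def spearman_vs_icars(
    parameter_values: pd.DataFrame,
    icars_by_subject: dict[str, float],
) -> pd.DataFrame:
    """Spearman rank correlation of each saccadic parameter with ICARS.

    ``parameter_values`` is tidy with columns (subject_id, parameter, value),
    one row per subject and parameter (typically the subject mean).  Returns
    one row per parameter with (rho, p, n); constant inputs yield NaN rho
    with ``defined=False``.
    """
    required = {"subject_id", "parameter", "value"}
    if not required.issubset(parameter_values.columns):
        raise ValueError(f"parameter_values must have columns {sorted(required)}")
    rows = []
    for param, sub in parameter_values.groupby("parameter", sort=True):
        sub = sub.dropna(subset=["value"])
        sub = sub[sub["subject_id"].isin(icars_by_subject)]
        x = sub["value"].to_numpy(dtype=float)
        y = np.array([icars_by_subject[s] for s in sub["subject_id"]], dtype=float)
        if x.size < 3:
            rows.append(dict(parameter=param, rho=np.nan, p=np.nan, n=int(x.size), defined=False))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(dict(parameter=param, rho=np.nan, p=np.nan, n=int(x.size), defined=False))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(dict(parameter=param, rho=float(rho), p=float(p), n=int(x.size), defined=True))
    return pd.DataFrame(rows)


def variability_summary(
    per_subject_sds: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate per-subject parameter SDs within groups.

    Input is tidy with columns (subject_id, group, eccentricity_deg,
    parameter, sd).  Returns, per (group, eccentricity, parameter), the mean
    of the per-subject SDs and the SD of those SDs across subjects --
    the 'mean (between-subject SD)' presentation used for saccadic
    variability tables.
    """
    required = {"subject_id", "group", "eccentricity_deg", "parameter", "sd"}
    if not required.issubset(per_subject_sds.columns):
        raise ValueError(f"per_subject_sds must have columns {sorted(required)}")
    rows = []
    for (group, ecc, param), sub in per_subject_sds.groupby(
        ["group", "eccentricity_deg", "parameter"], sort=True
    ):
        vals = sub["sd"].to_numpy(dtype=float)
        rows.append(
            dict(
                group=group,
                eccentricity_deg=ecc,
                parameter=param,
                mean_sd=float(np.mean(vals)),
                between_subject_sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                n_subjects=int(vals.size),
            )
        )
    return pd.DataFrame(rows)
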