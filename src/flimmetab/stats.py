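"""Cohort summaries and normality-gated statistical test selection.

Reproduces a common slice-physiology reporting convention: box plots of the
25–75 % interquartile range with whiskers at the 5–95 % percentiles, median
and mean both reported; and a test-selection decision tree gated on a
Kolmogorov-Smirnov (Lilliefors) normality test — parametric tests (paired /
unpaired t, Welch when the SDs differ, repeated-measures ANOVA) when all
groups pass, the rank-based equivalents (Wilcoxon matched pairs,
Mann-Whitney, Kruskal-Wallis, Friedman with a Dunn post-test) when any
fails.  The omnibus tests are delegated to scipy/statsmodels; the
contribution here is the reproducible selection logic and reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = ["CohortSummary", "TestResult", "summarize", "select_test"]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    whisker_lo: float               # 5th percentile
    whisker_hi: float               # 95th percentile
    n_neurons: int | None = None
    n_slices: int | None = None
    n_mice: int | None = None


def summarize(values, n_neurons=None, n_slices=None, n_mice=None) -> CohortSummary:
    """Box-plot style summary: box at 25/75 %, whiskers at 5/95 %.

    Percentiles use linear interpolation between order statistics
    (numpy's default rule).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q5, q25, med, q75, q95 = np.percentile(v, [5, 25, 50, 75, 95])
    return CohortSummary(n=int(v.size), mean=float(v.mean()),
                         sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                         median=float(med), q25=float(q25), q75=float(q75),
                         whisker_lo=float(q5), whisker_hi=float(q95),
                         n_neurons=n_neurons, n_slices=n_slices, n_mice=n_mice)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    pvalue: float
    normality_pvalues: tuple[float, ...]
    posthoc: str | None = None
    posthoc_table: pd.DataFrame | None = None


def _is_normal(x) -> tuple[bool, float]:
    if len(x) < 4:
        raise ValueError("normality test needs at least 4 observations per group")
    if np.std(x) == 0:
        return False, 0.0
    _, p = lilliefors(np.asarray(x, dtype=float), dist="norm")
    return p >= NORMALITY_ALPHA, float(p)


def _dunn_friedman(groups) -> pd.DataFrame:
    """Dunn's multiple-comparison z tests after a Friedman omnibus.

    Within-block ranks are summed per condition; the difference of rank
    sums is compared with its null SD sqrt(n*k*(k+1)/6) and the p-values
    are Bonferroni-adjusted over the k*(k-1)/2 comparisons.
    """
    k = len(groups)
    n = len(groups[0])
    data = np.column_stack(groups)
    ranks = sps.rankdata(data, axis=1)
    rank_sums = ranks.sum(axis=0)
    sd = np.sqrt(n * k * (k + 1) / 6.0)
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = abs(rank_sums[i] - rank_sums[j]) / sd
        p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        rows.append((i, j, z, p))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_adjusted"])


def _holm_paired_t(groups) -> pd.DataFrame:
    """Pairwise paired t tests with Holm adjustment (post hoc for RM-ANOVA)."""
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw = []
    for i, j in pairs:
        t, p = sps.ttest_rel(groups[i], groups[j])
        raw.append((i, j, float(t), float(p)))
    order = np.argsort([r[3] for r in raw])
    adj = {}
    running = 0.0
    for rank, idx in enumerate(order):
        p_adj = min(1.0, (len(raw) - rank) * raw[idx][3])
        running = max(running, p_adj)
        adj[idx] = running
    return pd.DataFrame([(i, j, t, adj[idx]) for idx, (i, j, t, _) in enumerate(raw)],
                        columns=["group_i", "group_j", "t", "p_adjusted"])


def select_test(groups, paired: bool = False) -> TestResult:
    """Choose and run the comparison a normality-gated decision tree dictates.

    Two groups: t test (paired / unpaired / Welch when the SDs differ by
    more than a factor of ~1.5) if every group passes the Lilliefors
    normality check, otherwise Wilcoxon matched pairs or Mann-Whitney.
    Three or more groups: repeated-measures ANOVA (paired) or one-way ANOVA
    when normal, otherwise Friedman with a Dunn post-test (paired) or
    Kruskal-Wallis.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups (or conditions)")
    if paired and len({len(g) for g in groups}) != 1:
        raise ValueError("paired comparisons need equal group sizes")
    flags, ps = zip(*(_is_normal(g) for g in groups))
    all_normal = all(flags)

    if len(groups) == 2:
        a, b = groups
        if paired:
            if all_normal:
                t, p = sps.ttest_rel(a, b)
                return TestResult("paired t", float(t), float(p), ps)
            stat, p = sps.wilcoxon(a, b)
            return TestResult("Wilcoxon matched pairs", float(stat), float(p), ps)
        if all_normal:
            sd_a, sd_b = np.std(a, ddof=1), np.std(b, ddof=1)
            welch = max(sd_a, sd_b) > 1.5 * min(sd_a, sd_b)
            t, p = sps.ttest_ind(a, b, equal_var=not welch)
            return TestResult("Welch t" if welch else "unpaired t",
                              float(t), float(p), ps)
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("Mann-Whitney", float(stat), float(p), ps)

    if paired:
        if all_normal:
            frame = pd.DataFrame({
                "y": np.concatenate(groups),
                "cond": np.repeat(np.arange(len(groups)), len(groups[0])),
                "subj": np.tile(np.arange(len(groups[0])), len(groups)),
            })
            from statsmodels.stats.anova import AnovaRM
            res = AnovaRM(frame, "y", "subj", within=["cond"]).fit()
            f = float(res.anova_table["F Value"].iloc[0])
            p = float(res.anova_table["Pr > F"].iloc[0])
            return TestResult("repeated-measures ANOVA", f, p, ps,
                              posthoc="pairwise paired t (Holm)",
                              posthoc_table=_holm_paired_t(groups))
        stat, p = sps.friedmanchisquare(*groups)
        return TestResult("Friedman", float(stat), float(p), ps,
                          posthoc="Dunn", posthoc_table=_dunn_friedman(groups))
    if all_normal:
        f, p = sps.f_oneway(*groups)
        return TestResult("one-way ANOVA", float(f), float(p), ps)
    stat, p = sps.kruskal(*groups)
    return TestResult("Kruskal-Wallis", float(stat), float(p), ps)
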