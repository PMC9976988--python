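"""Cohort-description statistics for three-group clinical tables.

Covers the statistics typically reported in a demographics table: Pearson
chi-square for categorical variables (with Fisher's exact test available
for 2x2 tables), one-way ANOVA computed either from raw values or from
per-group (n, mean, SD) summaries, Kruskal-Wallis for skewed variables,
ANCOVA partial F for a group factor adjusting for covariates, and
Bonferroni-corrected post-hoc p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "pearson_chi2",
    "fisher_exact_2x2",
    "anova_from_summary",
    "anova",
    "kruskal_wallis",
    "ancova_group_f",
    "bonferroni",
    "one_sample_t_vs_norm",
    "table1",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    return t


def pearson_chi2(table) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) and degrees of freedom."""
    t = _as_table(table)
    chi2, _, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


def anova_from_summary(groups) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group (n, mean, sd) summaries.

    Accepts GroupSummary instances or (n, mean, sd) tuples.  Returns
    (F, df_between, df_within).
    """
    gs = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    N, G = ns.sum(), len(gs)
    grand = (ns * means).sum() / N
    msb = (ns * (means - grand) ** 2).sum() / (G - 1)
    msw = ((ns - 1) * sds**2).sum() / (N - G)
    if msw == 0:
        raise ValueError("zero within-group variance")
    return float(msb / msw), int(G - 1), int(N - G)


def anova(samples) -> tuple[float, int, int]:
    """Classic one-way ANOVA on raw per-group value vectors."""
    summaries = [
        GroupSummary(len(s), float(np.mean(s)), float(np.std(s, ddof=1)))
        for s in samples
    ]
    return anova_from_summary(summaries)


def kruskal_wallis(samples) -> float:
    """Kruskal-Wallis H with tie correction."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise ValueError("all values tied")
    h, _ = stats.kruskal(*samples)
    return float(h)


def ancova_group_f(values, group, covariates) -> tuple[float, tuple[int, int]]:
    """Partial F for a group factor after adjusting for covariates.

    Compares nested OLS models [intercept + covariates] versus
    [intercept + covariates + group dummies] on complete cases.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == 1 and y.size > 1:
        X = X.T
    if X.size == 0:
        X = np.empty((y.size, 0))
    keep = np.isfinite(y)
    if X.shape[1]:
        keep &= np.all(np.isfinite(X), axis=1)
    y, g, X = y[keep], g[keep], X[keep]
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 group levels")
    dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    ones = np.ones((y.size, 1))
    reduced = np.column_stack([ones, X])
    full = np.column_stack([reduced, dummies])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")

    def rss(D):
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        r = y - D @ beta
        return float(r @ r)

    rss_r, rss_f = rss(reduced), rss(full)
    df1 = len(levels) - 1
    df2 = y.size - full.shape[1]
    if df2 <= 0 or rss_f == 0:
        raise ValueError("degenerate ANCOVA fit")
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return float(F), (df1, df2)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values (p * m, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = m or p.size
    return np.minimum(p * m, 1.0)


def one_sample_t_vs_norm(values, norm: float) -> tuple[float, float]:
    """Parametric one-sample t of values against a published norm."""
    t, p = stats.ttest_1samp(np.asarray(values, dtype=float), norm)
    return float(t), float(p)


def table1(
    roster: pd.DataFrame,
    continuous: dict[str, str] | None = None,
    categorical: list[str] | None = None,
    groups: tuple[str, ...] = ("CTR", "FLE", "TLE"),
) -> pd.DataFrame:
    """Demographics-table statistics from a subject roster.

    ``continuous`` maps column name -> test ('anova' or 'kruskal');
    ``categorical`` lists columns compared with Pearson chi-square (pairwise
    deletion of missing values throughout).
    """
    continuous = continuous or {"age": "anova"}
    categorical = categorical or ["sex"]
    rows = []
    grouped = {g: roster[roster["group"] == g] for g in groups
               if (roster["group"] == g).any()}
    for col, test in continuous.items():
        samples = [g[col].dropna().to_numpy() for g in grouped.values()]
        samples = [s for s in samples if s.size >= 2]
        if len(samples) < 2:
            continue
        if test == "anova":
            F, df1, df2 = anova(samples)
            p = float(stats.f.sf(F, df1, df2))
            rows.append({"variable": col, "test": "anova", "statistic": F, "p": p})
        else:
            H = kruskal_wallis(samples)
            p = float(stats.chi2.sf(H, len(samples) - 1))
            rows.append({"variable": col, "test": "kruskal", "statistic": H, "p": p})
    for col in categorical:
        sub = roster.dropna(subset=[col])
        counts = pd.crosstab(sub["group"], sub[col])
        counts = counts.loc[[g for g in groups if g in counts.index]]
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            continue
        chi2, dof = pearson_chi2(counts.to_numpy())
        p = float(stats.chi2.sf(chi2, dof))
        rows.append({"variable": col, "test": "chi2", "statistic": chi2, "p": p})
    return pd.DataFrame(rows)
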