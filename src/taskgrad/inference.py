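"""Permutation inference and normative deviation mapping.

All tests are nonparametric, two-tailed, and report Monte-Carlo p values on
the grid k/(n_perm+1) with k >= 1, using the convention
p = (1 + #exceedances) / (1 + n_perm) so a p value of zero is impossible and
ties with the observed statistic count as exceedances (conservative).

One-sample tests build the null by random sign flips of the values;
two-sample tests and the area-between-curves (AbC) statistic exchange group
labels preserving group sizes; correlations permute the y residuals after
both variables are residualised on nuisance covariates.  Patient deviation
is expressed as a normative Z score against the control mean and SD per
system or gradient bin.

Randomness is controlled by a single master seed; tests run over families
of columns derive an independent stream per column from (seed, column
index), so the result for a column never depends on which other columns
are present or their order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import StatResult

__all__ = [
    "z_deviation",
    "cohens_d",
    "perm_one_sample",
    "perm_two_sample",
    "fdr_bh",
    "abc_test",
    "CurveComparison",
    "perm_correlation",
    "group_contrast_report",
]


def _rng(seed, *stream) -> np.random.Generator:
    """Deterministic generator for a master seed plus a stream key."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng([int(seed), *map(int, stream)])


def _perm_p(null_abs: np.ndarray, obs_abs: float) -> float:
    return (1.0 + np.count_nonzero(null_abs >= obs_abs)) / (1.0 + null_abs.size)


# ---------------------------------------------------------------------------
# Effect sizes and deviation scores


def z_deviation(act_pat, mu_ctr: float, sigma_ctr: float):
    """Normative deviation Z = (act_pat - mu_ctr) / sigma_ctr."""
    if sigma_ctr <= 0:
        raise ValueError("sigma_ctr must be positive")
    return (np.asarray(act_pat, dtype=float) - mu_ctr) / sigma_ctr


def cohens_d(a, b) -> float:
    """Standardised mean difference (a minus b) with pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# Permutation tests


def _one_sample_t(x: np.ndarray, axis=-1) -> np.ndarray:
    n = x.shape[axis]
    m = x.mean(axis=axis)
    s = x.std(axis=axis, ddof=1)
    return m / (s / np.sqrt(n))


def perm_one_sample(values, n_perm: int = 10000, seed: int = 0) -> StatResult:
    """Two-tailed sign-flip permutation one-sample t test against zero."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t_obs = float(x.mean() / (sd / np.sqrt(n)))

    rng = _rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = _one_sample_t(signs * x, axis=1)
    t_null = np.where(np.isfinite(t_null), t_null, np.inf)  # all-equal flips
    p = _perm_p(np.abs(t_null), abs(t_obs))
    d = float(x.mean() / sd)
    return StatResult(t_obs, p, n_perm, int(seed) if np.isscalar(seed) else -1,
                      effect_size_d=d)


def _two_sample_t_from_sums(sa, ssa, na, sb, ssb, nb):
    ma, mb = sa / na, sb / nb
    va = (ssa - na * ma**2) / (na - 1)
    vb = (ssb - nb * mb**2) / (nb - 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return t


def perm_two_sample(a, b, n_perm: int = 10000, seed: int = 0) -> StatResult:
    """Two-tailed label-exchange permutation two-sample t test (pooled SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    if ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) == 0:
        raise ValueError("zero pooled variance")
    t_obs = float(
        _two_sample_t_from_sums(a.sum(), (a**2).sum(), na, b.sum(), (b**2).sum(), nb)
    )

    rng = _rng(seed)
    n = na + nb
    total, total_sq = pooled.sum(), (pooled**2).sum()
    # each permutation: a uniformly random size-na subset plays group a
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
    xa = pooled[idx]
    sa, ssa = xa.sum(axis=1), (xa**2).sum(axis=1)
    t_null = _two_sample_t_from_sums(sa, ssa, na, total - sa, total_sq - ssa, nb)
    t_null = np.where(np.isfinite(t_null), t_null, np.inf)
    p = _perm_p(np.abs(t_null), abs(t_obs))
    return StatResult(t_obs, p, n_perm, int(seed) if np.isscalar(seed) else -1,
                      effect_size_d=cohens_d(a, b))


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p values and rejections at ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p values must lie in (0, 1]")
    reject, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


# ---------------------------------------------------------------------------
# Area between curves


@dataclass
class CurveComparison:
    """Global comparison of two groups' gradient-stratified mean curves."""

    abc: float
    p_perm: float
    n_perm: int
    seed: int
    per_bin: list[StatResult] = field(default_factory=list)


def abc_test(profiles_a, profiles_b, n_perm: int = 10000, seed: int = 0,
             fdr_q: float = 0.05, per_bin: bool = True) -> CurveComparison:
    """Area between group-mean curves with a label-exchange permutation null.

    The statistic is the mean over bins of the absolute difference between
    group-mean curves (unit bin width).  Per-bin two-sample permutation
    tests with BH-FDR across bins are attached when ``per_bin`` is true.
    """
    A = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    B = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("profiles have different bin counts")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")

    abc_obs = float(np.nanmean(np.abs(np.nanmean(A, axis=0) - np.nanmean(B, axis=0))))

    rng = _rng(seed, 0)
    pooled = np.vstack([A, B])
    n = na + nb
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    abc_null = np.empty(n_perm)
    col_sum = np.nansum(pooled, axis=0)
    for i in range(n_perm):
        ma = np.nanmean(pooled[idx[i, :na]], axis=0)
        mb = np.nanmean(pooled[idx[i, na:]], axis=0)
        abc_null[i] = np.nanmean(np.abs(ma - mb))
    p = _perm_p(abc_null, abc_obs)

    results: list[StatResult] = []
    if per_bin:
        for j in range(A.shape[1]):
            results.append(perm_two_sample(A[:, j], B[:, j], n_perm,
                                           _rng(seed, 1, j)))
        adj, _ = fdr_bh([r.p_perm for r in results], fdr_q)
        for r, pa in zip(results, adj):
            r.p_fdr = float(pa)
            r.seed = int(seed)
    return CurveComparison(abc_obs, p, n_perm, int(seed), results)


# ---------------------------------------------------------------------------
# Brain-behaviour correlations


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def perm_correlation(x, y, nuisance=None, method: str = "pearson",
                     n_perm: int = 10000, seed: int = 0) -> StatResult:
    """Permutation correlation with optional nuisance residualisation.

    Both variables are residualised on [intercept, nuisance] (for Spearman,
    ranks are taken first, then residualised); the observed statistic is the
    product-moment correlation of the residuals and the null is built by
    permuting the y residuals.  Missing entries are removed pairwise.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = None if nuisance is None else np.atleast_2d(np.asarray(nuisance, dtype=float))
    if Z is not None and Z.shape[0] == 1 and x.size > 1:
        Z = Z.T
    keep = np.isfinite(x) & np.isfinite(y)
    if Z is not None:
        keep &= np.all(np.isfinite(Z), axis=1)
    x, y = x[keep], y[keep]
    c = 0 if Z is None else Z.shape[1]
    if x.size < c + 3:
        raise ValueError("too few complete pairs")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    design = (np.ones((x.size, 1)) if Z is None
              else np.column_stack([np.ones(x.size), Z[keep]]))
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance after residualisation")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    r_obs = float(np.mean(rx * ry))

    rng = _rng(seed)
    perm = np.argsort(rng.random((n_perm, x.size)), axis=1)
    r_null = (ry[perm] @ rx) / x.size
    p = _perm_p(np.abs(r_null), abs(r_obs))
    return StatResult(r_obs, p, n_perm, int(seed) if np.isscalar(seed) else -1)


# ---------------------------------------------------------------------------
# Cohort-level report


def group_contrast_report(
    profiles: dict[str, pd.DataFrame | np.ndarray],
    mode: str = "systems",
    control: str = "CTR",
    patient_groups: tuple[str, ...] = ("FLE", "TLE"),
    n_perm: int = 10000,
    seed: int = 0,
    fdr_q: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit permutation report across all group comparisons.

    For every system or gradient bin (a column of the profile matrices) the
    report holds: a control one-sample test of the raw adjusted effect, a
    one-sample test of each patient group's normative Z deviation, and a
    direct two-sample comparison of the two patient groups.  Within each
    comparison family, p values are BH-FDR adjusted across units and flagged
    both at ``p_fdr < fdr_q`` and uncorrected ``p < alpha``.
    """
    if control not in profiles:
        raise ValueError(f"control group '{control}' not in profiles")
    mats = {}
    columns = None
    for g, v in profiles.items():
        if isinstance(v, pd.DataFrame):
            columns = columns or list(v.columns)
            mats[g] = v.to_numpy(dtype=float)
        else:
            mats[g] = np.atleast_2d(np.asarray(v, dtype=float))
    M = mats[control].shape[1]
    if columns is None:
        columns = [f"bin{j + 1:02d}" if mode == "gradient" else f"unit{j}"
                   for j in range(M)]
    for g, m in mats.items():
        if m.shape[0] < 2:
            raise ValueError(f"group '{g}' has fewer than 2 subjects")
        if m.shape[1] != M:
            raise ValueError("profile column counts differ across groups")

    ctr = mats[control]
    mu = np.nanmean(ctr, axis=0)
    sigma = np.nanstd(ctr, axis=0, ddof=1)
    if np.any(sigma == 0):
        raise ValueError("control SD is zero for some unit")

    rows = []

    def add_family(comparison, results, extra=None):
        adj, _ = fdr_bh([r.p_perm for r in results], fdr_q)
        for j, (r, pa) in enumerate(zip(results, adj)):
            rows.append({
                "scale": mode, "unit": columns[j], "comparison": comparison,
                "statistic": r.statistic, "d": r.effect_size_d,
                "p_perm": r.p_perm, "p_fdr": float(pa),
                "sig_fdr": bool(pa < fdr_q), "sig_unc": bool(r.p_perm < alpha),
                "n_perm": n_perm, "seed": int(seed),
                **(extra[j] if extra else {}),
            })

    add_family(f"{control}_vs_zero", [
        perm_one_sample(ctr[:, j], n_perm, _rng(seed, 0, j)) for j in range(M)
    ])
    for gi, g in enumerate(patient_groups):
        if g not in mats:
            continue
        Zg = (mats[g] - mu) / sigma
        res = [perm_one_sample(Zg[:, j], n_perm, _rng(seed, 1 + gi, j))
               for j in range(M)]
        extra = [{"mean_z": float(np.nanmean(Zg[:, j]))} for j in range(M)]
        add_family(f"{g}_deviation", res, extra)
    if all(g in mats for g in patient_groups[:2]) and len(patient_groups) >= 2:
        g1, g2 = patient_groups[:2]
        add_family(f"{g1}_vs_{g2}", [
            perm_two_sample(mats[g1][:, j], mats[g2][:, j], n_perm,
                            _rng(seed, 9, j))
            for j in range(M)
        ])
    return pd.DataFrame(rows)
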