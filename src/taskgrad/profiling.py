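"""From parcel-level contrast estimates to system and gradient profiles.

A subject's task effect is summarised at two scales: (i) mean beta per
canonical functional system, and (ii) mean beta per bin of the principal
connectivity gradient, with the gradient discretised into equal-occupancy
bins (20 by default) ordered from unimodal/sensory (bin 1) to transmodal
(bin 20).  Profiles are adjusted for nuisance covariates (age, sex) by
ordinary least squares fitted across all subjects pooled over groups:
covariate slopes are removed while the sample mean level is preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BetaMatrix, GradientMap, ParcelAtlas

__all__ = [
    "parcel_means",
    "adjust_covariates",
    "system_means",
    "assign_bins",
    "gradient_profile",
]


def parcel_means(beta_volume: np.ndarray, atlas: ParcelAtlas,
                 affine: np.ndarray | None = None) -> np.ndarray:
    """Mean of finite voxel values within each parcel of the atlas.

    Returns a vector ordered like ``atlas.parcel_ids``; a parcel containing
    no finite voxel yields NaN and a warning.  The beta grid must match the
    atlas grid exactly (no resampling is performed).
    """
    vol = np.asarray(beta_volume, dtype=float)
    if vol.shape != atlas.labels.shape:
        raise ValueError(
            f"beta grid shape {vol.shape} does not match atlas {atlas.labels.shape}"
        )
    if affine is not None and not np.allclose(affine, atlas.affine, atol=1e-6):
        raise ValueError("beta volume affine does not match atlas affine")

    labels = atlas.labels.ravel()
    flat = vol.ravel()
    finite = np.isfinite(flat)
    nmax = labels.max() + 1
    sums = np.bincount(labels[finite], weights=flat[finite], minlength=nmax)
    counts = np.bincount(labels[finite], minlength=nmax)

    out = np.full(atlas.n_parcels, np.nan)
    for i, pid in enumerate(atlas.parcel_ids):
        if counts[pid] > 0:
            out[i] = sums[pid] / counts[pid]
        else:
            warnings.warn(f"parcel {pid} has no finite voxels; value set missing")
    return out


def adjust_covariates(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Remove linear covariate effects from each column of ``values``.

    Per column, ordinary least squares of the value on [intercept,
    covariates] is fitted over all subjects with a non-missing value (groups
    pooled); the output is the residual plus the fit evaluated at the
    covariate means of those subjects, so covariate slopes are removed while
    the column's mean level is preserved.  Missing (NaN) entries stay
    missing.
    """
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance covariate")
    n, c = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < c + 1:
        raise ValueError("rank-deficient covariate design")

    out = np.full_like(y, np.nan)
    for j in range(y.shape[1]):
        avail = np.isfinite(y[:, j])
        if avail.sum() < c + 2:
            raise ValueError(
                f"column {j}: need at least {c + 2} non-missing subjects"
            )
        dj = design[avail]
        beta, *_ = np.linalg.lstsq(dj, y[avail, j], rcond=None)
        at_means = np.concatenate([[1.0], X[avail].mean(axis=0)]) @ beta
        out[avail, j] = y[avail, j] - dj @ beta + at_means
    return out[:, 0] if squeeze else out


def system_means(parcel_betas: np.ndarray, atlas: ParcelAtlas) -> pd.DataFrame:
    """Unweighted mean beta over each system's parcels, skipping missing.

    ``parcel_betas`` is subjects x P with columns ordered like
    ``atlas.parcel_ids``; returns a subjects x K DataFrame with system-name
    columns.
    """
    vals = np.atleast_2d(np.asarray(parcel_betas, dtype=float))
    if vals.shape[1] != atlas.n_parcels:
        raise ValueError("parcel beta columns do not match atlas parcels")
    cols = {}
    for k, name in enumerate(atlas.system_names):
        idx = [i for i, p in enumerate(atlas.parcel_ids) if atlas.system_of[p] == k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            cols[name] = np.nanmean(vals[:, idx], axis=1)
    return pd.DataFrame(cols)


def assign_bins(gradient: GradientMap, n_bins: int = 20,
                mode: str = "occupancy") -> dict[int, int]:
    """Discretise the gradient into bins (1 = lowest/unimodal).

    In the default ``occupancy`` mode parcels are sorted ascending by
    gradient value (ties by parcel id) and cut into ``n_bins`` contiguous
    groups whose sizes differ by at most one; when P is not divisible by
    n_bins the larger groups take the lowest bin indices.  In ``width``
    mode bins are equal gradient-value intervals between the observed min
    and max (bins may then be empty).
    """
    items = list(gradient.value_of.items())
    P = len(items)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if P < n_bins:
        raise ValueError(f"need at least {n_bins} parcels, got {P}")
    vals = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("gradient values must be finite")
    if np.ptp(vals) == 0:
        warnings.warn("all gradient values identical; binning by parcel id order")
    if mode == "width":
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
        idx = np.clip(np.searchsorted(edges, vals, side="right"), 1, n_bins)
        return {pid: int(b) for (pid, _), b in zip(items, idx)}
    if mode != "occupancy":
        raise ValueError("mode must be 'occupancy' or 'width'")
    order = sorted(items, key=lambda kv: (kv[1], kv[0]))

    base, extra = divmod(P, n_bins)
    bin_of: dict[int, int] = {}
    pos = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        for pid, _ in order[pos:pos + size]:
            bin_of[pid] = b
        pos += size
    return bin_of


def gradient_profile(
    parcel_betas: np.ndarray,
    bin_of: dict[int, int],
    parcel_ids,
    overlap_frac: float = 0.0,
) -> np.ndarray:
    """Mean beta per gradient bin, optionally with overlapping rank windows.

    For each bin the window covers that bin's rank range extended on both
    sides by ``overlap_frac * P / (2 * n_bins)`` ranks (rounded), clipped at
    the ends, giving a sliding-window width of about
    ``(1 + overlap_frac) * P / n_bins``; ``overlap_frac = 0`` reproduces
    plain per-bin means exactly.  Missing parcels are skipped inside a
    window; a window with no available parcel yields NaN.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    vals = np.atleast_2d(np.asarray(parcel_betas, dtype=float))
    parcel_ids = list(parcel_ids)
    if set(bin_of) != set(parcel_ids):
        raise ValueError("bin assignment must cover exactly the given parcels")
    P = len(parcel_ids)
    n_bins = max(bin_of.values())

    # rank order: ascending bin, preserving within-bin order as given
    col_of = {p: i for i, p in enumerate(parcel_ids)}
    ranked = sorted(parcel_ids, key=lambda p: (bin_of[p], col_of[p]))
    rank_cols = np.array([col_of[p] for p in ranked])
    bins_sorted = np.array([bin_of[p] for p in ranked])

    extra = int(round(overlap_frac * P / (2.0 * n_bins)))
    out = np.full((vals.shape[0], n_bins), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty windows
        for b in range(1, n_bins + 1):
            inside = np.nonzero(bins_sorted == b)[0]
            if inside.size == 0:  # possible only with value-width bins
                continue
            lo = max(inside[0] - extra, 0)
            hi = min(inside[-1] + extra, P - 1)
            out[:, b - 1] = np.nanmean(vals[:, rank_cols[lo:hi + 1]], axis=1)
    return out
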