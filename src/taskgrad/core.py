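"""Domain containers and file I/O for parcel-level task-fMRI analysis.

The central objects are a labelled parcellation (:class:`ParcelAtlas`), a
per-parcel scalar position on the principal connectivity gradient
(:class:`GradientMap`), a subjects x parcels matrix of task contrast
estimates (:class:`BetaMatrix`), and a tabular subject roster carried as a
:class:`pandas.DataFrame`.  Volumes are NIfTI-1 (read via nibabel); tables
are tab- or comma-delimited text with a header row.

Missing data are represented as NaN in float matrices and exposed through a
boolean ``missing_mask``; no sentinel numbers are ever used, so means taken
over available entries are always valid.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "YEO7_SYSTEMS",
    "GROUPS",
    "ParcelAtlas",
    "GradientMap",
    "BetaMatrix",
    "StatResult",
    "read_atlas",
    "read_gradient",
    "write_atlas",
    "read_roster",
    "validate_roster",
    "read_beta_table",
    "write_beta_table",
    "read_cohort",
    "exclude_high_motion",
]

#: Canonical seven resting-state systems (order is the reporting order).
YEO7_SYSTEMS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience",
    "limbic",
    "control",
    "default",
)

#: The three study groups: healthy controls, frontal- and temporal-lobe epilepsy.
GROUPS = ("CTR", "FLE", "TLE")

#: Roster columns that must always be present.
ROSTER_REQUIRED = ("subject_id", "group", "age", "sex", "mean_fd")


def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)


@dataclass(frozen=True)
class ParcelAtlas:
    """Integer-labelled parcellation plus parcel-to-system assignments.

    Parameters
    ----------
    labels :
        3-D integer array; 0 is background, positive labels are parcels.
    affine :
        4x4 voxel-to-world transform of the label grid.
    parcel_ids :
        Ordered positive parcel labels; defines column order of every
        subjects x parcels matrix in the package.
    system_of :
        Map parcel_id -> system index into ``system_names``.
    system_names :
        Ordered system names (7 by default, 17 supported as pass-through).
    """

    labels: np.ndarray
    affine: np.ndarray
    parcel_ids: tuple[int, ...]
    system_of: Mapping[int, int]
    system_names: tuple[str, ...]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        ids = list(self.parcel_ids)
        if len(ids) != len(set(ids)) or any(i <= 0 for i in ids):
            raise ValueError("parcel ids must be unique and positive")
        for pid in ids:
            if pid not in self.system_of:
                raise ValueError(f"parcel {pid} has no system assignment")
            sid = self.system_of[pid]
            if not 0 <= sid < len(self.system_names):
                raise ValueError(f"parcel {pid} references unknown system {sid}")
        present = set(np.unique(labels)) - {0}
        missing = sorted(present - set(ids))
        if missing:
            raise ValueError(
                f"labels present in volume but absent from parcel table: {missing}"
            )
        for k, name in enumerate(self.system_names):
            if not any(self.system_of[p] == k for p in ids):
                raise ValueError(f"system '{name}' has zero parcels")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_systems(self) -> int:
        return len(self.system_names)

    def parcels_of_system(self, system: int | str) -> list[int]:
        if isinstance(system, str):
            system = self.system_names.index(system)
        return [p for p in self.parcel_ids if self.system_of[p] == system]


@dataclass(frozen=True)
class GradientMap:
    """Per-parcel loading on the unimodal-to-transmodal connectivity gradient."""

    value_of: Mapping[int, float]

    def __post_init__(self):
        vals = np.array(list(self.value_of.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("gradient values must be finite")

    def values(self, parcel_ids: Sequence[int]) -> np.ndarray:
        return np.array([self.value_of[p] for p in parcel_ids], dtype=float)


@dataclass
class BetaMatrix:
    """Subjects x parcels contrast estimates for one task contrast.

    ``values`` uses NaN for missing entries; ``missing_mask`` exposes them as
    a boolean array.  Row order always matches the roster's subject order.
    """

    contrast_id: str
    subjects: list[str]
    parcel_ids: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.parcel_ids)):
            raise ValueError("beta matrix shape does not match roster/parcels")
        with np.errstate(invalid="ignore"):
            bad = np.isinf(self.values)
        if bad.any():
            raise ValueError("non-missing beta entries must be finite")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def reindex(self, subjects: Sequence[str]) -> "BetaMatrix":
        """Return a copy with rows rearranged to the given subject order."""
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subjects]
        return BetaMatrix(
            self.contrast_id, list(subjects), self.parcel_ids, self.values[idx]
        )


@dataclass
class StatResult:
    """One permutation-test result.

    ``p_perm`` is always on the grid k/(n_perm+1), k >= 1; ``p_fdr`` is set
    after Benjamini-Hochberg adjustment across a family of results.
    """

    statistic: float
    p_perm: float
    n_perm: int
    seed: int
    effect_size_d: float | None = None
    p_fdr: float | None = None
    tails: str = "two"

    def __post_init__(self):
        if not 0.0 < self.p_perm <= 1.0:
            raise ValueError("p_perm must lie in (0, 1]")
        if self.p_perm < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p_perm below the attainable permutation floor")


# ---------------------------------------------------------------------------
# Atlas I/O


def read_atlas(label_volume_path, parcel_table_path, delimiter=None) -> ParcelAtlas:
    """Load a labelled NIfTI volume plus its parcel table.

    The table needs columns ``parcel_id`` and ``system_id`` (integer index
    or system name), and may carry a ``gradient`` column (read separately by
    :func:`read_gradient`).  An optional ``system_name`` column fixes the
    system ordering; otherwise seven-system defaults are used for indices.
    """
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"label volume {label_volume_path} is not integer-valued")
    labels = np.round(data).astype(np.int32)

    table = _read_table(parcel_table_path, delimiter)
    if "parcel_id" not in table or "system_id" not in table:
        raise ValueError("parcel table must have columns parcel_id, system_id")
    parcel_ids = tuple(int(p) for p in table["parcel_id"])

    sys_col = table["system_id"]
    if sys_col.dtype == object:  # names given directly
        names = tuple(dict.fromkeys(str(s) for s in sys_col))
        system_of = {int(p): names.index(str(s)) for p, s in zip(parcel_ids, sys_col)}
    else:
        sids = [int(s) for s in sys_col]
        k = max(sids) + 1
        if "system_name" in table:
            names_by_id = dict(zip(sids, table["system_name"].astype(str)))
            names = tuple(names_by_id.get(i, f"system{i}") for i in range(k))
        elif k == len(YEO7_SYSTEMS):
            names = YEO7_SYSTEMS
        else:
            names = tuple(f"system{i}" for i in range(k))
        system_of = dict(zip(parcel_ids, sids))

    return ParcelAtlas(labels, img.affine, parcel_ids, system_of, names)


def read_gradient(parcel_table_path, delimiter=None) -> GradientMap:
    """Read the per-parcel gradient column from a parcel table."""
    table = _read_table(parcel_table_path, delimiter)
    if "gradient" not in table:
        raise ValueError("parcel table has no 'gradient' column")
    return GradientMap(
        {int(p): float(g) for p, g in zip(table["parcel_id"], table["gradient"])}
    )


def write_atlas(atlas: ParcelAtlas, label_volume_path, parcel_table_path,
                gradient: GradientMap | None = None) -> None:
    """Write the label volume (NIfTI) and parcel table (TSV)."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(label_volume_path))
    rows = {
        "parcel_id": list(atlas.parcel_ids),
        "system_id": [atlas.system_of[p] for p in atlas.parcel_ids],
        "system_name": [atlas.system_names[atlas.system_of[p]] for p in atlas.parcel_ids],
    }
    if gradient is not None:
        rows["gradient"] = [gradient.value_of[p] for p in atlas.parcel_ids]
    pd.DataFrame(rows).to_csv(parcel_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Roster and beta-table I/O


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROSTER_REQUIRED if c not in roster.columns]
    if missing:
        raise ValueError(f"roster lacks required columns: {missing}")
    if roster["subject_id"].duplicated().any():
        dups = roster.loc[roster["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    bad = roster.loc[~roster["group"].isin(GROUPS), "subject_id"].tolist()
    if bad:
        raise ValueError(f"subjects with group outside {GROUPS}: {bad}")
    if (roster["age"] <= 0).any():
        raise ValueError("all ages must be positive")
    fd = roster["mean_fd"]
    if fd.notna().all() and (fd < 0).any():
        raise ValueError("mean_fd must be non-negative")
    return roster


def read_roster(path, delimiter=None) -> pd.DataFrame:
    roster = _read_table(path, delimiter)
    roster["subject_id"] = roster["subject_id"].astype(str)
    return validate_roster(roster)


def read_beta_table(path, delimiter=None) -> tuple[list[str], tuple[int, ...], np.ndarray]:
    """Read a subjects x parcels beta TSV (columns: subject_id, p<id>...)."""
    table = _read_table(path, delimiter)
    subjects = [str(s) for s in table["subject_id"]]
    pcols = [c for c in table.columns if c != "subject_id"]
    parcel_ids = tuple(int(str(c).lstrip("p")) for c in pcols)
    values = table[pcols].to_numpy(dtype=float)
    return subjects, parcel_ids, values


def write_beta_table(beta: BetaMatrix, path) -> None:
    frame = pd.DataFrame(beta.values, columns=[f"p{p}" for p in beta.parcel_ids])
    frame.insert(0, "subject_id", beta.subjects)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(
    roster_path,
    beta_dir,
    contrasts: Sequence[str] | None = None,
    atlas: ParcelAtlas | None = None,
) -> tuple[pd.DataFrame, dict[str, BetaMatrix]]:
    """Load a roster and per-contrast beta matrices, aligned by subject_id.

    ``beta_dir`` may contain either precomputed tables ``beta_<contrast>.tsv``
    (subjects x parcels) or, when ``atlas`` is given, one NIfTI volume per
    subject under ``<contrast>/<subject_id>.nii[.gz]`` from which parcel
    means are extracted.  Subjects missing a contrast get a fully
    missing-masked row for that contrast.
    """
    from .profiling import parcel_means  # local import to avoid a cycle

    roster = read_roster(roster_path)
    beta_dir = Path(beta_dir)
    if contrasts is None:
        contrasts = sorted(
            p.stem.removeprefix("beta_") for p in beta_dir.glob("beta_*.tsv")
        ) or sorted(p.name for p in beta_dir.iterdir() if p.is_dir())
    subjects = list(roster["subject_id"])

    betas: dict[str, BetaMatrix] = {}
    for contrast in contrasts:
        table_path = beta_dir / f"beta_{contrast}.tsv"
        if table_path.exists():
            file_subj, parcel_ids, vals = read_beta_table(table_path)
            if len(set(file_subj)) != len(file_subj):
                raise ValueError(f"duplicate subject ids in {table_path}")
            pos = {s: i for i, s in enumerate(file_subj)}
            values = np.full((len(subjects), len(parcel_ids)), np.nan)
            for i, s in enumerate(subjects):
                if s in pos:
                    values[i] = vals[pos[s]]
        elif atlas is not None and (beta_dir / contrast).is_dir():
            parcel_ids = atlas.parcel_ids
            values = np.full((len(subjects), len(parcel_ids)), np.nan)
            for i, s in enumerate(subjects):
                for suffix in (".nii.gz", ".nii"):
                    vol_path = beta_dir / contrast / f"{s}{suffix}"
                    if vol_path.exists():
                        try:
                            vol = np.asanyarray(nib.load(str(vol_path)).dataobj)
                        except Exception as exc:  # pragma: no cover - IO failure
                            raise IOError(f"unreadable volume {vol_path}: {exc}")
                        values[i] = parcel_means(vol.astype(float), atlas)
                        break
        else:
            raise FileNotFoundError(
                f"no beta table or volume directory for contrast '{contrast}' "
                f"under {beta_dir}"
            )
        betas[contrast] = BetaMatrix(contrast, subjects, tuple(parcel_ids), values)
    return roster, betas


# ---------------------------------------------------------------------------
# Motion quality control


def exclude_high_motion(
    roster: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop subjects whose mean framewise displacement exceeds ``threshold``.

    The comparison is strictly greater-than: a subject at exactly the
    threshold is kept.  Returns the filtered roster and a JSON-serialisable
    exclusion log.
    """
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be positive")
    fd = roster["mean_fd"]
    if fd.isna().any():
        bad = roster.loc[fd.isna(), "subject_id"].tolist()
        raise ValueError(f"mean_fd missing for subjects: {bad}")
    mask = fd > threshold
    log = [
        {"subject_id": str(r.subject_id), "mean_fd": float(r.mean_fd),
         "threshold": float(threshold), "reason": "high_motion"}
        for r in roster[mask].itertuples()
    ]
    return roster[~mask].reset_index(drop=True), log


def write_exclusion_log(log: list[dict], path) -> None:
    Path(path).write_text(json.dumps(log, indent=2) + "\n")
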