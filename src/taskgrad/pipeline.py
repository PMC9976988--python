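"""End-to-end orchestration: QC -> profiling -> inference -> reports.

`analyze_cohort` runs the full analysis in memory on roster + beta
matrices; `run_pipeline` wraps it with file I/O, an exclusion log and a
machine-readable run manifest, driven by a YAML `RunConfig`.  Given a seed,
every number in the report bundle is reproducible bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    BetaMatrix, GradientMap, ParcelAtlas, exclude_high_motion, read_atlas,
    read_cohort, read_gradient, write_exclusion_log,
)
from .inference import abc_test, group_contrast_report, perm_correlation
from .profiling import adjust_covariates, assign_bins, gradient_profile, system_means

log = logging.getLogger("taskgrad")

__all__ = ["RunConfig", "analyze_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    roster_path: str = ""
    parcel_table_path: str = ""
    beta_dir: str = ""
    atlas_volume_path: str | None = None
    out_dir: str | None = None
    contrasts: list[str] | None = None
    n_bins: int = 20
    overlap_frac: float = 0.0
    bin_mode: str = "occupancy"
    adjust_per_group: bool = False
    n_perm: int = 10000
    seed: int = 0
    fdr_q: float = 0.05
    alpha: float = 0.05
    fd_threshold: float = 0.5
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    control: str = "CTR"
    patient_groups: list[str] = field(default_factory=lambda: ["FLE", "TLE"])
    correlations: list[dict] = field(default_factory=list)

    def validate(self) -> "RunConfig":
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        for p in (self.roster_path, self.parcel_table_path, self.beta_dir):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.atlas_volume_path and not Path(self.atlas_volume_path).exists():
            raise FileNotFoundError(self.atlas_volume_path)
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def analyze_cohort(
    roster: pd.DataFrame,
    betas: dict[str, BetaMatrix],
    atlas: ParcelAtlas,
    gradient: GradientMap,
    config: RunConfig | None = None,
    **overrides,
) -> dict:
    """Full in-memory analysis of one cohort; returns the report bundle.

    Stages: motion QC, per-contrast system and gradient-bin profiling,
    covariate adjustment, control one-sample tests, patient deviation (Z)
    tests, patient-vs-patient two-sample tests, the area-between-curves
    global comparison for every group pair, and score correlations.
    """
    if config is None:
        config = RunConfig()
    for k, v in overrides.items():
        setattr(config, k, v)
    if config.n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    kept, exclusions = _stage("motion_qc", exclude_high_motion,
                              roster, config.fd_threshold)
    log.info("motion QC: kept %d/%d subjects", len(kept), len(roster))
    subjects = list(kept["subject_id"])
    groups_of = kept.set_index("subject_id")["group"]
    covs = kept[config.covariates].to_numpy(dtype=float)
    bin_of = _stage("assign_bins", assign_bins, gradient, config.n_bins,
                    config.bin_mode)

    def _adjust(values, covsub, groups_arr):
        if not config.adjust_per_group:
            return adjust_covariates(values, covsub)
        out = np.array(values, dtype=float)
        for g in np.unique(groups_arr):
            m = groups_arr == g
            out[m] = adjust_covariates(values[m], covsub[m])
        return out

    bundle: dict = {"exclusions": exclusions, "contrasts": {}}
    for contrast, beta in sorted(betas.items()):
        beta = beta.reindex(subjects)
        present = ~beta.missing_mask.all(axis=1)

        sysprof = _stage("system_means", system_means, beta.values, atlas)
        gradprof = _stage(
            "gradient_profile", gradient_profile,
            beta.values, bin_of, atlas.parcel_ids, config.overlap_frac,
        )
        present_ids = np.array(subjects)[present]
        grp = groups_of.loc[present_ids].to_numpy()
        sys_adj = pd.DataFrame(
            _stage("adjust", _adjust, sysprof.to_numpy()[present],
                   covs[present], grp),
            columns=sysprof.columns, index=present_ids,
        )
        grad_adj = pd.DataFrame(
            _stage("adjust", _adjust, gradprof[present], covs[present], grp),
            columns=[f"bin{b:02d}" for b in range(1, config.n_bins + 1)],
            index=present_ids,
        )

        def split(frame):
            return {
                g: frame[grp == g]
                for g in [config.control, *config.patient_groups]
                if (grp == g).sum() >= 2
            }

        sys_groups, grad_groups = split(sys_adj), split(grad_adj)
        reports = {}
        for mode, groups in (("systems", sys_groups), ("gradient", grad_groups)):
            reports[mode] = _stage(
                f"report_{mode}", group_contrast_report, groups, mode,
                config.control, tuple(config.patient_groups),
                config.n_perm, config.seed, config.fdr_q, config.alpha,
            )
        abc_rows = []
        names = list(grad_groups)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                cc = _stage(
                    "abc", abc_test, grad_groups[ga].to_numpy(),
                    grad_groups[gb].to_numpy(), config.n_perm, config.seed,
                    config.fdr_q, False,
                )
                abc_rows.append({
                    "contrast": contrast, "group_a": ga, "group_b": gb,
                    "abc": cc.abc, "p_perm": cc.p_perm,
                    "n_perm": cc.n_perm, "seed": cc.seed,
                })
        bundle["contrasts"][contrast] = {
            "systems": reports["systems"],
            "gradient": reports["gradient"],
            "abc": pd.DataFrame(abc_rows),
            "profiles": {"systems": sys_groups, "gradient": grad_groups},
        }

    corr_rows = []
    for ci, spec in enumerate(config.correlations):
        contrast = spec["contrast"]
        score_col = spec["score"]
        scale = spec.get("scale", "systems")
        method = spec.get("method", "pearson")
        nuisance_cols = spec.get("nuisance", [])
        entry = bundle["contrasts"][contrast]
        prof = pd.concat(entry["profiles"][scale].values())
        by_id = kept.set_index("subject_id")
        x = by_id.loc[prof.index, score_col].to_numpy(float)
        nuis = (by_id.loc[prof.index, nuisance_cols].to_numpy(float)
                if nuisance_cols else None)
        for uj, unit in enumerate(prof.columns):
            res = _stage(
                "correlate", perm_correlation, x, prof[unit].to_numpy(),
                nuis, method, config.n_perm,
                np.random.default_rng([config.seed, 100 + ci, uj]),
            )
            corr_rows.append({
                "contrast": contrast, "score": score_col, "scale": scale,
                "unit": unit, "method": method, "r": res.statistic,
                "p_perm": res.p_perm, "n_perm": config.n_perm,
                "seed": config.seed,
            })
    if corr_rows:
        frames = pd.DataFrame(corr_rows)
        for (contrast, scorec, scale), sub in frames.groupby(
                ["contrast", "score", "scale"], sort=False):
            from .inference import fdr_bh
            adj, _ = fdr_bh(sub["p_perm"].to_numpy(), config.fdr_q)
            frames.loc[sub.index, "p_fdr"] = adj
        bundle["correlations"] = frames
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """File-driven pipeline run; writes TSV reports and a manifest."""
    config.validate()
    atlas = _stage("read_atlas", read_atlas,
                   config.atlas_volume_path, config.parcel_table_path) \
        if config.atlas_volume_path else None
    gradient = _stage("read_gradient", read_gradient, config.parcel_table_path)
    roster, betas = _stage("read_cohort", read_cohort, config.roster_path,
                           config.beta_dir, config.contrasts, atlas)
    if atlas is None:
        raise ValueError("atlas_volume_path is required")

    bundle = analyze_cohort(roster, betas, atlas, gradient, config)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_exclusion_log(bundle["exclusions"], out / "exclusions.json")
        for contrast, entry in bundle["contrasts"].items():
            for mode in ("systems", "gradient", "abc"):
                entry[mode].to_csv(out / f"{contrast}_{mode}.tsv",
                                   sep="\t", index=False)
        if "correlations" in bundle:
            bundle["correlations"].to_csv(out / "correlations.tsv",
                                          sep="\t", index=False)
        manifest = {
            "config": asdict(config),
            "versions": {
                "taskgrad": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_subjects_input": int(len(roster)),
            "n_subjects_kept": int(len(roster) - len(bundle["exclusions"])),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        bundle["manifest"] = manifest
    return bundle
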