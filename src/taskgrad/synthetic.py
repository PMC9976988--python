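"""Synthetic parcel-level task-fMRI cohorts with known ground truth.

The generator emulates a three-group study (healthy controls and frontal-
and temporal-lobe epilepsy) scanned with cognitive task fMRI and summarised
at the parcel level on a 200-parcel, seven-system atlas.  Controls show
task-positive activation of dorsal-attention/frontoparietal systems and
deactivation of the default-mode system; patient groups carry group deltas
expressed in subject-SD units (so they translate directly into Cohen's d
and normative-Z targets), plus age/sex covariate slopes, a heavy-tailed
head-motion distribution (~2% of subjects exceed 0.5 mm mean framewise
displacement) and skewed task-performance scores coupled to the subject's
task-positive signal.

Noise model per subject s, parcel p of system k::

    beta[s, p] = m_k + delta[group(s), k] * sigma_subj
               + a_k * (age_s - mean age) + b_k * sex_s
               + u[s, k] + e[s, p]

with u ~ N(0, sigma_subj^2) a subject-by-system random effect shared across
the system's parcels (so effects specified in subject-SD units survive
averaging over parcels) and e ~ N(0, sigma_jitter^2) independent parcel
jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BetaMatrix, GradientMap, GROUPS, ParcelAtlas, YEO7_SYSTEMS

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "SimulatedCohort",
    "default_effects",
    "make_atlas_and_gradient",
    "simulate_cohort",
    "worked_fixture",
]

#: Parcel counts per system at the 200-parcel scale (seven-system scheme).
SYSTEM_OCCUPANCY_200 = (31, 35, 26, 24, 13, 26, 45)

#: Expected gradient position per system (unimodal low, transmodal high).
GRADIENT_BASE = {
    "visual": -1.6,
    "somatomotor": -1.2,
    "dorsal_attention": -0.5,
    "salience": -0.2,
    "limbic": 0.2,
    "control": 0.6,
    "default": 1.5,
}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: group sizes, demographics, atlas geometry, seed."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CTR": 52, "FLE": 56, "TLE": 64}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CTR": (34.1, 10.4), "FLE": (33.4, 10.2), "TLE": (39.2, 10.7)
        }
    )
    female_frac: dict[str, float] = field(
        default_factory=lambda: {"CTR": 30 / 52, "FLE": 29 / 56, "TLE": 44 / 64}
    )
    n_parcels: int = 200
    system_names: tuple[str, ...] = YEO7_SYSTEMS
    occupancy: tuple[int, ...] = SYSTEM_OCCUPANCY_200
    gradient_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(n < 4 for n in self.n_per_group.values()):
            raise ValueError("need at least 4 subjects per group")
        if sum(self.occupancy) != self.n_parcels:
            raise ValueError("system occupancy must sum to n_parcels")
        if self.n_parcels < len(self.system_names):
            raise ValueError("need at least one parcel per system")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure for one task contrast.

    Group deltas, covariate slopes excepted, are in units of the
    subject-level SD ``subject_sd`` so that an injected delta of 0.6
    corresponds to a Cohen's d (and expected normative Z) of ~0.6 at the
    system/bin level.
    """

    contrast_id: str
    control_mean: dict[str, float] = field(default_factory=dict)
    delta: dict[str, dict[str, float]] = field(default_factory=dict)
    age_slope: dict[str, float] = field(default_factory=dict)
    sex_slope: dict[str, float] = field(default_factory=dict)
    subject_sd: float = 0.1
    parcel_jitter_sd: float = 0.08
    score_coupling: float = 8.0
    score_skew: str = "lognormal"

    def __post_init__(self):
        if self.subject_sd <= 0 or self.parcel_jitter_sd < 0:
            raise ValueError("noise SDs must be positive")
        for g, d in self.delta.items():
            if not all(math.isfinite(v) for v in d.values()):
                raise ValueError(f"non-finite delta for group {g}")


def default_effects() -> dict[str, EffectSpec]:
    """Effect structure for the two flagship contrasts.

    Control system means echo the magnitudes seen for language and verbal
    working-memory contrasts in healthy adults (frontoparietal/salience
    activation ~0.1 for fluency, dorsal-attention/control activation
    0.2-0.26 for working memory, default-mode deactivation -0.06 to -0.08);
    patient deltas echo reduced task-positive activation (negative, larger
    in TLE for working memory) and reduced default-mode deactivation
    (positive at the transmodal end, larger in FLE).
    """
    common = dict(
        age_slope={"dorsal_attention": -0.002, "control": -0.002, "default": 0.001},
        sex_slope={"somatomotor": 0.02},
    )
    return {
        "verbal_fluency": EffectSpec(
            "verbal_fluency",
            control_mean={"control": 0.10, "salience": 0.08, "default": -0.06},
            delta={
                "FLE": {"default": 0.6, "control": -0.4},
                "TLE": {"control": -0.2},
            },
            **common,
        ),
        "verbal_wm": EffectSpec(
            "verbal_wm",
            control_mean={
                "dorsal_attention": 0.20, "control": 0.26,
                "somatomotor": -0.08, "default": -0.08,
            },
            delta={
                "FLE": {"dorsal_attention": -0.62, "control": -0.40, "default": 0.3},
                "TLE": {"dorsal_attention": -0.82, "control": -0.73},
            },
            **common,
        ),
    }


@dataclass
class SimulatedCohort:
    """A generated cohort: roster, per-contrast betas, atlas and gradient."""

    roster: pd.DataFrame
    betas: dict[str, BetaMatrix]
    atlas: ParcelAtlas
    gradient: GradientMap
    design: CohortDesign
    effects: dict[str, EffectSpec]


# ---------------------------------------------------------------------------


def _block_volume(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Lay parcels out as 2x2x2-voxel cubes on a lattice."""
    nx = math.ceil(n_parcels ** (1 / 3))
    ny = math.ceil(math.sqrt(n_parcels / nx))
    nz = math.ceil(n_parcels / (nx * ny))
    vol = np.zeros((2 * nx, 2 * ny, 2 * nz), dtype=np.int32)
    pid = 1
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if pid > n_parcels:
                    break
                vol[2 * i:2 * i + 2, 2 * j:2 * j + 2, 2 * k:2 * k + 2] = pid
                pid += 1
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return vol, affine


def make_atlas_and_gradient(
    design: CohortDesign, seed: int | None = None
) -> tuple[ParcelAtlas, GradientMap]:
    """Build a synthetic labelled volume and a system-ordered gradient.

    Gradient values are a per-system expected position plus Gaussian noise,
    so systems overlap in the middle of the axis while default-mode parcels
    dominate the transmodal apex.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    P, K = design.n_parcels, len(design.system_names)
    if P < K:
        raise ValueError("need at least one parcel per system")
    labels, affine = _block_volume(P)
    parcel_ids = tuple(range(1, P + 1))
    system_of = {}
    pid = 1
    for k, count in enumerate(design.occupancy):
        for _ in range(count):
            system_of[pid] = k
            pid += 1
    atlas = ParcelAtlas(labels, affine, parcel_ids, system_of, design.system_names)
    grad = {
        p: GRADIENT_BASE[design.system_names[system_of[p]]]
        + rng.normal(0.0, design.gradient_noise_sd)
        for p in parcel_ids
    }
    return atlas, GradientMap(grad)


def _patient_clinical(rng, group: str, n: int, age: np.ndarray) -> dict:
    onset_med = 10.0 if group == "FLE" else 13.0
    onset = np.minimum(np.maximum(rng.gamma(3.0, onset_med / 3.0, n), 1.0), age - 1)
    freq_mu, freq_sd = (1.15, 0.81) if group == "FLE" else (0.87, 0.55)
    fbtcs_p = 31 / 54 if group == "FLE" else 20 / 64
    days_med = 1.0 if group == "FLE" else 5.0
    return {
        "onset_age": np.round(onset, 1),
        "duration": np.round(age - onset, 1),
        "log_sz_freq": np.round(rng.normal(freq_mu, freq_sd, n), 2),
        "fbtcs": rng.binomial(1, fbtcs_p, n),
        "days_since_seizure": np.round(rng.lognormal(np.log(days_med), 1.0, n), 1),
    }


def simulate_cohort(
    design: CohortDesign | None = None,
    effects: dict[str, EffectSpec] | None = None,
    seed: int | None = None,
) -> SimulatedCohort:
    """Generate a full cohort: roster, demographics and per-contrast betas."""
    design = design or CohortDesign()
    effects = effects or default_effects()
    master = design.seed if seed is None else seed
    atlas, gradient = make_atlas_and_gradient(design, np.random.default_rng(
        [master, 0]).integers(2**31))
    rng = np.random.default_rng([master, 1])

    rows = []
    for group in GROUPS:
        n = design.n_per_group.get(group, 0)
        mu, sd = design.age_mean_sd[group]
        age = np.round(np.maximum(rng.normal(mu, sd, n), 18.0), 1)
        sex = rng.binomial(1, design.female_frac[group], n)  # 1 = female
        frame = pd.DataFrame({
            "subject_id": [f"{group.lower()}{i + 1:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "side": "NA" if group == "CTR" else
                    rng.choice(["L", "R"], n, p=[0.53, 0.47]),
            "mean_fd": np.round(rng.lognormal(np.log(0.18), 0.5, n), 3),
        })
        if group == "CTR":
            for col in ("onset_age", "duration", "log_sz_freq",
                        "fbtcs", "days_since_seizure"):
                frame[col] = np.nan
        else:
            for col, vals in _patient_clinical(rng, group, n, age).items():
                frame[col] = vals
        rows.append(frame)
    roster = pd.concat(rows, ignore_index=True)
    n_total = len(roster)
    mean_age = float(roster["age"].mean())

    sys_of_col = np.array([atlas.system_of[p] for p in atlas.parcel_ids])
    K = atlas.n_systems
    betas: dict[str, BetaMatrix] = {}
    for ci, (contrast, spec) in enumerate(sorted(effects.items())):
        crng = np.random.default_rng([master, 2, ci])
        mean_k = np.array([spec.control_mean.get(s, 0.0) for s in atlas.system_names])
        a_k = np.array([spec.age_slope.get(s, 0.0) for s in atlas.system_names])
        b_k = np.array([spec.sex_slope.get(s, 0.0) for s in atlas.system_names])
        delta_k = np.zeros((n_total, K))
        for g, dd in spec.delta.items():
            mask = (roster["group"] == g).to_numpy()
            for s, v in dd.items():
                delta_k[mask, atlas.system_names.index(s)] = v * spec.subject_sd

        u = crng.normal(0.0, spec.subject_sd, (n_total, K))
        subj_sys = (
            mean_k[None, :] + delta_k
            + np.outer(roster["age"] - mean_age, a_k)
            + np.outer(roster["sex"], b_k)
            + u
        )
        jitter = crng.normal(0.0, spec.parcel_jitter_sd, (n_total, atlas.n_parcels))
        values = subj_sys[:, sys_of_col] + jitter
        betas[contrast] = BetaMatrix(
            contrast, list(roster["subject_id"]), atlas.parcel_ids, values
        )

        # performance score: monotone (skewed) in the task-positive signal
        tp_cols = [atlas.system_names.index(s)
                   for s in ("dorsal_attention", "control")]
        tp = subj_sys[:, tp_cols].mean(axis=1)
        linear = spec.score_coupling * tp / spec.subject_sd + crng.normal(
            0.0, 1.0, n_total)
        if spec.score_skew == "lognormal":
            score = np.exp(0.35 * (linear - linear.mean()) / linear.std()) * 20.0
        else:
            score = 20.0 + linear
        roster[f"score_{contrast}"] = np.round(score, 2)

    return SimulatedCohort(roster, betas, atlas, gradient, design, effects)


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write a cohort to disk (NIfTI atlas + TSV tables); returns the paths."""
    from pathlib import Path

    from .core import write_atlas, write_beta_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "atlas": str(out / "atlas.nii.gz"),
        "parcels": str(out / "parcels.tsv"),
        "roster": str(out / "roster.tsv"),
        "beta_dir": str(out),
    }
    write_atlas(cohort.atlas, paths["atlas"], paths["parcels"], cohort.gradient)
    cohort.roster.to_csv(paths["roster"], sep="\t", index=False, na_rep="NA")
    for contrast, beta in cohort.betas.items():
        write_beta_table(beta, out / f"beta_{contrast}.tsv")
    return paths


def worked_fixture(seed: int = 7042) -> SimulatedCohort:
    """Miniature deterministic cohort: 3 groups x 6 subjects, 40 parcels."""
    design = CohortDesign(
        n_per_group={"CTR": 6, "FLE": 6, "TLE": 6},
        n_parcels=40,
        occupancy=(6, 7, 5, 5, 3, 5, 9),
        seed=seed,
    )
    return simulate_cohort(design)
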