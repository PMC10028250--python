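"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a neonate piglet study: ~58 subjects recorded in
their first 1-10 life hours, ~6 strides each, with roughly 10% of piglets
classified low birth weight (LBW: lowest birth-weight decile of the litter
AND at most 800 g).  Per stride it produces the analysis feature row (nine
gait variables, twelve dynamic-posture values, twelve coordination
components, subject characteristics) and harmonic representations of the
six joint-angle profiles consistent with those features.

Kinematics depend linearly on the *effective* age (recorded age minus an
optional injected developmental delay), mass, size and sex, plus Gaussian
noise.  Noise levels are calibrated so that inverting the kinematics for
age leaves a conditional standard deviation of about 2 h — the scale on
which the 75%-underestimation screening rule is meaningfully exercised.
The injected delay (default 5 h) is applied to LBW subjects recorded above
5 h of age, the subgroup a delayed-development hypothesis singles out.

Coordination lives in a 20-dimensional latent space embedded orthogonally
in the 96 coordination variables; the first twelve latent dimensions carry
unit-variance structure (and all of the subject-characteristic signal), so
a 12-component PCA of the 96-variable matrix retains the information.
Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._walker import WalkerConfig, synthesize_walker
from .fourier import ANALYSIS_JOINTS, REFERENCE_JOINT, FourierRepresentation
from .model import COORDINATION_COLUMNS, GAIT_COLUMNS, POSTURE_COLUMNS, SEX_COLUMN

LBW_MASS_CAP_G = 800.0
LBW_LITTER_QUANTILE = 0.10


def classify_birth_weight(
    litter_masses_g,
    litters=None,
    mass_cap_g: float = LBW_MASS_CAP_G,
    quantile: float = LBW_LITTER_QUANTILE,
) -> np.ndarray:
    """LBW/NBW categories from birth masses (grams), per litter.

    A piglet is LBW iff its birth mass is within the lowest ``quantile``
    of its litter (the ceil(quantile*n) lightest, ties broken by position,
    deterministic) AND does not exceed ``mass_cap_g``.
    """
    masses = np.asarray(litter_masses_g, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("birth masses must be positive")
    if litters is None:
        litters = np.zeros(len(masses), dtype=int)
    litters = np.asarray(litters)
    out = np.full(len(masses), "NBW", dtype=object)
    for lit in np.unique(litters):
        idx = np.flatnonzero(litters == lit)
        k = int(np.ceil(quantile * len(idx)))
        order = idx[np.lexsort((idx, masses[idx]))]  # stable: mass, then position
        for i in order[:k]:
            if masses[i] <= mass_cap_g:
                out[i] = "LBW"
    return out


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_subjects: int = 58
    strides_per_subject: tuple[int, int] = (4, 8)
    litter_size: int = 12
    age_range_h: tuple[float, float] = (1.0, 10.0)
    birth_weight_mean_g: float = 1500.0
    birth_weight_sd_g: float = 250.0
    growth_restricted_fraction: float = 0.12  # low-weight mixture component
    growth_restricted_mean_g: float = 720.0
    growth_restricted_sd_g: float = 90.0
    delay_h: float = 5.0  # injected developmental delay
    delay_min_age_h: float = 5.0  # only LBW subjects older than this are delayed
    inject_delay: bool = True
    target_age_sd_h: float = 2.0  # calibration target: sd(age | kinematics)
    target_mass_sd_kg: float = 0.15
    target_size_sd: float = 0.5
    n_latent_coordination: int = 20
    profile_samples: int = 100

    def __post_init__(self) -> None:
        if self.delay_h < 0 or self.target_age_sd_h <= 0:
            raise ValueError("delay must be non-negative and noise targets positive")


# feature -> (baseline, noise sd); slopes are attached below
_FEATURE_BASE: dict[str, tuple[float, float]] = {
    "stride_distance": (0.95, 0.08),
    "stride_frequency": (0.42, 0.05),
    "speed": (0.40, 0.05),
    "duty_factor_fore": (0.68, 0.03),
    "duty_factor_hind": (0.66, 0.03),
    "clearance_fore": (0.25, 0.04),
    "clearance_hind": (0.28, 0.04),
    "head_angle": (-0.20, 0.06),
    "hindlimb_phase": (0.78, 0.04),
    "shoulder_mean": (0.55, 0.08),
    "elbow_mean": (-0.65, 0.08),
    "carpal_mean": (0.30, 0.08),
    "hip_mean": (-0.45, 0.08),
    "stifle_mean": (0.75, 0.08),
    "tarsal_mean": (-0.55, 0.08),
    "shoulder_erom": (0.30, 0.05),
    "elbow_erom": (0.45, 0.05),
    "carpal_erom": (0.55, 0.05),
    "hip_erom": (0.25, 0.05),
    "stifle_erom": (0.40, 0.05),
    "tarsal_erom": (0.50, 0.05),
}


def _effect_slopes(cfg: GeneratorConfig) -> dict[str, dict[str, float]]:
    """Linear effects of (age_eff, mass, size, sex) on features.

    Slopes are chosen from the information budget: for driver theta with
    prior sd tau and target conditional sd sigma*, the summed squared
    signal-to-noise sum_j (a_j / s_j)^2 must equal 1/sigma*^2 - 1/tau^2,
    split evenly over that driver's carrier features.
    """
    def budget(tau: float, target: float) -> float:
        return max(1.0 / target**2 - 1.0 / tau**2, 0.0)

    tau_age = (cfg.age_range_h[1] - cfg.age_range_h[0]) / np.sqrt(12.0)
    s_age = np.sqrt(budget(tau_age, cfg.target_age_sd_h) / 6.0)
    s_mass = np.sqrt(budget(0.28, cfg.target_mass_sd_kg) / 3.0)
    s_size = np.sqrt(budget(1.0, cfg.target_size_sd) / 4.0)

    def a(feature: str, snr: float) -> float:
        return snr * _FEATURE_BASE[feature][1]

    return {
        "age": {
            "clearance_fore": a("clearance_fore", s_age),
            "stride_frequency": a("stride_frequency", s_age),
            "hip_mean": a("hip_mean", s_age),
            "carpal_erom": a("carpal_erom", s_age),
            "latent1": s_age,
            "latent2": s_age,
        },
        "mass": {
            "clearance_hind": a("clearance_hind", s_mass),
            "tarsal_mean": a("tarsal_mean", s_mass),
            "latent3": s_mass,
        },
        "size": {
            "head_angle": a("head_angle", s_size),
            "duty_factor_hind": a("duty_factor_hind", s_size),
            "shoulder_mean": a("shoulder_mean", s_size),
            "latent4": s_size,
        },
        "sex": {
            "stifle_mean": 0.05,
            "latent5": 0.3,
        },
    }


@dataclass
class SyntheticCohort:
    """A generated cohort: subject table, stride features, profiles."""

    subjects: pd.DataFrame
    strides: pd.DataFrame  # one row per stride: features + characteristics
    representations: list[FourierRepresentation]
    coordination_96: np.ndarray  # strides x 96, latent embedding
    config: GeneratorConfig
    seed: int
    true_effects: dict = field(default_factory=dict)

    @property
    def delayed_subjects(self) -> list[str]:
        return sorted(self.subjects.loc[self.subjects["true_delay_h"] > 0, "subject_id"])


def _base_harmonics(rng: np.random.Generator, n_harmonics: int = 8) -> dict[str, np.ndarray]:
    """Smooth per-joint base coordination shapes (unit energy amplitude)."""
    shapes = {}
    for j, joint in enumerate(ANALYSIS_JOINTS):
        mag = np.exp(-0.6 * np.arange(1, n_harmonics + 1)) * (1.0 + 0.2 * rng.standard_normal(n_harmonics))
        phase = rng.uniform(0, 2 * np.pi, n_harmonics)
        c = np.abs(mag) * np.exp(1j * phase)
        c[0] = abs(c[0])  # dominant first harmonic, in phase with reference
        shapes[joint] = c / np.sqrt((np.abs(c) ** 2).sum())
    return shapes


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministically from (config, seed)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.age_range_h

    # --- subjects -------------------------------------------------------
    n = cfg.n_subjects
    litters = np.repeat(np.arange(int(np.ceil(n / cfg.litter_size))), cfg.litter_size)[:n]
    # birth-weight mixture: a normal bulk plus a growth-restricted low tail
    restricted = rng.random(n) < cfg.growth_restricted_fraction
    bw = np.where(
        restricted,
        rng.normal(cfg.growth_restricted_mean_g, cfg.growth_restricted_sd_g, n),
        rng.normal(cfg.birth_weight_mean_g, cfg.birth_weight_sd_g, n),
    ).clip(450, 2300)
    category = classify_birth_weight(bw, litters)
    age = rng.uniform(lo, hi, n)
    sex = rng.integers(0, 2, n)
    mass = bw / 1000.0 + 0.005 * age + rng.normal(0, 0.03, n)
    size = 3.2 * (mass - mass.mean()) + rng.normal(0, 0.3, n)
    delay = np.where(
        cfg.inject_delay & (category == "LBW") & (age > cfg.delay_min_age_h), cfg.delay_h, 0.0
    )
    age_kin = age - delay  # effective age driving the kinematics
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "litter": litters,
            "sex_male": sex,
            "birth_weight_g": bw,
            "birth_weight_category": category,
            "mass": mass,
            "size": size,
            "age": age,
            "true_delay_h": delay,
        }
    )

    # --- per-stride features -------------------------------------------
    effects = _effect_slopes(cfg)
    centers = {"age": (lo + hi) / 2.0, "mass": float(mass.mean()), "size": 0.0, "sex": 0.5}
    n_strides = rng.integers(cfg.strides_per_subject[0], cfg.strides_per_subject[1] + 1, n)
    rows = []
    latent_rows = []
    m_latent = cfg.n_latent_coordination
    for i in range(n):
        drivers = {
            "age": age_kin[i] - centers["age"],
            "mass": mass[i] - centers["mass"],
            "size": size[i] - centers["size"],
            "sex": sex[i] - centers["sex"],
        }
        for k in range(n_strides[i]):
            row = {
                "subject_id": subjects.loc[i, "subject_id"],
                "stride_id": f"{subjects.loc[i, 'subject_id']}_t{k}",
                SEX_COLUMN: int(sex[i]),
                "birth_weight_category": category[i],
                "mass": mass[i],
                "size": size[i],
                "age": age[i],
                "true_delay_h": delay[i],
            }
            latent = np.zeros(m_latent)
            latent[:12] += rng.standard_normal(12)  # unit-variance analysis dims
            latent[12:] += 0.1 * rng.standard_normal(m_latent - 12)
            for name, (base, sd) in _FEATURE_BASE.items():
                val = base + rng.normal(0, sd)
                for drv, slopes in effects.items():
                    val += slopes.get(name, 0.0) * drivers[drv]
                row[name] = val
            for drv, slopes in effects.items():
                for lname, slope in slopes.items():
                    if lname.startswith("latent"):
                        latent[int(lname[6:]) - 1] += slope * drivers[drv]
            # eROM must stay positive
            for j in ANALYSIS_JOINTS:
                row[f"{j}_erom"] = max(row[f"{j}_erom"], 0.05)
            rows.append(row)
            latent_rows.append(latent)
    strides = pd.DataFrame(rows)
    latent_mat = np.asarray(latent_rows)

    # orthonormal embedding of the latent coordination space into the 96
    # coordination variables (fixed by the cohort seed)
    basis, _ = np.linalg.qr(rng.standard_normal((96, m_latent)))
    coordination_96 = latent_mat @ basis.T
    for c, col in enumerate(COORDINATION_COLUMNS):
        strides[col] = latent_mat[:, c]

    # --- joint-angle profiles consistent with posture + coordination ----
    shapes = _base_harmonics(np.random.default_rng(seed + 1))
    pert_map = 0.08 * np.random.default_rng(seed + 2).standard_normal((len(ANALYSIS_JOINTS), 8, 2, m_latent))
    reps: list[FourierRepresentation] = []
    phases = rng.uniform(0, 1, len(strides))
    for s_idx in range(len(strides)):
        row = strides.iloc[s_idx]
        coeffs: dict[str, np.ndarray] = {}
        phi = phases[s_idx]
        rot = np.exp(-2j * np.pi * np.arange(9) * phi)
        for j, joint in enumerate(ANALYSIS_JOINTS):
            pert = pert_map[j, :, 0, :] @ latent_rows[s_idx] + 1j * (pert_map[j, :, 1, :] @ latent_rows[s_idx])
            q = shapes[joint] + pert
            q = q / np.sqrt((np.abs(q) ** 2).sum())
            c = np.zeros(9, dtype=complex)
            c[0] = row[f"{joint}_mean"]
            c[1:] = row[f"{joint}_erom"] * q
            coeffs[joint] = c * rot
        ref = np.zeros(9, dtype=complex)
        ref[0] = 0.1
        ref[1] = 0.25  # reference phase 0 before the stride's time shift
        coeffs[REFERENCE_JOINT] = ref * rot
        reps.append(
            FourierRepresentation(
                coeffs=coeffs,
                meta={"stride_id": row["stride_id"], "subject_id": row["subject_id"], "true_phase": phi},
            )
        )

    return SyntheticCohort(
        subjects=subjects,
        strides=strides,
        representations=reps,
        coordination_96=coordination_96,
        config=cfg,
        seed=seed,
        true_effects=effects,
    )


def simulate_linear_outcome(
    features: pd.DataFrame,
    predictors: tuple[str, ...],
    beta: np.ndarray,
    alpha: float = 0.0,
    sigma: float = 0.5,
    nu: float = 30.0,
    outcome_name: str = "outcome",
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an outcome from the inference model itself with known slopes.

    ``beta`` are slopes on predictors standardized over ``features``; the
    outcome is alpha + Z beta + sigma * t_nu noise (already on its natural
    scale).  Used for parameter-recovery and calibration tests where the
    generating coefficients must be known exactly.
    """
    rng = np.random.default_rng(seed)
    X = features.loc[:, list(predictors)].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    y = alpha + Z @ np.asarray(beta, dtype=float) + sigma * rng.standard_t(nu, len(features))
    out = features.copy()
    out[outcome_name] = y
    return out


def generate_landmarks(
    cohort: SyntheticCohort,
    out_dir=None,
    frame_rate: float = 50.0,
    subjects: list[str] | None = None,
):
    """Synthesize walker landmark recordings for (a subset of) subjects.

    Each subject gets one recording of a planar walker scaled by its size
    score, with exact touchdown frames and strictly periodic strides.
    Returns {subject_id: (LandmarkTrajectories, WalkerTruth)}; when
    ``out_dir`` is given the recordings are also written as
    DeepLabCut-dialect CSVs (one per subject, 1000 px/m).
    """
    from .landmarks import write_landmark_table

    result = {}
    chosen = subjects or list(cohort.subjects["subject_id"][: min(3, len(cohort.subjects))])
    for sid in chosen:
        srow = cohort.subjects.set_index("subject_id").loc[sid]
        n_str = int((cohort.strides["subject_id"] == sid).sum()) or 4
        cfg = WalkerConfig(
            size=float(1.0 + 0.05 * srow["size"]),
            frame_rate=frame_rate,
            n_strides=min(n_str, 6),
        )
        traj, truth = synthesize_walker(cfg)
        traj.meta["subject_id"] = sid
        result[sid] = (traj, truth)
        if out_dir is not None:
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_landmark_table(traj, out / f"{sid}.csv", scale=1e-3)
    return result


def cohort_to_csv(cohort: SyntheticCohort, out_dir) -> None:
    """Write subjects.csv, strides.csv and a config echo."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.strides.to_csv(out / "strides.csv", index=False)
    (out / "generator_config.json").write_text(
        json.dumps({"seed": cohort.seed, **asdict(cohort.config)}, indent=2, default=list)
    )
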