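"""File-based pipeline stages: simulate -> segment -> transform -> fit ->
predict -> report.

Every stage reads and writes plain CSV/JSON so each is independently
testable and resumable; record counts are logged at stage boundaries
(candidate strides -> plausible -> retained), mirroring the quality funnel
of the analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fourier, kinematics, multivariate, segmentation
from .landmarks import SEGMENTS, read_landmark_table
from .model import COORDINATION_COLUMNS, PosteriorPredictor, SubjectModel, split_dataset
from .screening import RATIO_THRESHOLD
from .synthetic import GeneratorConfig, cohort_to_csv, generate_cohort, generate_landmarks

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise StageError(f"stage {stage!r}: missing input file {path}")
    return Path(path)


def run_simulate(out_dir, seed: int = 0, config: GeneratorConfig | None = None, landmarks: bool = False):
    """Generate a synthetic cohort and write its tables (and optionally
    walker landmark recordings in the DeepLabCut dialect)."""
    cohort = generate_cohort(config, seed=seed)
    cohort_to_csv(cohort, out_dir)
    if landmarks:
        generate_landmarks(cohort, out_dir=Path(out_dir) / "landmarks")
    logger.info("simulate: %d subjects, %d strides", len(cohort.subjects), len(cohort.strides))
    return cohort


def run_segment(
    landmark_csvs: list,
    out_csv,
    frame_rate: float = 50.0,
    scale: float = 1.0,
    likelihood_min: float = 0.9,
    noise_max: float = 0.05,
    bone_length_tolerance: float = 0.3,
    cyclicality_max: float = segmentation.DEFAULT_CYCLICALITY_MAX,
) -> pd.DataFrame:
    """Find episodes and stride candidates in landmark recordings.

    Writes one row per candidate: source file, episode, frames,
    touchdowns, stance fractions, cyclicality and filter verdicts.
    """
    rows = []
    for path in landmark_csvs:
        path = _require(Path(path), "segment")
        traj = read_landmark_table(path, frame_rate=frame_rate, scale=scale)
        subject = path.stem
        episodes = segmentation.find_episodes(
            traj, likelihood_min=likelihood_min, noise_max=noise_max, bone_length_tolerance=bone_length_tolerance
        )
        n_candidates = 0
        for ep in episodes:
            for cand in segmentation.label_strides(traj, ep, subject_id=subject):
                gv = kinematics.gait_variables(traj, cand)
                ref_len = kinematics.reference_length(traj, cand.start, cand.end)
                gv_dimless = kinematics.dimensionless(gv, ref_len)
                cand.gait = gv_dimless.as_dict() | {"stride_frequency": gv.stride_frequency}
                n_candidates += 1
                rows.append(
                    {
                        "source": str(path),
                        "subject_id": subject,
                        "stride_id": f"{subject}_{cand.stride_id}",
                        "episode_start": ep.start,
                        "episode_end": ep.end,
                        "start": cand.start,
                        "end": cand.end,
                        "touchdown_hind": cand.touchdown_hind,
                        "stance_fore": cand.stance_fore,
                        "stance_hind": cand.stance_hind,
                        "cyclicality": cand.cyclicality,
                        "reference_length": ref_len,
                        **{f"gv_{k}": v for k, v in gv_dimless.as_dict().items()},
                        "passed": np.nan,  # filled below
                        "failed_filters": "",
                    }
                )
                cands = [cand]
                kept = segmentation.filter_strides(cands, cyclicality_max=cyclicality_max)
                rows[-1]["passed"] = bool(kept)
                rows[-1]["failed_filters"] = ";".join(cand.failed_filters)
        logger.info("segment %s: %d episodes, %d candidates", path.name, len(episodes), n_candidates)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    logger.info("segment: %d candidates, %d retained", len(df), int(df["passed"].sum()) if len(df) else 0)
    return df


def run_transform(
    landmark_csvs: list,
    stride_table_csv,
    out_csv,
    frame_rate: float = 50.0,
    scale: float = 1.0,
    n_samples: int = 100,
    subjects_csv=None,
) -> pd.DataFrame:
    """Turn retained strides into the analysis feature table.

    Extracts joint-angle profiles, applies the Fourier decomposition with
    affine superimposition (alignment on the total forelimb angle),
    separates dynamic posture from coordination, runs the coordination PCA
    (12 components) and assembles gait variables into one row per stride.
    Optionally merges subject metadata (sex, mass, age, ...) by subject id.
    """
    strides = pd.read_csv(_require(Path(stride_table_csv), "transform"))
    strides = strides[strides["passed"] == True]  # noqa: E712
    by_source: dict[str, pd.DataFrame] = dict(tuple(strides.groupby("source")))
    reps = []
    meta_rows = []
    for path in landmark_csvs:
        key = str(Path(path))
        if key not in by_source:
            continue
        traj = read_landmark_table(path, frame_rate=frame_rate, scale=scale)
        for _, row in by_source[key].iterrows():
            class _S:  # minimal stride view for extract_profiles
                start = int(row["start"])
                end = int(row["end"])
                stride_id = row["stride_id"]
                subject_id = row["subject_id"]

            sk = kinematics.extract_profiles(traj, _S, n_samples=n_samples)
            reps.append(fourier.FourierRepresentation.from_profiles(sk.profiles, stride_id=row["stride_id"]))
            meta_rows.append(row)
    if not reps:
        raise StageError("stage 'transform': no retained strides found")
    aligned, _ = fourier.align_cycles(reps)
    coord = np.stack([fourier.coordination_residual(rep) for rep in aligned])
    scores, pca = multivariate.coordination_pca(coord)
    logger.info(
        "transform: %d strides, 12 coordination components capture %.1f%% of variability",
        len(reps),
        100 * pca.explained_variance_ratio[:12].sum(),
    )
    out_rows = []
    for i, row in enumerate(meta_rows):
        rec = {
            "stride_id": row["stride_id"],
            "subject_id": row["subject_id"],
            **{k.removeprefix("gv_"): row[k] for k in row.index if k.startswith("gv_")},
        }
        affine, _ = fourier.extract_affine(reps[i])
        for joint in fourier.ANALYSIS_JOINTS:
            rec[f"{joint}_mean"] = affine.mean[joint]
            rec[f"{joint}_erom"] = affine.amplitude[joint]
        for c, col in enumerate(COORDINATION_COLUMNS):
            rec[col] = scores[i, c]
        out_rows.append(rec)
    df = pd.DataFrame(out_rows)
    if subjects_csv is not None:
        meta = pd.read_csv(_require(Path(subjects_csv), "transform"))
        df = df.merge(meta, on="subject_id", how="left")
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_fit(
    features_csv,
    outcome: str,
    out_dir,
    draws: int = 1000,
    tune: int = 1000,
    chains: int = 4,
    seed: int = 0,
    profile: str | None = None,
):
    """Split the feature table, fit the outcome model on the NBW training
    set and save the posterior bundle plus the split tables."""
    df = pd.read_csv(_require(Path(features_csv), "fit"))
    train, validation, test = split_dataset(df, seed=seed)
    logger.info("fit %s: train %d / validation %d / test %d strides", outcome, len(train), len(validation), len(test))
    model = SubjectModel.from_dataframe(train, outcome=outcome)
    results = model.fit(draws=draws, tune=tune, chains=chains, seed=seed, profile=profile)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.save_bundle(out)
    train.to_csv(out / "train.csv", index=False)
    validation.to_csv(out / "validation.csv", index=False)
    test.to_csv(out / "test.csv", index=False)
    if not results.converged:
        logger.warning("fit %s: R-hat above 1.01 — run marked failed, results still written", outcome)
        (out / "FAILED").write_text("rhat > 1.01")
    return results


def run_predict(features_csv, bundle_dir, out_csv, n_samples: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-stride posterior-predictive inference with a saved bundle.

    Writes one row per stride: actual value, predictive mean, mean Delta,
    predictive sd and the fraction of predictive samples below actual.
    """
    df = pd.read_csv(_require(Path(features_csv), "predict"))
    predictor = PosteriorPredictor.load(_require(Path(bundle_dir), "predict"))
    inferences = predictor.predict(df, n_samples=n_samples, seed=seed)
    out = pd.DataFrame(
        {
            "stride_id": [inf.stride_id for inf in inferences],
            "subject_id": [inf.subject_id for inf in inferences],
            "outcome": predictor.design.outcome,
            "actual": [inf.actual for inf in inferences],
            "pred_mean": [float(inf.samples.mean()) for inf in inferences],
            "mean_delta": [inf.mean_delta for inf in inferences],
            "pred_sd": [inf.sd for inf in inferences],
            "fraction_below": [inf.fraction_below for inf in inferences],
        }
    )
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def run_report(predictions_csv, out_csv, ratio_threshold: float = RATIO_THRESHOLD) -> pd.DataFrame:
    """Aggregate per-stride predictions into per-subject screening verdicts.

    Works from the per-stride prediction summaries: the underestimation
    ratio is the mean per-stride fraction of predictive samples below
    actual (equal predictive sample counts per stride), the count is the
    number of strides with negative mean Delta, and the flag applies the
    ratio threshold plus the stride-majority rule.
    """
    pred = pd.read_csv(_require(Path(predictions_csv), "report"))
    rows = []
    for sid, grp in pred.groupby("subject_id"):
        n = len(grp)
        count = int((grp["mean_delta"] < 0).sum())
        ratio = float(grp["fraction_below"].mean())
        rows.append(
            {
                "subject_id": sid,
                "actual": float(grp["actual"].mean()),
                "strides": n,
                "underestimation_count": count,
                "underestimation_ratio": round(ratio, 4),
                "pred_mean_delta": float(grp["mean_delta"].mean()),
                "pred_sd": float(np.sqrt((grp["pred_sd"] ** 2).mean())),
                "consistent_underestimation": bool(ratio > ratio_threshold and count > n / 2),
            }
        )
    out = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    logger.info("report: %d subjects, %d flagged", len(out), int(out["consistent_underestimation"].sum()))
    return out


def run_pipeline(
    out_dir,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    outcome: str = "age",
    draws: int = 1000,
    tune: int = 1000,
    chains: int = 4,
    profile: str | None = None,
) -> pd.DataFrame:
    """End-to-end run on a synthetic cohort: simulate -> fit -> predict ->
    report.  Returns the per-subject verdict table."""
    out = Path(out_dir)
    run_simulate(out, seed=seed, config=config)
    run_fit(out / "strides.csv", outcome, out / f"model_{outcome}", draws=draws, tune=tune, chains=chains, seed=seed, profile=profile)
    run_predict(out / "strides.csv", out / f"model_{outcome}", out / f"predictions_{outcome}.csv", seed=seed)
    verdicts = run_report(out / f"predictions_{outcome}.csv", out / f"verdicts_{outcome}.csv")
    (out / "run_config.json").write_text(
        json.dumps(
            {"seed": seed, "outcome": outcome, "draws": draws, "tune": tune, "chains": chains, "profile": profile},
            indent=2,
        )
    )
    return verdicts
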