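"""Locomotion episodes, footfall detection and stride-cycle filtering.

The continuous recording is first reduced to episodes: maximal frame
intervals with high pose-estimation likelihood (rolling mean), steady
landmark movement (bounded frame-to-frame displacement) and consistent
skeleton-segment lengths.  Within an episode, footfalls are found with a
kinematic contact proxy — a hoof is in stance while its horizontal speed
stays below a fraction of the stride-mean withers speed — and strides are
cut from forelimb touchdown to the next ipsilateral forelimb touchdown.
A start-end-matching check (Procrustes superimposition of the full
17-landmark configuration) quantifies how cyclical each candidate is, and
plausibility bounds on the gait variables discard implausible candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import procrustes

from .landmarks import SEGMENTS, LandmarkTrajectories

#: Default plausibility bounds (closed intervals) for gait variables.
#: Speed bound assumes dimensionless values; frequency is in Hz.
DEFAULT_GAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "duty_factor_fore": (0.0, 1.0),
    "duty_factor_hind": (0.0, 1.0),
    "speed": (0.0, 3.0),
    "stride_frequency": (0.1, 10.0),
    "clearance_fore": (0.0, 1.0),
    "clearance_hind": (0.0, 1.0),
    "hindlimb_phase": (0.0, 1.0),
}

DEFAULT_CYCLICALITY_MAX = 0.02  # Procrustes disparity; noiseless strides score ~1e-12


@dataclass
class Episode:
    """Half-open frame interval [start, end) of usable rightward walking."""

    start: int
    end: int
    mean_likelihood: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class StrideCandidate:
    """One forelimb-cycle stride candidate with its quality verdicts."""

    start: int  # forelimb touchdown frame
    end: int  # next ipsilateral forelimb touchdown (half-open)
    touchdown_fore: int = -1
    touchdown_hind: int | None = None
    stance_fore: float = np.nan  # fraction of stride frames in contact
    stance_hind: float = np.nan
    cyclicality: float = np.nan  # Procrustes disparity start vs end config
    passed_filters: bool = True
    failed_filters: list[str] = field(default_factory=list)
    gait: dict | None = None  # gait-variable dict, filled before filtering
    stride_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("stride end must exceed start")
        if self.touchdown_fore < 0:
            self.touchdown_fore = self.start


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean along axis 0, edges padded by reflection."""
    if window <= 1:
        return x
    pad = window // 2
    xp = np.pad(x, [(pad, pad)] + [(0, 0)] * (x.ndim - 1), mode="edge")
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid")[: x.shape[0]], 0, xp)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def find_episodes(
    traj: LandmarkTrajectories,
    likelihood_min: float = 0.9,
    noise_max: float = 0.05,
    bone_length_tolerance: float = 0.3,
    likelihood_window: int = 5,
    min_frames: int = 1,
) -> list[Episode]:
    """Maximal frame intervals passing the three digitization-quality filters.

    A frame is usable when (i) the ``likelihood_window``-frame rolling-mean
    likelihood of every landmark is at least ``likelihood_min``, (ii) no
    landmark moves more than ``noise_max`` meters from the previous frame,
    and (iii) within the resulting run, every skeleton-segment length stays
    within a relative ``bone_length_tolerance`` of the run's median length
    (runs are split at violating frames).
    """
    lik = _rolling_mean(traj.likelihood, likelihood_window)
    ok = (lik >= likelihood_min).all(axis=1)
    disp = np.linalg.norm(np.diff(traj.xy, axis=0), axis=2).max(axis=1)
    ok[1:] &= disp <= noise_max

    seg_len = traj.segment_lengths(SEGMENTS).to_numpy()
    episodes: list[Episode] = []
    for s, e in _runs(ok):
        med = np.median(seg_len[s:e], axis=0)
        med = np.where(med > 0, med, 1.0)
        rel = np.abs(seg_len[s:e] / med - 1.0)
        good = (rel <= bone_length_tolerance).all(axis=1)
        for s2, e2 in _runs(good):
            if e2 - s2 >= min_frames:
                episodes.append(
                    Episode(start=s + s2, end=s + e2, mean_likelihood=float(traj.likelihood[s + s2 : s + e2].mean()))
                )
    return episodes


def stance_mask(
    traj: LandmarkTrajectories,
    episode: Episode,
    hoof: str,
    v_stance_fraction: float = 0.1,
    min_stance_frames: int = 3,
) -> np.ndarray:
    """Boolean stance mask over the episode frames for one hoof.

    Stance: horizontal hoof speed below ``v_stance_fraction`` of the
    episode-mean withers speed, sustained for at least
    ``min_stance_frames`` frames.
    """
    s, e = episode.start, episode.end
    fps = traj.frame_rate
    hx = traj.point(hoof)[s:e, 0]
    speed = np.abs(np.gradient(hx)) * fps
    w = traj.point("withers")[s:e, 0]
    v_ref = abs(w[-1] - w[0]) / max((e - s - 1) / fps, 1e-9)
    if v_ref <= 0:
        v_ref = np.abs(np.gradient(w)).mean() * fps
    mask = speed < v_stance_fraction * v_ref
    out = np.zeros_like(mask)
    for s2, e2 in _runs(mask):
        if e2 - s2 >= min_stance_frames:
            out[s2:e2] = True
    return out


def detect_footfalls(
    traj: LandmarkTrajectories,
    episode: Episode,
    hoof: str,
    v_stance_fraction: float = 0.1,
    min_stance_frames: int = 3,
) -> list[int]:
    """Touchdown frames (stance onsets) for one hoof within an episode.

    Returns an empty list when fewer than two touchdowns are found (no
    complete stride can be cut).
    """
    mask = stance_mask(traj, episode, hoof, v_stance_fraction, min_stance_frames)
    touchdowns = [episode.start + s for s, _ in _runs(mask) if s > 0]  # onset must be observed
    return touchdowns if len(touchdowns) >= 2 else []


def cyclicality(traj: LandmarkTrajectories, stride) -> float:
    """Procrustes disparity between start- and end-of-stride configurations.

    Both 17-landmark configurations are superimposed by translation,
    rotation and uniform scaling; 0 means a perfectly cyclic stride.
    """
    start, end = int(stride.start), int(stride.end)
    end = min(end, traj.n_frames - 1)
    a = traj.xy[start]
    b = traj.xy[end]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("degenerate configuration: all landmarks coincident")
    _, _, disparity = procrustes(a, b)
    return float(disparity)


def label_strides(
    traj: LandmarkTrajectories,
    episode: Episode,
    v_stance_fraction: float = 0.1,
    min_stance_frames: int = 3,
    subject_id: str = "",
) -> list[StrideCandidate]:
    """Cut stride candidates: forelimb touchdown to next forelimb touchdown.

    Fills per-candidate hindlimb touchdown, stance fractions (duty-factor
    numerators) and the Procrustes cyclicality.
    """
    fore_td = detect_footfalls(traj, episode, "forehoof", v_stance_fraction, min_stance_frames)
    if len(fore_td) < 2:
        return []
    fore_mask = stance_mask(traj, episode, "forehoof", v_stance_fraction, min_stance_frames)
    hind_mask = stance_mask(traj, episode, "hindhoof", v_stance_fraction, min_stance_frames)
    hind_td = [episode.start + s for s, _ in _runs(hind_mask) if s > 0]

    out: list[StrideCandidate] = []
    for k, (s, e) in enumerate(zip(fore_td[:-1], fore_td[1:])):
        i0, i1 = s - episode.start, e - episode.start
        hind_in = [t for t in hind_td if s <= t < e]
        cand = StrideCandidate(
            start=s,
            end=e,
            touchdown_fore=s,
            touchdown_hind=hind_in[0] if hind_in else None,
            stance_fore=float(fore_mask[i0:i1].mean()),
            stance_hind=float(hind_mask[i0:i1].mean()),
            stride_id=f"ep{episode.start}_s{k}",
            subject_id=subject_id,
        )
        cand.cyclicality = cyclicality(traj, cand)
        out.append(cand)
    return out


def filter_strides(
    candidates: list[StrideCandidate],
    gait_variable_bounds: dict[str, tuple[float, float]] | None = None,
    cyclicality_max: float = DEFAULT_CYCLICALITY_MAX,
) -> list[StrideCandidate]:
    """Keep candidates whose gait variables all lie inside their bounds.

    Each candidate must carry its gait-variable dict (``cand.gait``).
    Failed filter names are recorded on every candidate; the returned list
    contains the retained ones only.
    """
    bounds = DEFAULT_GAIT_BOUNDS if gait_variable_bounds is None else gait_variable_bounds
    kept: list[StrideCandidate] = []
    for cand in candidates:
        failed: list[str] = []
        gait = cand.gait or {}
        for name, (lo, hi) in bounds.items():
            if name in gait:
                v = gait[name]
                if not (np.isfinite(v) and lo <= v <= hi):
                    failed.append(name)
        if np.isfinite(cand.cyclicality) and cand.cyclicality > cyclicality_max:
            failed.append("cyclicality")
        cand.failed_filters = failed
        cand.passed_filters = not failed
        if cand.passed_filters:
            kept.append(cand)
    return kept
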