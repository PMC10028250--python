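"""Joint-angle profiles and spatiotemporal gait variables.

Angle convention (right-handed frame, y up): a straight joint — distal
segment continuing the proximal one — is zero; counter-clockwise angles
are positive; range (-pi, pi].  The six analysis joints are shoulder,
elbow, carpal, hip, stifle and tarsal; the total forelimb angle
(croup-withers-forehoof) serves as temporal reference only.

Gait variables follow kinematic contact definitions (no force plate):
stride distance/frequency/speed, fore- and hindlimb duty factor, fore- and
hindlimb clearance (1 - min/max of the proximal-trunk-landmark-to-hoof
distance, a flexion proxy), stride-average head angle, and hindlimb phase
(fore-to-hind touchdown lag as a cycle fraction).  Dimensionless conversion
uses dynamic-similarity scaling with the cumulated snout-to-tailbase
landmark chain distance as the reference length h:
distance/h, frequency*sqrt(h/g), speed/sqrt(g*h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .landmarks import AXIS_CHAIN, LandmarkTrajectories

#: Landmark triplets (proximal, center, distal) defining each angle.
JOINT_TRIPLETS: dict[str, tuple[str, str, str]] = {
    "shoulder": ("scapula", "shoulder", "elbow"),
    "elbow": ("shoulder", "elbow", "carpal"),
    "carpal": ("elbow", "carpal", "forefetlock"),
    "hip": ("croup", "hip", "stifle"),
    "stifle": ("hip", "stifle", "tarsal"),
    "tarsal": ("stifle", "tarsal", "hindfetlock"),
    "forelimb_total": ("croup", "withers", "forehoof"),
}

GRAVITY = 9.81  # m/s^2


def joint_angle(p_proximal, p_center, p_distal) -> float | np.ndarray:
    """Signed joint angle for points or arrays of points.

    Zero for a collinear continuation of the proximal segment; positive
    counter-clockwise; range (-pi, pi].  Accepts (..., 2) arrays and
    broadcasts over leading dimensions.
    """
    p = np.asarray(p_proximal, dtype=float)
    c = np.asarray(p_center, dtype=float)
    d = np.asarray(p_distal, dtype=float)
    u = c - p
    v = d - c
    if np.any(np.linalg.norm(u, axis=-1) < 1e-12) or np.any(np.linalg.norm(v, axis=-1) < 1e-12):
        raise ValueError("degenerate segment: coincident points")
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = (u * v).sum(axis=-1)
    ang = np.arctan2(cross, dot)
    return float(ang) if ang.ndim == 0 else ang


def line_angle(p_from, p_to) -> np.ndarray:
    """Angle of the line p_from -> p_to against the horizontal, radians."""
    v = np.asarray(p_to, dtype=float) - np.asarray(p_from, dtype=float)
    return np.arctan2(v[..., 1], v[..., 0])


@dataclass
class StrideKinematics:
    """Uniformly resampled joint-angle profiles of one stride cycle.

    ``profiles`` maps joint name -> array of ``n_samples`` angles sampled at
    t = 0, 1/n, ..., (n-1)/n of the cycle (sample n wraps back to 0).
    """

    profiles: dict[str, np.ndarray]
    n_samples: int
    reference_length: float  # meters
    stride_id: str = ""
    subject_id: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class GaitVariables:
    """Whole-stride summary variables (collective variables)."""

    stride_distance: float  # m, or h after dimensionless conversion
    stride_frequency: float  # Hz, or dimensionless
    speed: float  # m/s, or dimensionless
    duty_factor_fore: float
    duty_factor_hind: float
    clearance_fore: float
    clearance_hind: float
    head_angle: float  # rad
    hindlimb_phase: float  # cycle fraction [0, 1)
    torso_angle: float = 0.0  # rad; stored, not part of the 9 model variables
    is_dimensionless: bool = False

    #: Names of the nine variables that enter the subject model.
    MODEL_VARIABLES = (
        "stride_distance",
        "stride_frequency",
        "speed",
        "duty_factor_fore",
        "duty_factor_hind",
        "clearance_fore",
        "clearance_hind",
        "head_angle",
        "hindlimb_phase",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.MODEL_VARIABLES}


def _angle_series(traj: LandmarkTrajectories, joint: str) -> np.ndarray:
    if joint == "torso":
        return line_angle(traj.point("croup"), traj.point("withers"))
    p, c, d = JOINT_TRIPLETS[joint]
    return joint_angle(traj.point(p), traj.point(c), traj.point(d))


def reference_length(traj: LandmarkTrajectories, start: int, end: int) -> float:
    """Stride-mean cumulated landmark-chain distance along the body axis."""
    total = np.zeros(end - start)
    for a, b in zip(AXIS_CHAIN[:-1], AXIS_CHAIN[1:]):
        total += np.linalg.norm(traj.point(a)[start:end] - traj.point(b)[start:end], axis=1)
    return float(total.mean())


def extract_profiles(
    traj: LandmarkTrajectories,
    stride,
    n_samples: int = 100,
    joints: tuple[str, ...] | None = None,
    likelihood_min: float = 0.5,
    max_bad_fraction: float = 0.2,
) -> StrideKinematics:
    """Extract unwrapped, uniformly resampled joint-angle profiles.

    ``stride`` is anything with integer ``start`` and ``end`` frame
    attributes (half-open [start, end)), e.g. a
    :class:`~gaitscreen.segmentation.StrideCandidate`.  Angles are computed
    per frame, unwrapped to remove 2*pi jumps, and linearly interpolated
    onto ``n_samples`` uniform points of the cycle.  More than
    ``max_bad_fraction`` of frames below ``likelihood_min`` (any landmark)
    is an error: insufficient digitization.
    """
    start, end = int(stride.start), int(stride.end)
    if end - start < 3:
        raise ValueError("stride too short")
    bad = (traj.likelihood[start:end] < likelihood_min).any(axis=1)
    if bad.mean() > max_bad_fraction:
        raise ValueError(
            f"insufficient digitization: {bad.mean():.0%} of frames below likelihood {likelihood_min}"
        )
    if joints is None:
        joints = ("shoulder", "elbow", "carpal", "hip", "stifle", "tarsal", "forelimb_total")
    # phase of each frame within the cycle; frame `end` closes the loop
    frames = np.arange(start, end + 1)
    frames = frames.clip(max=traj.n_frames - 1)
    phase_in = (frames - start) / (end - start)
    phase_out = np.arange(n_samples) / n_samples
    profiles: dict[str, np.ndarray] = {}
    for joint in joints:
        series = _angle_series(traj, joint)[frames]
        series = np.unwrap(series)
        profiles[joint] = np.interp(phase_out, phase_in, series)
    return StrideKinematics(
        profiles=profiles,
        n_samples=n_samples,
        reference_length=reference_length(traj, start, end),
        stride_id=str(getattr(stride, "stride_id", "")),
        subject_id=str(getattr(stride, "subject_id", "")),
        meta={"start": start, "end": end},
    )


def gait_variables(traj: LandmarkTrajectories, stride) -> GaitVariables:
    """Compute the nine spatiotemporal gait variables for one stride.

    ``stride`` must provide frames ``start``/``end`` and per-hoof contact
    information: ``touchdown_hind`` (frame of the hindhoof touchdown inside
    the stride) and stance fractions ``stance_fore``/``stance_hind``
    (fraction of stride frames in ground contact).
    """
    start, end = int(stride.start), int(stride.end)
    n = end - start
    if n <= 0:
        raise ValueError("zero stride duration")
    duration = n / traj.frame_rate

    withers = traj.point("withers")
    end_frame = min(end, traj.n_frames - 1)
    distance = float(abs(withers[end_frame, 0] - withers[start, 0]) * n / max(end_frame - start, 1))
    frequency = 1.0 / duration
    speed = distance * frequency

    def clearance(proximal: str, hoof: str) -> float:
        d = np.linalg.norm(traj.point(proximal)[start:end] - traj.point(hoof)[start:end], axis=1)
        if d.max() <= 0:
            raise ValueError("degenerate limb length")
        return float(1.0 - d.min() / d.max())

    head = float(np.mean(line_angle(traj.point("ear")[start:end], traj.point("snout")[start:end])))
    torso = float(np.mean(line_angle(traj.point("croup")[start:end], traj.point("withers")[start:end])))

    td_hind = getattr(stride, "touchdown_hind", None)
    phase = float(((td_hind - start) / n) % 1.0) if td_hind is not None else np.nan

    return GaitVariables(
        stride_distance=distance,
        stride_frequency=frequency,
        speed=speed,
        duty_factor_fore=float(getattr(stride, "stance_fore", np.nan)),
        duty_factor_hind=float(getattr(stride, "stance_hind", np.nan)),
        clearance_fore=clearance("withers", "forehoof"),
        clearance_hind=clearance("hip", "hindhoof"),
        head_angle=head,
        hindlimb_phase=phase,
        torso_angle=torso,
    )


def dimensionless(gv: GaitVariables, ref_length: float, g: float = GRAVITY) -> GaitVariables:
    """Convert gait variables to dimensionless form (dynamic similarity).

    distance -> distance / h, frequency -> frequency * sqrt(h/g),
    speed -> speed / sqrt(g*h) with h = ``ref_length``.  Fractions and
    angles are unchanged.  The identity speed = distance * frequency is
    preserved by construction.
    """
    if not ref_length > 0:
        raise ValueError(f"reference length must be positive, got {ref_length}")
    if gv.is_dimensionless:
        raise ValueError("gait variables already dimensionless")
    return replace(
        gv,
        stride_distance=gv.stride_distance / ref_length,
        stride_frequency=gv.stride_frequency * np.sqrt(ref_length / g),
        speed=gv.speed / np.sqrt(g * ref_length),
        is_dimensionless=True,
    )
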