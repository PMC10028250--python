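"""Planar quadruped walker: a forward-kinematic fixture with known truth.

The walker is a side-view linkage of the 17 canonical landmarks.  The
trunk translates at constant speed; each limb's hoof follows a prescribed
cyclic trajectory with an exact stance phase (hoof fixed on the ground),
and the limb joints are solved by closed-form two-link inverse kinematics
with a prescribed distal (carpal/tarsal) flexion wave.  Because hoof and
trunk motion are analytic functions of cycle phase, the generator knows
its own touchdown times exactly and is strictly periodic: landmark
configurations one stride apart differ by a pure translation, so the
Procrustes start-end disparity of a generated stride is numerically zero.

All positions are available at arbitrary times, which lets tests compare
pipeline-extracted joint-angle profiles against truth sampled directly on
the stride-uniform phase grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LANDMARKS, LandmarkTrajectories


def _smootherstep(w: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2-continuous 0->1 ramp."""
    w = np.clip(w, 0.0, 1.0)
    return w**3 * (w * (6.0 * w - 15.0) + 10.0)


@dataclass
class WalkerConfig:
    """Geometry and gait of the synthetic walker (meters, seconds)."""

    size: float = 1.0  # uniform geometric scale (1 = neonate piglet)
    frame_rate: float = 50.0
    stride_frames: int = 40  # integer frames per cycle -> exact periodicity
    stride_length: float = 0.08  # m, per size unit
    duty_factor: float = 0.65
    hind_phase: float = 0.75  # fore->hind touchdown lag, cycle fraction
    step_height: float = 0.02  # swing hoof lift, m per size unit
    distal_flexion: float = 0.5  # peak carpal/tarsal swing flexion, rad
    n_strides: int = 4
    lead_fraction: float = 0.25  # cycle fraction before the first touchdown

    @property
    def frequency(self) -> float:
        return self.frame_rate / self.stride_frames

    @property
    def speed(self) -> float:
        return self.stride_length * self.size * self.frequency


@dataclass
class WalkerTruth:
    """Ground truth accompanying a synthesized recording."""

    touchdowns_fore: list[int]  # exact touchdown frames
    touchdowns_hind: list[int]
    stride_frames: int
    config: WalkerConfig
    profile_fn: object = field(repr=False, default=None)  # joints at arbitrary phase

    def profiles(self, stride_index: int = 0, n_samples: int = 100) -> dict[str, np.ndarray]:
        """True joint-angle profiles of one stride on the uniform phase grid."""
        return self.profile_fn(stride_index, n_samples)


class Walker:
    """Analytic landmark positions of the walking linkage at any time."""

    def __init__(self, config: WalkerConfig):
        self.cfg = config
        s = config.size
        # trunk reference heights and offsets (meters, y up)
        self.withers_y = 0.23 * s
        self.croup_y = 0.22 * s
        self.trunk_len = 0.22 * s
        # rigid offsets from withers (head chain) and croup (tail)
        self.head_offsets = {
            "ear": np.array([0.035, 0.045]) * s,
            "eye": np.array([0.085, 0.055]) * s,
            "snout": np.array([0.135, 0.035]) * s,
        }
        self.tail_offset = np.array([-0.05, 0.01]) * s
        self.scapula_offset = np.array([0.005, -0.025]) * s
        self.fore_root_offset = np.array([0.015, -0.055]) * s  # shoulder
        self.hip_offset = np.array([0.005, -0.02]) * s
        # limb segment lengths
        self.fore = {"l1": 0.075 * s, "l2": 0.065 * s, "l3": 0.06 * s}
        self.hind = {"l1": 0.085 * s, "l2": 0.075 * s, "l3": 0.065 * s}

    # --- per-limb hoof trajectory ---------------------------------------
    def _hoof(self, t: np.ndarray, phase0: float, x_home: float):
        """Hoof position with exact stance; cycle phase 0 = touchdown."""
        cfg = self.cfg
        u = (t * cfg.frequency - phase0) % 1.0
        cycle = np.floor(t * cfg.frequency - phase0)
        lam = cfg.stride_length * cfg.size
        anchor = x_home + cycle * lam
        stance = u < cfg.duty_factor
        w = (u - cfg.duty_factor) / (1.0 - cfg.duty_factor)
        x = np.where(stance, anchor, anchor + lam * _smootherstep(w))
        y = np.where(stance, 0.0, cfg.step_height * cfg.size * np.sin(np.pi * np.clip(w, 0, 1)) ** 2)
        flex = np.where(stance, 0.0, cfg.distal_flexion * np.sin(np.pi * np.clip(w, 0, 1)) ** 2)
        return np.stack([x, y], axis=-1), flex

    def _limb(self, root: np.ndarray, hoof: np.ndarray, flex: np.ndarray, seg: dict, bend: float):
        """Positions of mid joint, distal joint, fetlock for one limb.

        The distal pair (l2, l3) with interior flexion ``flex`` acts as a
        single effective link for the two-link IK; the distal joint is then
        placed on the correct side of the mid-to-hoof line.
        """
        l1, l2, l3 = seg["l1"], seg["l2"], seg["l3"]
        b_eff = np.sqrt(l2**2 + l3**2 + 2 * l2 * l3 * np.cos(flex))
        # solve per-sample (b_eff varies with time)
        d = hoof - root
        r = np.linalg.norm(d, axis=-1)
        r = np.clip(r, np.abs(l1 - b_eff) + 1e-9, l1 + b_eff - 1e-9)
        psi = np.arctan2(d[..., 1], d[..., 0])
        cos_alpha = (l1**2 + r**2 - b_eff**2) / (2 * l1 * r)
        alpha = np.arccos(np.clip(cos_alpha, -1.0, 1.0))
        ang1 = psi + bend * alpha
        mid = root + l1 * np.stack([np.cos(ang1), np.sin(ang1)], axis=-1)
        # distal joint: offset delta from the mid->hoof line
        dh = hoof - mid
        psi2 = np.arctan2(dh[..., 1], dh[..., 0])
        delta = np.arctan2(l3 * np.sin(flex), l2 + l3 * np.cos(flex))
        ang2 = psi2 - bend * delta
        distal = mid + l2 * np.stack([np.cos(ang2), np.sin(ang2)], axis=-1)
        fetlock = distal + 0.6 * (hoof - distal)
        return mid, distal, fetlock

    def positions(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """All 17 landmark positions at times ``t`` (seconds)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cfg = self.cfg
        x_withers = cfg.speed * t
        withers = np.stack([x_withers, np.full_like(t, self.withers_y)], axis=-1)
        croup = withers + np.array([-self.trunk_len, self.croup_y - self.withers_y])
        out = {"withers": withers, "croup": croup, "tailbase": croup + self.tail_offset}
        for name, off in self.head_offsets.items():
            out[name] = withers + off
        out["scapula"] = withers + self.scapula_offset
        shoulder = withers + self.fore_root_offset
        hip = croup + self.hip_offset
        out["shoulder"] = shoulder
        out["hip"] = hip

        lam = cfg.stride_length * cfg.size
        # anchor positions chosen so each limb stands under its root at
        # mid-stance (touchdown ahead by duty/2 strides, liftoff behind)
        fore_home = self.fore_root_offset[0] + (cfg.lead_fraction + cfg.duty_factor / 2) * lam
        hind_lead = cfg.lead_fraction + cfg.hind_phase
        hind_home = -self.trunk_len + self.hip_offset[0] + (hind_lead + cfg.duty_factor / 2) * lam
        fore_hoof, fore_flex = self._hoof(t, cfg.lead_fraction, fore_home)
        hind_hoof, hind_flex = self._hoof(t, hind_lead, hind_home)
        elbow, carpal, forefetlock = self._limb(shoulder, fore_hoof, fore_flex, self.fore, bend=-1.0)
        stifle, tarsal, hindfetlock = self._limb(hip, hind_hoof, hind_flex, self.hind, bend=+1.0)
        out.update(
            elbow=elbow, carpal=carpal, forefetlock=forefetlock, forehoof=fore_hoof,
            stifle=stifle, tarsal=tarsal, hindfetlock=hindfetlock, hindhoof=hind_hoof,
        )
        return out

    def angles(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """True joint angles at times ``t`` under the standard convention."""
        from .kinematics import JOINT_TRIPLETS, joint_angle

        pos = self.positions(t)
        return {
            joint: joint_angle(pos[p], pos[c], pos[d])
            for joint, (p, c, d) in JOINT_TRIPLETS.items()
        }


def synthesize_walker(config: WalkerConfig | None = None) -> tuple[LandmarkTrajectories, WalkerTruth]:
    """Generate a DLC-style recording of the walker plus its ground truth.

    The recording covers ``n_strides`` forelimb cycles with lead-in and
    lead-out margins; all likelihoods are 1.  Touchdown frames are exact
    (the touchdown phase is an integer number of frames by construction).
    """
    cfg = config or WalkerConfig()
    walker = Walker(cfg)
    F = cfg.stride_frames
    lead = int(round(cfg.lead_fraction * F))
    n_frames = lead + cfg.n_strides * F + F  # trailing margin of one cycle
    t = np.arange(n_frames) / cfg.frame_rate
    pos = walker.positions(t)
    xy = np.stack([pos[name] for name in LANDMARKS], axis=1)
    traj = LandmarkTrajectories(
        xy=xy,
        likelihood=np.ones((n_frames, len(LANDMARKS))),
        frame_rate=cfg.frame_rate,
        meta={"synthetic": True, "walker": True},
    )

    touchdowns_fore = [lead + k * F for k in range(cfg.n_strides + 1)]
    hind_first = lead + int(round(cfg.hind_phase * F))
    touchdowns_hind = [hind_first + k * F for k in range(cfg.n_strides + 1) if hind_first + k * F < n_frames]

    def profile_fn(stride_index: int, n_samples: int = 100) -> dict[str, np.ndarray]:
        t0 = touchdowns_fore[stride_index] / cfg.frame_rate
        ts = t0 + np.arange(n_samples) / n_samples / cfg.frequency
        ang = walker.angles(ts)
        return {k: np.unwrap(v) for k, v in ang.items()}

    truth = WalkerTruth(
        touchdowns_fore=touchdowns_fore,
        touchdowns_hind=touchdowns_hind,
        stride_frames=F,
        config=cfg,
        profile_fn=profile_fn,
    )
    return traj, truth
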